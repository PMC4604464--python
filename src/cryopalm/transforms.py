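"""Rigid in-plane transforms used to map the light-microscope frame onto the EM frame.

All coordinates are in nanometres; angles are in radians, counter-clockwise,
about a stated pivot point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform2D:
    """Translation (dx, dy) plus rotation theta about ``pivot``.

    A point p maps to ``R(theta) @ (p - pivot) + pivot + (dx, dy)``.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    pivot: tuple[float, float] = (0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.pivot, dtype=float)
        out = (pts - c) @ self.rotation_matrix().T + c + np.array([self.dx, self.dy])
        return out if np.ndim(points) == 2 else out[0]

    def inverse(self) -> "RigidTransform2D":
        """The transform undoing this one (same pivot)."""
        R_T = self.rotation_matrix().T
        d = R_T @ np.array([self.dx, self.dy])
        return RigidTransform2D(dx=-d[0], dy=-d[1], theta=-self.theta, pivot=self.pivot)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` then ``self``.

        The composed transform is expressed about this transform's pivot.
        """
        R1 = self.rotation_matrix()
        c1 = np.asarray(self.pivot, dtype=float)
        d1 = np.array([self.dx, self.dy])
        # self(other(p)) = R1 R2 (p - c2) + R1 (c2 - c1 + d2) + c1 + d1
        c2 = np.asarray(other.pivot, dtype=float)
        d2 = np.array([other.dx, other.dy])
        theta = self.theta + other.theta
        # express about c1: R(p - c1) + c1 + d  with d chosen to match at p = c1
        probe = self.apply(other.apply(c1))
        d = probe - c1
        return RigidTransform2D(dx=d[0], dy=d[1], theta=theta, pivot=tuple(c1))

    def about_pivot(self, pivot: tuple[float, float]) -> "RigidTransform2D":
        """The same mapping re-expressed about a different pivot point."""
        c_new = np.asarray(pivot, dtype=float)
        d = self.apply(c_new) - c_new
        return RigidTransform2D(dx=float(d[0]), dy=float(d[1]), theta=self.theta,
                                pivot=(float(c_new[0]), float(c_new[1])))

    def as_dict(self) -> dict:
        return {
            "dx_nm": float(self.dx),
            "dy_nm": float(self.dy),
            "theta_rad": float(self.theta),
            "theta_deg": float(np.degrees(self.theta)),
            "pivot_nm": [float(self.pivot[0]), float(self.pivot[1])],
        }
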