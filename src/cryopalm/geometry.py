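"""Polyline geometry: EM-derived membrane contours and point-to-curve distances."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ContourPolyline:
    """Ordered membrane trace in nm, as segmented from an electron micrograph.

    ``vertices`` is an (N, 2) array of (x_nm, y_nm); a closed contour implicitly
    contains the segment joining the last vertex back to the first.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 vertices")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("zero-length segment in contour")
        if self.closed and np.allclose(v[0], v[-1]):
            v = v[:-1]  # drop duplicated closing vertex; closure is implicit
        self.vertices = v

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment start/end arrays, including the closing segment if closed."""
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        if not self.closed:
            a, b = a[:-1], b[:-1]
        return a, b

    @property
    def length(self) -> float:
        a, b = self.segments()
        return float(np.hypot(*(b - a).T).sum())

    def resample(self, spacing_nm: float) -> np.ndarray:
        """Points placed every ``spacing_nm`` along the curve (dense sampling)."""
        a, b = self.segments()
        pts = []
        for p, q in zip(a, b):
            seg_len = float(np.hypot(*(q - p)))
            n = max(int(np.ceil(seg_len / spacing_nm)), 1)
            t = np.arange(n) / n
            pts.append(p + t[:, None] * (q - p))
        return np.vstack(pts)

    def transformed(self, transform) -> "ContourPolyline":
        return ContourPolyline(transform.apply(self.vertices), closed=self.closed)

    # -- text round-trip (two columns x_nm y_nm; '#closed' header flag) -------

    def write(self, path: str | Path) -> None:
        header = "closed" if self.closed else "open"
        np.savetxt(path, self.vertices, fmt="%.4f", header=header)

    @classmethod
    def read(cls, path: str | Path) -> "ContourPolyline":
        closed = True
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            closed = "open" not in first
        return cls(np.loadtxt(path), closed=closed)


def point_to_polyline_distance(points: np.ndarray, curve: ContourPolyline) -> np.ndarray:
    """Minimum Euclidean distance (nm) from each point to the curve.

    The distance to each segment is the perpendicular foot where it falls inside
    the segment, else the nearer endpoint; the closing segment of a closed
    contour is included.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a, b = curve.segments()
    ab = b - a                                      # (M, 2)
    ab2 = np.einsum("ij,ij->i", ab, ab)             # (M,)
    ap = pts[:, None, :] - a[None, :, :]            # (N, M, 2)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.hypot(*(pts[:, None, :] - foot).transpose(2, 0, 1))
    dmin = d.min(axis=1)
    return dmin if np.ndim(points) == 2 else float(dmin[0])


def blob_polyline(center: tuple[float, float], radius_nm: float,
                  harmonics: dict[int, tuple[float, float]] | None = None,
                  spacing_nm: float = 10.0) -> ContourPolyline:
    """Smooth irregular closed contour, e.g. a sectioned organelle outline:
    r(phi) = R (1 + sum_k a_k cos(k phi + phase_k)).

    ``harmonics`` maps harmonic order k to (amplitude fraction a_k, phase);
    the default gives a gently elongated, asymmetric outline whose rotation
    is identifiable (unlike a circle's).
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if harmonics is None:
        harmonics = {2: (0.18, 0.4), 3: (0.10, 1.9)}
    n = max(int(np.ceil(2 * np.pi * radius_nm / spacing_nm)), 16)
    phi = 2 * np.pi * np.arange(n) / n
    r = np.full(n, 1.0)
    for k, (a, ph) in harmonics.items():
        r = r + a * np.cos(k * phi + ph)
    r = radius_nm * np.maximum(r, 0.2)
    v = np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])
    return ContourPolyline(v, closed=True)


def circle_polyline(center: tuple[float, float], radius_nm: float,
                    spacing_nm: float = 10.0) -> ContourPolyline:
    """Closed regular-polygon approximation of a circle (e.g. a mitochondrial
    outer-membrane cross-section), with vertex spacing ~``spacing_nm``."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    n = max(int(np.ceil(2 * np.pi * radius_nm / spacing_nm)), 8)
    ang = 2 * np.pi * np.arange(n) / n
    v = np.column_stack([center[0] + radius_nm * np.cos(ang),
                         center[1] + radius_nm * np.sin(ang)])
    return ContourPolyline(v, closed=True)
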