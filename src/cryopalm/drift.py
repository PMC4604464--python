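"""Post-hoc 3D drift estimation from fiducial-bead traces.

Beads are bright, always-on markers; their per-frame localizations trace the
sample drift, which is smoothed and subtracted from every molecule
localization.  This is the software analogue of an active feedback
stabilization loop, and its residual-bead scatter quantifies the achieved
stability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AXES = ["x_nm", "y_nm", "z_nm"]


@dataclass
class DriftTrace:
    """Per-frame displacement relative to the reference (first) frame."""

    frame: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray
    dz_nm: np.ndarray
    n_beads: int
    smoothing_window: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame, "dx_nm": self.dx_nm,
                             "dy_nm": self.dy_nm, "dz_nm": self.dz_nm})

    def write_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


class BeadLostWarning(UserWarning):
    pass


def track_fiducials(table: pd.DataFrame, bead_seeds_nm: np.ndarray,
                    search_radius_nm: float = 400.0,
                    min_coverage: float = 0.8,
                    n_frames: int | None = None) -> list[pd.DataFrame]:
    """Extract per-bead trajectories from a per-frame localization table.

    Per frame, the detection nearest the bead's last known position (the seed
    initially) within ``search_radius_nm`` is taken, so slow drifts larger
    than the search radius can still be followed; gaps are linearly
    interpolated.  Beads visible in fewer than ``min_coverage`` of the frames
    are excluded with a warning.
    """
    seeds = np.atleast_2d(np.asarray(bead_seeds_nm, dtype=float))
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1 if len(table) else 0
    has_z = "z_nm" in table.columns
    trajectories = []
    for b, seed in enumerate(seeds):
        rows = np.full((n_frames, 3), np.nan)
        ref = np.asarray(seed[:2], dtype=float)
        for f, g in table.groupby("frame"):
            d = np.hypot(g["x_nm"] - ref[0], g["y_nm"] - ref[1])
            i = d.idxmin()
            if d.loc[i] <= search_radius_nm:
                rows[int(f), 0] = g.loc[i, "x_nm"]
                rows[int(f), 1] = g.loc[i, "y_nm"]
                rows[int(f), 2] = g.loc[i, "z_nm"] if has_z else 0.0
                ref = rows[int(f), :2]
        coverage = np.isfinite(rows[:, 0]).mean()
        if coverage < min_coverage:
            warnings.warn(f"bead {b} visible in only {coverage:.0%} of frames; excluded",
                          BeadLostWarning)
            continue
        frames = np.arange(n_frames)
        good = np.isfinite(rows[:, 0])
        for c in range(3):
            rows[~good, c] = np.interp(frames[~good], frames[good], rows[good, c])
        trajectories.append(pd.DataFrame({"frame": frames, "x_nm": rows[:, 0],
                                          "y_nm": rows[:, 1], "z_nm": rows[:, 2]}))
    return trajectories


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad: pad + len(x)]
    return out


def estimate_drift(trajectories: list[pd.DataFrame],
                   smoothing_window: int = 50) -> DriftTrace:
    """Average bead displacement relative to the reference (first) frame,
    smoothed with a moving average."""
    if not trajectories:
        raise ValueError("need at least one valid bead trajectory")
    n_frames = len(trajectories[0])
    disp = np.zeros((n_frames, 3))
    for traj in trajectories:
        p = traj[AXES].to_numpy()
        disp += p - p[0]
    disp /= len(trajectories)
    for c in range(3):
        disp[:, c] = _moving_average(disp[:, c], smoothing_window)
    disp -= disp[0]   # trace at the reference frame is exactly zero
    return DriftTrace(frame=np.arange(n_frames), dx_nm=disp[:, 0],
                      dy_nm=disp[:, 1], dz_nm=disp[:, 2],
                      n_beads=len(trajectories), smoothing_window=smoothing_window)


def apply_drift(table: pd.DataFrame, drift: DriftTrace) -> pd.DataFrame:
    """Subtract the drift trace from every localization (by its frame).

    Photon counts and widths are untouched."""
    out = table.copy()
    f = out["frame"].to_numpy().astype(int)
    out["x_nm"] = out["x_nm"] - drift.dx_nm[f]
    out["y_nm"] = out["y_nm"] - drift.dy_nm[f]
    if "z_nm" in out.columns:
        out["z_nm"] = out["z_nm"] - drift.dz_nm[f]
    return out


def estimate_and_apply_drift(trajectories: list[pd.DataFrame], table: pd.DataFrame,
                             smoothing_window: int = 50
                             ) -> tuple[pd.DataFrame, DriftTrace, float]:
    """Estimate drift from bead trajectories, subtract it from the table, and
    report the residual bead RMS (nm, over all axes) after correction."""
    drift = estimate_drift(trajectories, smoothing_window)
    corrected = apply_drift(table, drift)
    res = []
    d = np.column_stack([drift.dx_nm, drift.dy_nm, drift.dz_nm])
    for traj in trajectories:
        p = traj[AXES].to_numpy() - d
        res.append(p - p.mean(axis=0))
    res = np.vstack(res)
    rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    return corrected, drift, rms
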