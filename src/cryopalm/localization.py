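"""Sub-pixel localization: elliptical Gaussian fitting, frame linking,
astigmatic z assignment and localization-precision estimation.

The localization table is a pandas DataFrame with the documented columns
``frame, x_nm, y_nm, z_nm, photons, bg_photons, wx_nm, wy_nm, ellipticity,
first_frame, last_frame, precision_nm, precision_z_nm`` (z columns appear once
a calibration is applied).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf

from .calibration import ZCalibration
from .detection import detect_spots


# ---------------------------------------------------------------------------
# elliptical Gaussian fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFit:
    x_px: float          # in frame coordinates (pixel centres at integers)
    y_px: float
    volume: float        # integrated counts above background
    wx_px: float
    wy_px: float
    background: float    # counts per pixel
    ok: bool
    at_bounds: bool


def _pixel_profile(coords: np.ndarray, center: float, sigma: float) -> np.ndarray:
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((coords + 0.5 - center) / s) - erf((coords - 0.5 - center) / s))


def _model(shape):
    ny, nx = shape
    ys, xs = np.arange(ny), np.arange(nx)

    def f(_, x0, y0, vol, wx, wy, bg):
        return (bg + vol * np.outer(_pixel_profile(ys, y0, wy),
                                    _pixel_profile(xs, x0, wx))).ravel()

    return f


def fit_elliptical_gaussian(crop: np.ndarray, origin: tuple[int, int] = (0, 0)
                            ) -> GaussianFit:
    """Least-squares fit of an axis-aligned elliptical Gaussian plus a constant
    background to a crop containing one candidate peak.

    The model integrates the Gaussian over each pixel; ``volume`` is the total
    integrated signal above background in camera counts (photons follow by
    dividing by the camera gain).  ``origin`` is the (y, x) pixel offset of the
    crop within the full frame.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2 or min(crop.shape) < 7:
        raise ValueError("crop must be at least 7x7 px")
    ny, nx = crop.shape
    border = np.concatenate([crop[0], crop[-1], crop[:, 0], crop[:, -1]])
    bg0 = float(np.median(border))
    sub = np.clip(crop - bg0, 0, None)
    total = sub.sum()
    if total <= 0:
        return GaussianFit(np.nan, np.nan, 0.0, np.nan, np.nan, bg0, False, False)
    ys, xs = np.mgrid[0:ny, 0:nx]
    x0 = float((sub * xs).sum() / total)
    y0 = float((sub * ys).sum() / total)
    p0 = [x0, y0, float(total), 1.2, 1.2, bg0]
    lo = [-1.0, -1.0, 1e-3, 0.3, 0.3, -np.inf]
    hi = [nx, ny, np.inf, float(max(nx, ny)), float(max(nx, ny)), np.inf]
    try:
        # Poisson-approximate weights (sigma ~ sqrt(expected counts), taken
        # from a smoothed image so the weights are not noise-correlated);
        # unweighted LSQ over-weights bright centre pixels and loses ~30%
        # efficiency, raw-data weights bias the fit at low counts
        weights = np.sqrt(np.clip(ndimage.gaussian_filter(crop, 1.0), 1.0, None))
        popt, _ = curve_fit(_model(crop.shape), None, crop.ravel(), p0=p0,
                            sigma=weights.ravel(),
                            bounds=(lo, hi), maxfev=400)
    except (RuntimeError, ValueError):
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, bg0, False, False)
    x0, y0, vol, wx, wy, bg = popt
    eps = 1e-6
    at_bounds = bool(wx <= lo[3] + eps or wy <= lo[3] + eps
                     or wx >= hi[3] - eps or wy >= hi[3] - eps)
    return GaussianFit(x_px=float(x0) + origin[1], y_px=float(y0) + origin[0],
                       volume=float(vol), wx_px=float(wx), wy_px=float(wy),
                       background=float(bg), ok=True, at_bounds=at_bounds)


# ---------------------------------------------------------------------------
# localization precision
# ---------------------------------------------------------------------------

def thompson_precision(sigma_nm, n_photons, bg_noise_photons, pixel_nm):
    """Thompson/Larson/Webb lateral localization precision (nm):

        s^2 = sigma^2/N + a^2/(12 N) + 8 pi sigma^4 b^2 / (a^2 N^2)

    with PSF width sigma, photon count N, pixel size a and background noise
    (std per pixel, in photons) b.
    """
    sigma = np.asarray(sigma_nm, dtype=float)
    N = np.asarray(n_photons, dtype=float)
    if np.any(N <= 0):
        raise ValueError("photon count must be positive")
    b = np.asarray(bg_noise_photons, dtype=float)
    a = pixel_nm
    s2 = sigma ** 2 / N + a ** 2 / (12 * N) + 8 * np.pi * sigma ** 4 * b ** 2 / (a ** 2 * N ** 2)
    return np.sqrt(s2)


def axial_precision(wx_nm, wy_nm, n_photons, cal: ZCalibration, z_nm):
    """Axial precision by propagating width noise through the calibration
    slope: sigma_z ~ sqrt(var wx + var wy) / |d(wx - wy)/dz| with the width
    standard error approximated as w/sqrt(N)."""
    slope = np.maximum(np.vectorize(cal.axial_slope)(z_nm), 1e-6)
    var_w = (np.asarray(wx_nm) ** 2 + np.asarray(wy_nm) ** 2) / np.asarray(n_photons, dtype=float)
    return np.sqrt(var_w) / slope


# ---------------------------------------------------------------------------
# movie -> per-frame localization table
# ---------------------------------------------------------------------------

def localize_movie(stack: np.ndarray, pixel_size_nm: float, gain: float = 1.0,
                   levels: int = 3, k: float = 3.0, window_px: int = 9,
                   merge_radius_px: float = 2.0) -> pd.DataFrame:
    """Detect and fit every spot in every frame (no linking yet)."""
    rows = []
    for f in range(stack.shape[0]):
        frame = stack[f]
        for cand in detect_spots(frame, frame_index=f, levels=levels, k=k,
                                 merge_radius_px=merge_radius_px,
                                 window_px=window_px):
            y0, y1, x0, x1 = cand.window
            fit = fit_elliptical_gaussian(frame[y0:y1, x0:x1], origin=(y0, x0))
            if not fit.ok or fit.at_bounds or fit.volume <= 0:
                continue
            rows.append((f, fit.x_px * pixel_size_nm, fit.y_px * pixel_size_nm,
                         fit.volume / gain, max(fit.background, 0.0) / gain,
                         fit.wx_px * pixel_size_nm, fit.wy_px * pixel_size_nm))
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons",
                                       "bg_photons", "wx_nm", "wy_nm"])


# ---------------------------------------------------------------------------
# trajectory linking
# ---------------------------------------------------------------------------

def link_trajectories(table: pd.DataFrame, max_displacement_nm: float = 160.0,
                      max_gap_frames: int = 1) -> pd.DataFrame:
    """Merge detections of the same molecule in successive frames.

    Greedy nearest-neighbour linking within ``max_displacement_nm``, allowing
    up to ``max_gap_frames`` missed frames.  A merged record carries the
    photon-weighted mean position and widths, summed photons, mean background
    and the first/last frame of the trajectory.
    """
    if len(table) == 0:
        out = table.copy()
        out["first_frame"] = out.get("frame", pd.Series(dtype=int))
        out["last_frame"] = out["first_frame"]
        return out
    if not table["frame"].is_monotonic_increasing:
        table = table.sort_values("frame", kind="stable").reset_index(drop=True)

    tracks: list[dict] = []
    open_tracks: list[int] = []
    cols = ["x_nm", "y_nm", "wx_nm", "wy_nm"]
    for f, group in table.groupby("frame", sort=True):
        open_tracks = [t for t in open_tracks
                       if f - tracks[t]["last_frame"] <= max_gap_frames + 1]
        det = group.reset_index(drop=True)
        pairs = []
        for ti in open_tracks:
            t = tracks[ti]
            d = np.hypot(det["x_nm"] - t["x_nm"], det["y_nm"] - t["y_nm"])
            for di in range(len(det)):
                if d[di] <= max_displacement_nm:
                    pairs.append((float(d[di]), di, ti))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))  # ties -> earlier index
        used_det, used_trk = set(), set()
        for dist, di, ti in pairs:
            if di in used_det or ti in used_trk:
                continue
            used_det.add(di)
            used_trk.add(ti)
            t = tracks[ti]
            row = det.iloc[di]
            wsum = t["photons"] + row["photons"]
            for c in cols:
                t[c] = (t[c] * t["photons"] + row[c] * row["photons"]) / wsum
            t["bg_photons"] = (t["bg_photons"] * t["n_obs"] + row["bg_photons"]) / (t["n_obs"] + 1)
            t["photons"] = wsum
            t["n_obs"] += 1
            t["last_frame"] = int(f)
        for di in range(len(det)):
            if di not in used_det:
                row = det.iloc[di]
                tracks.append({"x_nm": row["x_nm"], "y_nm": row["y_nm"],
                               "wx_nm": row["wx_nm"], "wy_nm": row["wy_nm"],
                               "photons": row["photons"],
                               "bg_photons": row["bg_photons"],
                               "first_frame": int(f), "last_frame": int(f),
                               "n_obs": 1})
                open_tracks.append(len(tracks) - 1)

    out = pd.DataFrame(tracks)
    out["frame"] = out["first_frame"]
    order = ["frame", "x_nm", "y_nm", "photons", "bg_photons", "wx_nm", "wy_nm",
             "first_frame", "last_frame", "n_obs"]
    return out[order].sort_values(["first_frame", "x_nm"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# z assignment + precision columns
# ---------------------------------------------------------------------------

def assign_z(table: pd.DataFrame, cal: ZCalibration,
             ellipticity_bounds: tuple[float, float] = (0.5, 2.0)) -> pd.DataFrame:
    """Assign z from fitted widths; reject records whose ellipticity is too
    large or too small, or whose widths leave the calibration envelope.

    Adds ``ellipticity``, ``z_nm`` (NaN when rejected) and ``reject_reason``
    ('' for accepted records).
    """
    out = table.copy()
    e = out["wx_nm"] / out["wy_nm"]
    out["ellipticity"] = e
    z = np.full(len(out), np.nan)
    reason = np.array([""] * len(out), dtype=object)
    lo, hi = ellipticity_bounds
    for i, (wx, wy, ei) in enumerate(zip(out["wx_nm"], out["wy_nm"], e)):
        if not (lo <= ei <= hi):
            reason[i] = "ellipticity"
            continue
        zi, code = cal.assign_z(wx, wy)
        if zi is None:
            reason[i] = code
        else:
            z[i] = zi
    out["z_nm"] = z
    out["reject_reason"] = reason
    return out


def add_precision(table: pd.DataFrame, pixel_size_nm: float,
                  cal: ZCalibration | None = None) -> pd.DataFrame:
    """Add Thompson lateral precision (and axial precision when z is known)."""
    out = table.copy()
    sigma = np.sqrt(out["wx_nm"] * out["wy_nm"])
    b = np.sqrt(np.clip(out["bg_photons"], 0, None))
    out["precision_nm"] = thompson_precision(sigma, out["photons"], b, pixel_size_nm)
    if cal is not None and "z_nm" in out:
        ok = out["z_nm"].notna()
        pz = np.full(len(out), np.nan)
        if ok.any():
            pz[ok.to_numpy()] = axial_precision(out.loc[ok, "wx_nm"],
                                                out.loc[ok, "wy_nm"],
                                                out.loc[ok, "photons"], cal,
                                                out.loc[ok, "z_nm"])
        out["precision_z_nm"] = pz
    return out
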