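"""Light -> EM correlation.

Two complementary procedures:

1. Multi-step fiducial-bead registration (light channel to channel, light to
   low-magnification EM, low- to high-magnification EM) whose per-step RMS
   residuals combine in quadrature into a total registration error budget.

2. Rigid in-plane correlation of the single-molecule localizations against an
   EM-derived membrane contour: find the translation + rotation minimizing the
   summed molecule-to-curve distances (sum D_i), excluding far outliers
   iteratively, with 2/3-1/3 cross-validation of the held-out molecule-to-
   membrane distances; z alignment uses the peak/FWHM of the z histogram
   against the tomogram thickness.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from skimage.transform import estimate_transform

from .geometry import ContourPolyline, point_to_polyline_distance
from .rendering import fit_gaussian_histogram
from .transforms import RigidTransform2D


# ---------------------------------------------------------------------------
# fiducial-bead registration + error budget
# ---------------------------------------------------------------------------

@dataclass
class RegistrationErrorBudget:
    """Per-step registration errors (nm): light channel-to-channel, light to
    low-mag EM, low- to high-mag EM."""

    epsilon_l_nm: float
    epsilon_le_nm: float
    epsilon_e_nm: float

    @property
    def total_nm(self) -> float:
        return combine_errors([self.epsilon_l_nm, self.epsilon_le_nm, self.epsilon_e_nm])

    def as_dict(self) -> dict:
        d = asdict(self)
        d["epsilon_total_nm"] = self.total_nm
        return d


def combine_errors(components) -> float:
    """Total registration error as the root-sum-of-squares of independent
    per-step errors."""
    c = np.asarray(components, dtype=float)
    if np.any(c < 0):
        raise ValueError("error components must be non-negative")
    return float(np.sqrt(np.sum(c ** 2)))


def register_point_sets(source: np.ndarray, target: np.ndarray,
                        model: str = "similarity"):
    """Least-squares similarity or affine registration of matched bead
    constellations.  Returns (skimage transform, RMS residual in input units).
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (N, 2) arrays")
    n_min = {"similarity": 3, "affine": 4}.get(model)
    if n_min is None:
        raise ValueError("model must be 'similarity' or 'affine'")
    if len(src) < n_min:
        raise ValueError(f"{model} registration needs at least {n_min} correspondences")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(np.abs(centered).max(), 1.0)) < 2:
        raise ValueError("degenerate (collinear) bead constellation")
    tform = estimate_transform(model, src, dst)
    residuals = tform(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals ** 2, axis=1))))
    return tform, rms


# ---------------------------------------------------------------------------
# rigid point-set-to-curve registration
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    transform: RigidTransform2D
    sum_distance_nm: float
    distances_nm: np.ndarray               # per included molecule, at optimum
    included: np.ndarray                   # bool mask over the input molecules
    n_excluded: int
    hit_bounds: bool
    crossval_mean_nm: float | None = None
    crossval_median_nm: float | None = None
    z_offset_nm: float | None = None
    z_thickness_nm: float | None = None

    def as_dict(self) -> dict:
        return {"transform": self.transform.as_dict(),
                "sum_distance_nm": float(self.sum_distance_nm),
                "n_included": int(self.included.sum()),
                "n_excluded": int(self.n_excluded),
                "hit_bounds": bool(self.hit_bounds),
                "crossval_mean_nm": self.crossval_mean_nm,
                "crossval_median_nm": self.crossval_median_nm,
                "z_offset_nm": self.z_offset_nm,
                "z_thickness_nm": self.z_thickness_nm}


def _as_points(molecules) -> np.ndarray:
    if isinstance(molecules, pd.DataFrame):
        return molecules[["x_nm", "y_nm"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(molecules, dtype=float))


def curve_objective(points: np.ndarray, curve: ContourPolyline,
                    pivot: tuple[float, float]):
    """Sum-distance objective: f(dx, dy, theta) over a fixed included set."""

    def f(params):
        t = RigidTransform2D(params[0], params[1], params[2], pivot=pivot)
        return float(point_to_polyline_distance(t.apply(points), curve).sum())

    return f


def register_points_to_curve(molecules, curve: ContourPolyline,
                             bounds_nm: float = 200.0, bounds_deg: float = 10.0,
                             exclusion_nm: float = 100.0,
                             coarse_steps: int = 9, max_iterations: int = 10,
                             pivot: tuple[float, float] | None = None
                             ) -> CorrelationResult:
    """Find the rigid in-plane transform minimizing the summed molecule-to-
    membrane distances (sum D_i).

    A coarse grid over the search bounds seeds a Nelder-Mead refinement; the
    set of included molecules (distance <= ``exclusion_nm`` under the current
    transform) is re-evaluated and the fit repeated until it stabilizes.
    Deterministic for fixed inputs and bounds.
    """
    pts = _as_points(molecules)
    if pivot is None:
        pivot = tuple(pts.mean(axis=0))
    b_th = np.radians(bounds_deg)

    included = point_to_polyline_distance(pts, curve) <= exclusion_nm + bounds_nm
    if included.sum() < 10:
        raise ValueError("fewer than 10 molecules within reach of the contour")

    params = np.zeros(3)
    hit_bounds = False
    mask = included.copy()
    for _ in range(max_iterations):
        sub = pts[mask]
        raw_obj = curve_objective(sub, curve, pivot)
        scale = max(len(sub), 1)

        def obj(p, _raw=raw_obj, _scale=scale):
            # soft wall keeps the simplex inside the stated search bounds
            over = (max(abs(p[0]) - bounds_nm, 0.0) + max(abs(p[1]) - bounds_nm, 0.0)
                    + max(abs(p[2]) - b_th, 0.0) * 1e3)
            return _raw(p) + 1e3 * _scale * over
        # coarse grid, then simplex refinement from the best few grid seeds
        # (the sum-distance landscape has local minima)
        cand = [(obj(params), params.copy())]
        for dx in np.linspace(-bounds_nm, bounds_nm, coarse_steps):
            for dy in np.linspace(-bounds_nm, bounds_nm, coarse_steps):
                for th in np.linspace(-b_th, b_th, coarse_steps):
                    p = np.array([dx, dy, th])
                    cand.append((obj(p), p))
        cand.sort(key=lambda c: c[0])
        best_val, params = np.inf, cand[0][1]
        for _, p0 in cand[:5]:
            res = minimize(obj, p0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
            if res.fun < best_val:
                best_val, params = res.fun, res.x
        # restarting shrinks the simplex around the incumbent; the sum of
        # distances is non-smooth at zero so a single run can stall early
        for _ in range(3):
            res = minimize(obj, params, method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
            if res.fun >= best_val - 1e-9:
                break
            best_val, params = res.fun, res.x
        if abs(params[0]) > bounds_nm or abs(params[1]) > bounds_nm or abs(params[2]) > b_th:
            hit_bounds = True
            warnings.warn("curve registration optimum at or beyond the search bounds")
        t = RigidTransform2D(*params, pivot=pivot)
        d_all = point_to_polyline_distance(t.apply(pts), curve)
        new_mask = d_all <= exclusion_nm
        if new_mask.sum() < 10:
            break
        if np.array_equal(new_mask, mask):
            mask = new_mask
            break
        mask = new_mask

    t = RigidTransform2D(*params, pivot=pivot)
    d_final = point_to_polyline_distance(t.apply(pts[mask]), curve)
    return CorrelationResult(transform=t, sum_distance_nm=float(d_final.sum()),
                             distances_nm=d_final, included=mask,
                             n_excluded=int((~mask).sum()), hit_bounds=hit_bounds)


def grid_search_registration(molecules, curve: ContourPolyline,
                             bounds_nm: float = 50.0, bounds_deg: float = 5.0,
                             step_nm: float = 1.0, step_deg: float = 0.1,
                             pivot: tuple[float, float] | None = None,
                             distance_map_px_nm: float = 1.0
                             ) -> tuple[RigidTransform2D, float]:
    """Exhaustive grid search over (dx, dy, theta), used as an optimizer
    oracle on small instances.

    Distances are looked up in a rasterized Euclidean distance map of the
    curve (``distance_map_px_nm`` resolution), which bounds the per-point
    distance error by roughly one raster pixel.
    """
    from scipy.ndimage import distance_transform_edt, map_coordinates

    pts = _as_points(molecules)
    if pivot is None:
        pivot = tuple(pts.mean(axis=0))
    dense = curve.resample(distance_map_px_nm / 2)
    pad = bounds_nm + np.hypot(*(pts - pivot).T).max() * np.radians(bounds_deg) + 20
    x0, y0 = dense.min(axis=0) - pad
    x1, y1 = dense.max(axis=0) + pad
    nx = int(np.ceil((x1 - x0) / distance_map_px_nm)) + 1
    ny = int(np.ceil((y1 - y0) / distance_map_px_nm)) + 1
    occ = np.ones((ny, nx), dtype=bool)
    ix = np.clip(np.rint((dense[:, 0] - x0) / distance_map_px_nm).astype(int), 0, nx - 1)
    iy = np.clip(np.rint((dense[:, 1] - y0) / distance_map_px_nm).astype(int), 0, ny - 1)
    occ[iy, ix] = False
    dmap = distance_transform_edt(occ, sampling=distance_map_px_nm)

    thetas = np.arange(-np.radians(bounds_deg), np.radians(bounds_deg) + 1e-12,
                       np.radians(step_deg))
    shifts = np.arange(-bounds_nm, bounds_nm + 1e-12, step_nm)
    best = (0.0, 0.0, 0.0)
    best_val = np.inf
    c = np.asarray(pivot)
    for th in thetas:
        rot = RigidTransform2D(0.0, 0.0, float(th), pivot=pivot).apply(pts)
        # evaluate all translations at once via the distance map
        gx = (rot[:, 0] - x0) / distance_map_px_nm
        gy = (rot[:, 1] - y0) / distance_map_px_nm
        sx = shifts / distance_map_px_nm
        X = gx[None, None, :] + sx[:, None, None]        # (Sx, 1, N)
        Y = gy[None, None, :] + sx[None, :, None]        # (1, Sy, N)
        X, Y = np.broadcast_arrays(X, Y)
        vals = map_coordinates(dmap, [Y.ravel(), X.ravel()], order=1,
                               mode="nearest").reshape(X.shape)
        totals = vals.sum(axis=2)                        # (Sx, Sy)
        i, j = np.unravel_index(np.argmin(totals), totals.shape)
        if totals[i, j] < best_val:
            best_val = float(totals[i, j])
            best = (float(shifts[i]), float(shifts[j]), float(th))
    t = RigidTransform2D(*best, pivot=pivot)
    return t, best_val


def crossvalidate_registration(molecules, curve: ContourPolyline,
                               holdout_fraction: float = 1.0 / 3.0, seed: int = 0,
                               **fit_kwargs) -> dict:
    """Fit the curve registration on a random training fraction (2/3 by
    default) and report the held-out molecule-to-membrane distances."""
    pts = _as_points(molecules)
    if len(pts) < 30:
        raise ValueError("cross-validation needs at least 30 molecules")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pts))
    n_hold = int(round(holdout_fraction * len(pts)))
    hold, train = perm[:n_hold], perm[n_hold:]
    result = register_points_to_curve(pts[train], curve, **fit_kwargs)
    d = point_to_polyline_distance(result.transform.apply(pts[hold]), curve)
    return {"result": result, "holdout_distances_nm": d,
            "mean_nm": float(d.mean()), "median_nm": float(np.median(d)),
            "n_train": len(train), "n_holdout": len(hold)}


# ---------------------------------------------------------------------------
# z alignment and precision filtering
# ---------------------------------------------------------------------------

def align_z(z_values_nm, tomogram_thickness_nm: float,
            consistency_slack_nm: float = 30.0) -> dict:
    """Locate the section mid-plane and apparent thickness from the Gaussian
    z histogram; flag consistency with the tomogram-measured thickness."""
    z = np.asarray(z_values_nm, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 100:
        raise ValueError("z alignment needs at least 100 z values")
    fit = fit_gaussian_histogram(z)
    if fit.degenerate or not fit.ok:
        return {"fit": fit, "z_offset_nm": np.nan, "thickness_nm": np.nan,
                "consistent": False, "degenerate": True}
    consistent = abs(fit.fwhm - tomogram_thickness_nm) <= consistency_slack_nm
    return {"fit": fit, "z_offset_nm": fit.center, "thickness_nm": fit.fwhm,
            "consistent": bool(consistent), "degenerate": False}


def filter_by_precision(table: pd.DataFrame, keep_fraction: float | None = None,
                        cutoff_nm: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Keep the best-precision records (smallest precision values).

    Exactly one of ``keep_fraction`` (retain ceil(f * n) best records) or
    ``cutoff_nm`` (retain precision <= cutoff) must be given.  Returns the
    filtered table and a summary with the resulting mean/median precision.
    """
    if (keep_fraction is None) == (cutoff_nm is None):
        raise ValueError("give exactly one of keep_fraction or cutoff_nm")
    if "precision_nm" not in table:
        raise ValueError("precision column is required")
    if keep_fraction is not None:
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        n_keep = int(np.ceil(keep_fraction * len(table)))
        kept = table.nsmallest(n_keep, "precision_nm")
    else:
        kept = table[table["precision_nm"] <= cutoff_nm]
    summary = {"n_kept": len(kept), "n_total": len(table),
               "precision_mean_nm": float(kept["precision_nm"].mean()) if len(kept) else np.nan,
               "precision_median_nm": float(kept["precision_nm"].median()) if len(kept) else np.nan}
    return kept.copy(), summary
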