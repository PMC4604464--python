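"""Super-resolution image rendering and image-space analyses.

Each drift-corrected molecule is drawn as a unit-mass Gaussian spot whose FWHM
equals 2.355 x its localization precision, so the rendered image conserves the
molecule count as total intensity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))   # 2.355


@dataclass
class RenderedImage:
    data: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float]            # (x, y) of the centre of pixel (0, 0)
    z_bounds_nm: tuple[float, float] | None = None

    @property
    def extent_nm(self) -> tuple[float, float]:
        ny, nx = self.data.shape
        return nx * self.pixel_nm, ny * self.pixel_nm


@dataclass
class GaussianHistFit:
    center: float
    sigma: float
    amplitude: float
    fwhm: float
    r_squared: float
    ok: bool
    degenerate: bool = False


def split_z_sections(table: pd.DataFrame, n_sections: int = 8
                     ) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Partition records into ``n_sections`` equal-width z bins spanning
    [min z, max z].  Returns (tables, bin edges)."""
    if table["z_nm"].isna().any():
        raise ValueError("all records must have z assigned")
    z = table["z_nm"].to_numpy()
    edges = np.linspace(z.min(), z.max(), n_sections + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_sections - 1)
    return [table[idx == i].copy() for i in range(n_sections)], edges


def render(table: pd.DataFrame, pixel_nm: float = 5.0,
           blur: str | float = "precision",
           bounds_nm: tuple[float, float, float, float] | None = None,
           z_bounds_nm: tuple[float, float] | None = None) -> RenderedImage:
    """Render molecules onto a grid of ``pixel_nm`` nm pixels.

    ``blur`` is 'precision' (per-molecule FWHM = 2.355 x precision), 'none'
    (pure 2D histogram, as used for Fourier ring correlation), or a fixed
    sigma in nm.  Each molecule contributes exactly unit mass.
    """
    if bounds_nm is None:
        if len(table) == 0:
            raise ValueError("cannot infer bounds from an empty table")
        pad = 3 * pixel_nm + (3 * float(table["precision_nm"].max())
                              if blur == "precision" and "precision_nm" in table else 0.0)
        bounds_nm = (table["x_nm"].min() - pad, table["x_nm"].max() + pad,
                     table["y_nm"].min() - pad, table["y_nm"].max() + pad)
    x0, x1, y0, y1 = bounds_nm
    nx = max(int(np.ceil((x1 - x0) / pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_nm)), 1)
    img = np.zeros((ny, nx))

    if len(table):
        xs = (table["x_nm"].to_numpy() - x0) / pixel_nm
        ys = (table["y_nm"].to_numpy() - y0) / pixel_nm
        if blur == "none":
            ix = np.floor(xs).astype(int)
            iy = np.floor(ys).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            np.add.at(img, (iy[ok], ix[ok]), 1.0)
        else:
            if blur == "precision":
                if "precision_nm" not in table:
                    raise ValueError("precision blur requires a precision_nm column")
                sig = table["precision_nm"].to_numpy() / pixel_nm
            else:
                sig = np.full(len(table), float(blur) / pixel_nm)
            sig = np.maximum(sig, 0.3)
            for xc, yc, s in zip(xs, ys, sig):
                r = int(np.ceil(4 * s)) + 1
                ax0, ax1 = max(int(xc) - r, 0), min(int(xc) + r + 1, nx)
                ay0, ay1 = max(int(yc) - r, 0), min(int(yc) + r + 1, ny)
                if ax0 >= ax1 or ay0 >= ay1:
                    continue
                gx = np.exp(-0.5 * ((np.arange(ax0, ax1) - xc) / s) ** 2)
                gy = np.exp(-0.5 * ((np.arange(ay0, ay1) - yc) / s) ** 2)
                stamp = np.outer(gy, gx)
                total = stamp.sum()
                if total > 0:
                    img[ay0:ay1, ax0:ax1] += stamp / total   # unit mass per molecule
    return RenderedImage(data=img, pixel_nm=pixel_nm, origin_nm=(x0, y0),
                         z_bounds_nm=z_bounds_nm)


def _gauss(x, a, mu, sigma, c):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c


def fit_gaussian_histogram(values: np.ndarray, bins: int = 30,
                           pad_fraction: float = 0.25) -> GaussianHistFit:
    """Gaussian fit to a histogram of values, with empty padding bins on both
    sides so the fitted curve is anchored to zero outside the data."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3 or np.ptp(values) == 0:
        v = float(values[0]) if len(values) else np.nan
        return GaussianHistFit(v, 0.0, np.nan, 0.0, np.nan, ok=False, degenerate=True)
    span = np.ptp(values)
    lo, hi = values.min() - pad_fraction * span, values.max() + pad_fraction * span
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # no baseline term: an empirical histogram decays to zero outside the data
    p0 = [counts.max(), float(values.mean()), float(values.std())]
    try:
        popt, _ = curve_fit(lambda x, a, mu, s: _gauss(x, a, mu, s, 0.0),
                            centers, counts, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        return GaussianHistFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    a, mu, sigma = popt
    popt = [a, mu, sigma, 0.0]
    sigma = abs(float(sigma))
    ss_res = float(np.sum((counts - _gauss(centers, *popt)) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return GaussianHistFit(center=float(mu), sigma=sigma, amplitude=float(a),
                           fwhm=FWHM_FACTOR * sigma, r_squared=r2, ok=True)


def z_extent(table: pd.DataFrame, bins: int = 30) -> GaussianHistFit:
    """Gaussian fit of the z histogram; peak marks the section mid-plane and
    FWHM the apparent section thickness.  A warning-quality fit (low R^2)
    indicates a non-Gaussian, e.g. uniform, axial distribution."""
    return fit_gaussian_histogram(table["z_nm"].to_numpy(), bins=bins)


def line_profile(image: RenderedImage, p0_nm: tuple[float, float],
                 p1_nm: tuple[float, float], width_nm: float = 50.0
                 ) -> tuple[np.ndarray, np.ndarray, GaussianHistFit]:
    """Intensity profile along the segment p0->p1, averaged across the
    perpendicular ``width_nm``, with a Gaussian fitted to the profile.

    Returns (positions along the segment in nm, profile, fit); the fitted
    sigma is in nm.  A flat profile is flagged as degenerate.
    """
    x0, y0 = image.origin_nm
    p0 = (np.asarray(p0_nm) - (x0, y0)) / image.pixel_nm
    p1 = (np.asarray(p1_nm) - (x0, y0)) / image.pixel_nm
    ny, nx = image.data.shape
    for p in (p0, p1):
        if not (0 <= p[0] < nx and 0 <= p[1] < ny):
            raise ValueError("profile segment must lie inside the image")
    seg = p1 - p0
    seg_len = float(np.hypot(*seg))
    u = seg / seg_len
    v = np.array([-u[1], u[0]])
    n_along = max(int(np.ceil(seg_len)), 2)
    half_w = 0.5 * width_nm / image.pixel_nm
    n_across = max(int(np.ceil(2 * half_w)), 1)
    t = np.linspace(0, seg_len, n_along)
    s = np.linspace(-half_w, half_w, n_across)
    pts = (p0[None, None, :] + t[:, None, None] * u[None, None, :]
           + s[None, :, None] * v[None, None, :])
    vals = map_coordinates(image.data, [pts[..., 1].ravel(), pts[..., 0].ravel()],
                           order=1, mode="constant").reshape(n_along, n_across)
    profile = vals.mean(axis=1)
    pos_nm = t * image.pixel_nm
    if profile.max() <= 0 or np.ptp(profile) < 1e-12:
        fit = GaussianHistFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                              ok=False, degenerate=True)
        return pos_nm, profile, fit
    base = float(profile.min())
    weights = profile - base
    mu0 = float((weights * pos_nm).sum() / weights.sum())
    sig0 = float(np.sqrt((weights * (pos_nm - mu0) ** 2).sum() / weights.sum()))
    p0_fit = [float(profile.max()) - base, mu0,
              max(sig0, image.pixel_nm), base]
    try:
        popt, _ = curve_fit(_gauss, pos_nm, profile, p0=p0_fit, maxfev=2000)
        a, mu, sigma, c = popt
        sigma = abs(float(sigma))
        ss_res = float(np.sum((profile - _gauss(pos_nm, *popt)) ** 2))
        ss_tot = float(np.sum((profile - profile.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        fit = GaussianHistFit(float(mu), sigma, float(a), FWHM_FACTOR * sigma,
                              r2, ok=a > 0)
    except (RuntimeError, ValueError):
        fit = GaussianHistFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    return pos_nm, profile, fit
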