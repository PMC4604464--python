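"""Resolution metrics: label density, Nyquist (labeling-density) resolution
and Fourier ring correlation.

The Nyquist criterion bounds the structural resolution achievable at areal
label density rho by R = 2 / sqrt(rho) (2D); FRC measures the achieved image
resolution from the correlation of two independent half-datasets as a
function of spatial frequency, with the conventional fixed 1/7 threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .geometry import ContourPolyline, point_to_polyline_distance
from .rendering import render

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCResult:
    resolution_nm: float            # inf when the curve never crosses
    frequency_per_nm: np.ndarray
    correlation: np.ndarray
    threshold: float
    resolved: bool

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_per_nm": self.frequency_per_nm,
                             "correlation": self.correlation})


@dataclass
class ResolutionReport:
    n_molecules: int
    density_mean_per_um2: float
    density_median_per_um2: float
    nyquist_mean_nm: float
    nyquist_median_nm: float
    frc_resolution_nm: float
    precision_mean_nm: float
    precision_median_nm: float

    def as_dict(self) -> dict:
        return asdict(self)


def nyquist_resolution(density_per_um2) -> np.ndarray | float:
    """Nyquist structural resolution in nm from an areal density in um^-2:
    R = 2 / sqrt(rho), i.e. 2000 / sqrt(rho per um^2) nm."""
    rho = np.asarray(density_per_um2, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    out = 2000.0 / np.sqrt(rho)
    return float(out) if out.ndim == 0 else out


def label_density(table: pd.DataFrame,
                  regions: list[ContourPolyline] | np.ndarray,
                  band_width_nm: float = 50.0,
                  pixel_nm: float | None = None) -> dict:
    """Molecule density per region in um^-2.

    ``regions`` is either a list of membrane contours (each region is the band
    within ``band_width_nm``/2 of the curve, of area length x band width) or a
    boolean mask (with ``pixel_nm`` giving its pixel size; the whole mask is
    one region).  Returns per-region densities plus mean/median.
    """
    pts = table[["x_nm", "y_nm"]].to_numpy()
    densities = []
    if isinstance(regions, np.ndarray):
        if pixel_nm is None:
            raise ValueError("mask regions need pixel_nm")
        area_um2 = regions.sum() * (pixel_nm ** 2) * 1e-6
        if area_um2 <= 0:
            raise ValueError("region area must be positive")
        ix = np.clip((pts[:, 0] / pixel_nm).astype(int), 0, regions.shape[1] - 1)
        iy = np.clip((pts[:, 1] / pixel_nm).astype(int), 0, regions.shape[0] - 1)
        count = int(regions[iy, ix].sum())
        densities.append(count / area_um2)
    else:
        for curve in regions:
            area_um2 = curve.length * band_width_nm * 1e-6
            if area_um2 <= 0:
                raise ValueError("region area must be positive")
            if len(pts):
                d = point_to_polyline_distance(pts, curve)
                count = int((d <= band_width_nm / 2).sum())
            else:
                count = 0
            densities.append(count / area_um2)
    densities = np.asarray(densities, dtype=float)
    return {"densities_per_um2": densities,
            "mean_per_um2": float(densities.mean()),
            "median_per_um2": float(np.median(densities))}


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

def frc_curve(img1: np.ndarray, img2: np.ndarray, pixel_nm: float,
              smooth_rings: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Ring-averaged correlation of two images as a function of spatial
    frequency (cycles/nm)."""
    if img1.shape != img2.shape:
        raise ValueError("half images must have the same shape")
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    ny, nx = img1.shape
    yy, xx = np.indices((ny, nx))
    r = np.hypot(yy - ny // 2, xx - nx // 2).astype(int)
    n_rings = min(ny, nx) // 2
    num = np.bincount(r.ravel(), weights=(f1 * np.conj(f2)).real.ravel(),
                      minlength=n_rings)[:n_rings]
    d1 = np.bincount(r.ravel(), weights=np.abs(f1).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    d2 = np.bincount(r.ravel(), weights=np.abs(f2).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(d1 * d2)
    frc = np.nan_to_num(frc, nan=0.0)
    if smooth_rings > 1:
        kernel = np.ones(smooth_rings) / smooth_rings
        frc = np.convolve(np.pad(frc, smooth_rings // 2, mode="edge"), kernel,
                          mode="same")[smooth_rings // 2: smooth_rings // 2 + n_rings]
    freq = np.arange(n_rings) / (min(ny, nx) * pixel_nm)
    return freq, frc


def frc_from_images(img1: np.ndarray, img2: np.ndarray, pixel_nm: float,
                    threshold: float = FRC_THRESHOLD) -> FRCResult:
    """Threshold crossing of the FRC curve.  ``resolved`` is False when the
    curve never drops below the threshold within the grid's frequency range
    (the data are indistinguishable down to the grid limit) or when the
    crossing sits at frequencies coarser than a quarter of the field (pure
    noise decorrelates immediately; nothing is actually resolved)."""
    freq, frc = frc_curve(img1, img2, pixel_nm)
    field_limit_nm = min(img1.shape) * pixel_nm / 4.0
    below = np.nonzero(frc[1:] < threshold)[0]
    if len(below) == 0:
        return FRCResult(resolution_nm=np.inf, frequency_per_nm=freq,
                         correlation=frc, threshold=threshold, resolved=False)
    i = below[0] + 1
    f0, f1_ = freq[i - 1], freq[i]
    c0, c1 = frc[i - 1], frc[i]
    fc = f0 + (c0 - threshold) / (c0 - c1) * (f1_ - f0) if c0 != c1 else f1_
    if fc <= 0:
        return FRCResult(resolution_nm=np.inf, frequency_per_nm=freq,
                         correlation=frc, threshold=threshold, resolved=False)
    res_nm = float(1.0 / fc)
    return FRCResult(resolution_nm=res_nm, frequency_per_nm=freq,
                     correlation=frc, threshold=threshold,
                     resolved=res_nm < field_limit_nm)


def frc_resolution(table: pd.DataFrame, pixel_nm: float = 5.0, seed: int = 0,
                   threshold: float = FRC_THRESHOLD,
                   bounds_nm: tuple[float, float, float, float] | None = None
                   ) -> FRCResult:
    """FRC resolution of a localization dataset.

    Molecules are randomly halved; each half is rendered as a plain 2D
    histogram (no precision blur, to avoid double-counting the localization
    uncertainty); the resolution is the inverse frequency where the
    ring-averaged correlation first drops below the threshold.
    """
    if len(table) < 200:
        raise ValueError("FRC needs at least 200 molecules")
    rng = np.random.default_rng(seed)
    mask = rng.permutation(len(table)) % 2 == 0
    if bounds_nm is None:
        pad = 3 * pixel_nm
        bounds_nm = (table["x_nm"].min() - pad, table["x_nm"].max() + pad,
                     table["y_nm"].min() - pad, table["y_nm"].max() + pad)
    im1 = render(table[mask], pixel_nm, blur="none", bounds_nm=bounds_nm)
    im2 = render(table[~mask], pixel_nm, blur="none", bounds_nm=bounds_nm)
    return frc_from_images(im1.data, im2.data, pixel_nm, threshold)


def resolution_report(table: pd.DataFrame, regions, band_width_nm: float = 50.0,
                      mask_pixel_nm: float | None = None,
                      frc_pixel_nm: float = 5.0, seed: int = 0) -> ResolutionReport:
    """Summary of every resolution metric for a reconstructed dataset."""
    dens = label_density(table, regions, band_width_nm=band_width_nm,
                         pixel_nm=mask_pixel_nm)
    try:
        frc = frc_resolution(table, pixel_nm=frc_pixel_nm, seed=seed)
        frc_nm = frc.resolution_nm
    except ValueError:
        frc_nm = np.nan
    prec = table["precision_nm"] if "precision_nm" in table else pd.Series(dtype=float)
    return ResolutionReport(
        n_molecules=len(table),
        density_mean_per_um2=dens["mean_per_um2"],
        density_median_per_um2=dens["median_per_um2"],
        nyquist_mean_nm=float(nyquist_resolution(dens["mean_per_um2"])),
        nyquist_median_nm=float(nyquist_resolution(dens["median_per_um2"])),
        frc_resolution_nm=float(frc_nm),
        precision_mean_nm=float(prec.mean()) if len(prec) else np.nan,
        precision_median_nm=float(prec.median()) if len(prec) else np.nan,
    )
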