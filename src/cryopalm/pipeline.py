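"""End-to-end pipelines: movie -> localization table -> metrics (reconstruct)
and localization table + EM contour -> correlation (correlate)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import ZCalibration
from .drift import DriftTrace, estimate_and_apply_drift, track_fiducials
from .geometry import ContourPolyline
from .localization import add_precision, assign_z, link_trajectories, localize_movie
from .metrics import ResolutionReport, resolution_report
from .registration import (CorrelationResult, align_z, crossvalidate_registration,
                           register_points_to_curve)
from .rendering import RenderedImage, render, split_z_sections


@dataclass
class ReconstructionParams:
    pixel_size_nm: float = 160.0
    gain: float = 1.0
    wavelet_k: float = 3.0
    window_px: int = 9
    link_radius_nm: float = 160.0
    link_max_gap: int = 1
    ellipticity_bounds: tuple[float, float] = (0.5, 2.0)
    drift_smoothing_frames: int = 50
    bead_mask_radius_nm: float = 600.0
    n_z_sections: int = 8
    render_pixel_nm: float = 10.0
    density_band_nm: float = 50.0


@dataclass
class ReconstructionOutput:
    table: pd.DataFrame
    raw_table: pd.DataFrame
    drift: DriftTrace | None
    residual_bead_rms_nm: float | None
    sections: list[RenderedImage]
    section_edges_nm: np.ndarray | None
    report: ResolutionReport | None


def reconstruct_movie(stack: np.ndarray, params: ReconstructionParams,
                      calibration: ZCalibration | None = None,
                      bead_seeds_nm: np.ndarray | None = None,
                      membrane: ContourPolyline | None = None,
                      seed: int = 0) -> ReconstructionOutput:
    """Run detect -> fit -> drift-correct -> link -> z -> precision -> render
    -> metrics on a raw movie.

    Without a calibration the reconstruction is 2D-only (no z assignment or
    z sections).  Bead localizations are removed from the molecule table
    after serving drift correction.
    """
    raw = localize_movie(stack, pixel_size_nm=params.pixel_size_nm,
                         gain=params.gain, k=params.wavelet_k,
                         window_px=params.window_px)
    drift = None
    residual = None
    table = raw
    if bead_seeds_nm is not None and len(bead_seeds_nm) and len(raw):
        seeds = np.atleast_2d(np.asarray(bead_seeds_nm, dtype=float))[:, :2]
        trajectories = track_fiducials(raw, seeds, n_frames=stack.shape[0])
        if trajectories:
            table, drift, residual = estimate_and_apply_drift(
                trajectories, raw, smoothing_window=params.drift_smoothing_frames)
        near_bead = np.zeros(len(table), dtype=bool)
        for s in seeds:
            near_bead |= (np.hypot(table["x_nm"] - s[0], table["y_nm"] - s[1])
                          <= params.bead_mask_radius_nm).to_numpy()
        table = table[~near_bead].reset_index(drop=True)

    table = link_trajectories(table, max_displacement_nm=params.link_radius_nm,
                              max_gap_frames=params.link_max_gap)
    sections: list[RenderedImage] = []
    edges = None
    if calibration is not None and len(table):
        table = assign_z(table, calibration, params.ellipticity_bounds)
        table = table[table["reject_reason"] == ""].reset_index(drop=True)
    table = add_precision(table, params.pixel_size_nm, calibration) if len(table) else table

    report = None
    if len(table) >= 3:
        if calibration is not None and "z_nm" in table and len(table) >= params.n_z_sections:
            parts, edges = split_z_sections(table, params.n_z_sections)
            for part, lo, hi in zip(parts, edges[:-1], edges[1:]):
                if len(part):
                    img = render(part, pixel_nm=params.render_pixel_nm,
                                 z_bounds_nm=(float(lo), float(hi)))
                else:
                    img = RenderedImage(np.zeros((1, 1)), params.render_pixel_nm,
                                        (0.0, 0.0), (float(lo), float(hi)))
                sections.append(img)
        if membrane is not None:
            report = resolution_report(table, [membrane],
                                       band_width_nm=params.density_band_nm, seed=seed)
        else:
            mask, mask_px = occupancy_mask(table)
            report = resolution_report(table, mask, mask_pixel_nm=mask_px, seed=seed)
    return ReconstructionOutput(table=table, raw_table=raw, drift=drift,
                                residual_bead_rms_nm=residual, sections=sections,
                                section_edges_nm=edges, report=report)


def occupancy_mask(table: pd.DataFrame, pixel_nm: float = 50.0,
                   dilate_px: int = 1) -> tuple[np.ndarray, float]:
    """Boolean structure mask from occupied coarse pixels (for label-density
    estimates when no segmented membrane is available)."""
    img = np.zeros((int(table["y_nm"].max() / pixel_nm) + 3,
                    int(table["x_nm"].max() / pixel_nm) + 3), dtype=bool)
    ix = (table["x_nm"] / pixel_nm).astype(int)
    iy = (table["y_nm"] / pixel_nm).astype(int)
    img[iy, ix] = True
    if dilate_px:
        img = ndimage.binary_dilation(img, iterations=dilate_px)
    return img, pixel_nm


def correlate_table(table: pd.DataFrame, contour: ContourPolyline,
                    tomogram_thickness_nm: float | None = None,
                    holdout_fraction: float = 1.0 / 3.0, seed: int = 0,
                    **fit_kwargs) -> tuple[CorrelationResult, dict]:
    """Run the full light->EM correlation: curve registration, 2/3-1/3
    cross-validation and (when z is present) z alignment."""
    result = register_points_to_curve(table, contour, **fit_kwargs)
    cv = crossvalidate_registration(table, contour, holdout_fraction=holdout_fraction,
                                    seed=seed, **fit_kwargs)
    result.crossval_mean_nm = cv["mean_nm"]
    result.crossval_median_nm = cv["median_nm"]
    if tomogram_thickness_nm is not None and "z_nm" in table and table["z_nm"].notna().sum() >= 100:
        zres = align_z(table["z_nm"].to_numpy(), tomogram_thickness_nm)
        result.z_offset_nm = zres["z_offset_nm"]
        result.z_thickness_nm = zres["thickness_nm"]
    return result, cv
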