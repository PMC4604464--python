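"""Ground-truthed synthetic scenes for the whole pipeline.

This module emulates the raw inputs a cryogenic single-molecule localization
(cryo-PALM) experiment on vitreous cryo-sections produces:

* raw movies of blinking membrane-bound emitters imaged through an astigmatic
  (cylindrical-lens) PSF with camera noise, fiducial beads and stage drift;
* membrane-decorating localization sets paired with an EM contour related by a
  known rigid transform, for testing light->EM registration;
* ensemble bleaching/switching traces with bi-exponential kinetics.

Every generator is deterministic given its seed.  Defaults follow the imaging
conditions the package targets: 20 Hz acquisition, ~200 nm section thickness,
and a Dronpa-like photon budget (mean/median 2203/1576 photons per molecule).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .calibration import ZCalibration
from .geometry import ContourPolyline, blob_polyline, circle_polyline
from .transforms import RigidTransform2D

DRONPA_MEAN_PHOTONS = 2203.0
DRONPA_MEDIAN_PHOTONS = 1576.0
SECTION_THICKNESS_NM = 200.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DriftModel:
    """Per-frame stage drift in nm.  ``kind`` is one of none | linear |
    sinusoid | random_walk; the reference (first) frame has zero drift."""

    kind: str = "none"
    rate_nm_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    period_frames: float = 500.0
    step_nm: float = 0.0

    def trace(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        f = np.arange(n_frames)[:, None]
        if self.kind == "none":
            return np.zeros((n_frames, 3))
        if self.kind == "linear":
            return f * np.asarray(self.rate_nm_per_frame)
        if self.kind == "sinusoid":
            return np.asarray(self.amplitude_nm) * np.sin(2 * np.pi * f / self.period_frames)
        if self.kind == "random_walk":
            steps = rng.normal(0.0, self.step_nm, size=(n_frames, 3))
            steps[0] = 0.0
            return np.cumsum(steps, axis=0)
        raise ValueError(f"unknown drift kind {self.kind!r}")


@dataclass
class SceneConfig:
    """Camera/illumination conditions for a simulated movie."""

    field_size_px: int = 32
    pixel_size_nm: float = 160.0     # 16 um camera pixel / 100x objective
    n_frames: int = 2000
    frame_rate_hz: float = 20.0
    photon_mean: float = DRONPA_MEAN_PHOTONS
    photon_median: float = DRONPA_MEDIAN_PHOTONS
    background_ppp: float = 10.0     # photons / pixel / frame
    gain: float = 1.0                # camera counts per photon
    read_noise: float = 1.0          # counts rms
    shot_noise: bool = True
    mean_on_frames: float = 2.0      # mean on-event length in frames; the
                                     # cryogenic Dronpa duty cycle is not
                                     # characterized, so this is a config default
    drift: DriftModel = field(default_factory=DriftModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_size_px < 16:
            raise ValueError("field size must be at least 16 px")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.photon_mean <= 0 or self.photon_median <= 0:
            raise ValueError("photon budgets must be positive")
        if self.photon_mean < self.photon_median:
            raise ValueError("photon mean must be >= median (right-skewed budget)")

    @property
    def field_nm(self) -> float:
        return self.field_size_px * self.pixel_size_nm

    def draw_budgets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Lognormal photon budgets matching the configured mean/median."""
        mu = math.log(self.photon_median)
        sigma = math.sqrt(2.0 * math.log(self.photon_mean / self.photon_median))
        return rng.lognormal(mu, sigma, size=n)


@dataclass
class MovieTruthSpec:
    """Geometry and photophysics of the simulated specimen."""

    geometry: str = "ring"           # ring | cylinder | uniform
    center_nm: tuple[float, float] | None = None
    radius_nm: float = 400.0
    length_nm: float = 1600.0        # cylinder axis extent
    n_emitters: int = 120
    label_jitter_nm: float = 5.0
    section_thickness_nm: float = SECTION_THICKNESS_NM
    always_on: bool = False
    fixed_photons: float | None = None     # overrides the lognormal draw
    fixed_z_nm: float | None = None        # overrides the uniform z draw
    bead_positions_nm: np.ndarray | None = None   # (B, 3); None -> default 3 beads
    n_beads: int = 3
    bead_photons_per_frame: float = 20000.0
    em_transform: RigidTransform2D = field(default_factory=RigidTransform2D)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    emitter_xyz_nm: np.ndarray            # (N, 3)
    photon_budgets: np.ndarray            # (N,)
    events: pd.DataFrame                  # emitter, frame, photons
    bead_xyz_nm: np.ndarray               # (B, 3)
    drift_nm: np.ndarray                  # (F, 3)
    membrane: ContourPolyline | None
    em_transform: RigidTransform2D
    section_thickness_nm: float


# ---------------------------------------------------------------------------
# PSF rendering
# ---------------------------------------------------------------------------

def _add_gaussian_photons(frame: np.ndarray, x_px: float, y_px: float,
                          sx_px: float, sy_px: float, photons: float) -> None:
    """Accumulate a pixel-integrated elliptical Gaussian of total mass
    ``photons`` centred at (x_px, y_px), in place.  Coordinates put the origin
    at the centre of pixel (0, 0); x runs along columns, y along rows."""
    ny, nx = frame.shape
    r = 5.0
    x0 = max(int(np.floor(x_px - r * sx_px)), 0)
    x1 = min(int(np.ceil(x_px + r * sx_px)) + 1, nx)
    y0 = max(int(np.floor(y_px - r * sy_px)), 0)
    y1 = min(int(np.ceil(y_px + r * sy_px)) + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    fx = 0.5 * (erf((xs + 0.5 - x_px) / (np.sqrt(2) * sx_px))
                - erf((xs - 0.5 - x_px) / (np.sqrt(2) * sx_px)))
    fy = 0.5 * (erf((ys + 0.5 - y_px) / (np.sqrt(2) * sy_px))
                - erf((ys - 0.5 - y_px) / (np.sqrt(2) * sy_px)))
    frame[y0:y1, x0:x1] += photons * np.outer(fy, fx)


# ---------------------------------------------------------------------------
# movie simulation
# ---------------------------------------------------------------------------

def _emitter_positions(config: SceneConfig, spec: MovieTruthSpec,
                       rng: np.random.Generator) -> tuple[np.ndarray, ContourPolyline | None]:
    half_t = spec.section_thickness_nm / 2.0
    cx = cy = config.field_nm / 2.0
    if spec.center_nm is not None:
        cx, cy = spec.center_nm
    n = spec.n_emitters
    if n < 1:
        return np.zeros((0, 3)), None
    z = (np.full(n, spec.fixed_z_nm) if spec.fixed_z_nm is not None
         else rng.uniform(-half_t, half_t, n))
    margin = 3 * config.pixel_size_nm
    if spec.geometry == "ring":
        if cx - spec.radius_nm < margin or cx + spec.radius_nm > config.field_nm - margin \
                or cy - spec.radius_nm < margin or cy + spec.radius_nm > config.field_nm - margin:
            raise ValueError("ring geometry does not fit inside the field")
        ang = rng.uniform(0, 2 * np.pi, n)
        xy = np.column_stack([cx + spec.radius_nm * np.cos(ang),
                              cy + spec.radius_nm * np.sin(ang)])
        membrane = circle_polyline((cx, cy), spec.radius_nm)
    elif spec.geometry == "cylinder":
        if spec.radius_nm > config.field_nm / 2 - margin:
            raise ValueError("cylinder geometry does not fit inside the field")
        y = rng.uniform(cy - spec.length_nm / 2, cy + spec.length_nm / 2, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        zc = spec.radius_nm * np.sin(phi)
        keep_half = np.abs(zc) <= half_t
        # resample rejected shell points until all lie inside the section
        while not np.all(keep_half):
            m = ~keep_half
            phi[m] = rng.uniform(0, 2 * np.pi, m.sum())
            zc = spec.radius_nm * np.sin(phi)
            keep_half = np.abs(zc) <= half_t
        xy = np.column_stack([cx + spec.radius_nm * np.cos(phi), y])
        z = zc if spec.fixed_z_nm is None else z
        membrane = None
    elif spec.geometry == "uniform":
        xy = rng.uniform(margin, config.field_nm - margin, (n, 2))
        membrane = None
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    xy = xy + rng.normal(0.0, spec.label_jitter_nm, xy.shape)
    return np.column_stack([xy, z]), membrane


def _blink_schedule(config: SceneConfig, spec: MovieTruthSpec, budgets: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-emitter emission events (emitter, frame, photons).

    Each emitter activates once, at a uniformly random frame, emits its whole
    photon budget spread evenly over a geometric number of consecutive on
    frames (mean ``mean_on_frames``), then photobleaches.  This makes the
    per-molecule total photons of the reconstructed movie follow the
    configured budget distribution directly.  ``always_on`` spreads the
    budget evenly over the whole movie instead (fiducial-like behaviour).
    """
    rows_e, rows_f, rows_p = [], [], []
    F = config.n_frames
    for i, budget in enumerate(budgets):
        if spec.always_on:
            per = budget / F
            rows_e.extend([i] * F)
            rows_f.extend(range(F))
            rows_p.extend([per] * F)
            continue
        n_on = int(rng.geometric(1.0 / config.mean_on_frames))
        f = int(rng.integers(0, F))
        per = budget / n_on
        for k in range(n_on):
            if f + k >= F:
                break          # activation near the end: tail photons are lost
            rows_e.append(i)
            rows_f.append(f + k)
            rows_p.append(per)
    return pd.DataFrame({"emitter": rows_e, "frame": rows_f, "photons": rows_p})


def simulate_movie(config: SceneConfig, spec: MovieTruthSpec,
                   calibration: ZCalibration | None = None
                   ) -> tuple[np.ndarray, GroundTruth]:
    """Render a raw movie (uint16, frames x rows x cols) plus its ground truth.

    Each active emitter contributes a pixel-integrated elliptical Gaussian
    whose per-axis widths follow the astigmatic calibration at the emitter's
    true z.  Fiducial beads are rendered in every frame.  The camera model is
    Poisson shot noise on signal+background, scalar gain, additive Gaussian
    read noise (no EMCCD excess-noise factor).
    """
    cal = calibration or ZCalibration.default()
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_nm
    n = config.field_size_px

    positions, membrane = _emitter_positions(config, spec, rng)
    budgets = config.draw_budgets(len(positions), rng)
    if spec.fixed_photons is not None:
        if spec.fixed_photons <= 0:
            raise ValueError("photon budget must be positive")
        budgets = np.full(len(positions), float(spec.fixed_photons))
    events = _blink_schedule(config, spec, budgets, rng)

    if spec.bead_positions_nm is not None:
        beads = np.asarray(spec.bead_positions_nm, dtype=float)
    elif spec.n_beads > 0:
        off = 2.5 * px
        corners = np.array([[off, off], [config.field_nm - off, off],
                            [off, config.field_nm - off],
                            [config.field_nm - off, config.field_nm - off]])
        beads = np.column_stack([corners[: spec.n_beads],
                                 np.zeros(min(spec.n_beads, 4))])
    else:
        beads = np.zeros((0, 3))

    drift = config.drift.trace(config.n_frames, rng)

    by_frame = {f: g for f, g in events.groupby("frame")} if len(events) else {}
    stack = np.zeros((config.n_frames, n, n), dtype=np.uint16)
    for f in range(config.n_frames):
        frame = np.full((n, n), float(config.background_ppp))
        g = by_frame.get(f)
        if g is not None:
            for i, phot in zip(g["emitter"].to_numpy(), g["photons"].to_numpy()):
                x, y, z = positions[i] + drift[f]
                wx, wy = cal.widths(z)
                _add_gaussian_photons(frame, x / px, y / px,
                                      float(wx) / px, float(wy) / px, phot)
        for b in range(len(beads)):
            x, y, z = beads[b] + drift[f]
            bwx, bwy = cal.widths(z)
            _add_gaussian_photons(frame, x / px, y / px,
                                  float(bwx) / px, float(bwy) / px,
                                  spec.bead_photons_per_frame)
        counts = rng.poisson(frame).astype(float) if config.shot_noise else frame
        counts = counts * config.gain
        if config.read_noise > 0:
            counts = counts + rng.normal(0.0, config.read_noise, counts.shape)
        stack[f] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    truth = GroundTruth(emitter_xyz_nm=positions, photon_budgets=budgets,
                        events=events, bead_xyz_nm=beads, drift_nm=drift,
                        membrane=membrane, em_transform=spec.em_transform,
                        section_thickness_nm=spec.section_thickness_nm)
    return stack, truth


# ---------------------------------------------------------------------------
# membrane / registration fixtures
# ---------------------------------------------------------------------------

def simulate_membrane_scene(radius_nm: float, n_emitters: int, jitter_nm: float,
                            transform: RigidTransform2D | None = None,
                            seed: int = 0, center_nm: tuple[float, float] = (0.0, 0.0),
                            radial_offset_nm: float = 0.0,
                            vertex_spacing_nm: float = 10.0
                            ) -> tuple[pd.DataFrame, ContourPolyline]:
    """Localizations decorating a circular membrane, plus the EM contour.

    The contour lives in the EM frame; emitter points are placed on the circle
    (optionally displaced radially outward by ``radial_offset_nm``, emulating
    the physical label-to-membrane offset), jittered isotropically, then mapped
    into the light frame by the inverse of ``transform`` (which therefore maps
    light -> EM).
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if jitter_nm < 0:
        raise ValueError("jitter must be non-negative")
    if n_emitters < 3:
        raise ValueError("need at least 3 emitters")
    transform = transform or RigidTransform2D()
    rng = np.random.default_rng(seed)
    contour = blob_polyline(center_nm, radius_nm, spacing_nm=vertex_spacing_nm)
    dense = contour.resample(2.0)
    idx = rng.integers(0, len(dense), n_emitters)
    pts = dense[idx]
    if radial_offset_nm != 0.0:
        nxt = dense[(idx + 1) % len(dense)]
        prv = dense[(idx - 1) % len(dense)]
        tangent = nxt - prv
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        outward = np.column_stack([tangent[:, 1], -tangent[:, 0]])
        pts = pts + radial_offset_nm * outward
    pts = pts + rng.normal(0.0, jitter_nm, pts.shape)
    light = transform.inverse().apply(pts)
    table = pd.DataFrame({"x_nm": light[:, 0], "y_nm": light[:, 1]})
    return table, contour


def simulate_multiring_scene(n_rings: int = 6, radius_range_nm: tuple[float, float] = (300.0, 500.0),
                             field_nm: float = 3000.0, density_per_um2: float = 749.0,
                             jitter_nm: float = 13.0, band_width_nm: float | None = None,
                             seed: int = 0
                             ) -> tuple[pd.DataFrame, list[ContourPolyline], float]:
    """A field of membrane cross-sections at a prescribed label density.

    Returns (localization table, contours, band area in um^2).  The molecule
    count is density x band area, where the accounted band extends +/- 2 sigma
    of the transverse label spread about each membrane (the region a density
    measurement over the structure would cover).
    """
    rng = np.random.default_rng(seed)
    if band_width_nm is None:
        band_width_nm = 4.0 * jitter_nm
    contours: list[ContourPolyline] = []
    margin = radius_range_nm[1] + 3 * band_width_nm
    centers = []
    grid = int(np.ceil(np.sqrt(n_rings)))
    cell = field_nm / grid
    k = 0
    for i in range(grid):
        for j in range(grid):
            if k >= n_rings:
                break
            centers.append(((i + 0.5) * cell, (j + 0.5) * cell))
            k += 1
    total_len = 0.0
    for c in centers:
        r = rng.uniform(*radius_range_nm)
        r = min(r, cell / 2 - 2 * band_width_nm)
        contour = circle_polyline(c, r, spacing_nm=10.0)
        contours.append(contour)
        total_len += contour.length
    band_area_um2 = total_len * band_width_nm * 1e-6
    n_pts = int(round(density_per_um2 * band_area_um2))
    # distribute molecules along the curves proportionally to length
    lengths = np.array([c.length for c in contours])
    counts = rng.multinomial(n_pts, lengths / lengths.sum())
    pts = []
    for contour, m in zip(contours, counts):
        dense = contour.resample(2.0)
        idx = rng.integers(0, len(dense), m)
        pts.append(dense[idx] + rng.normal(0.0, jitter_nm, (m, 2)))
    xy = np.vstack(pts) if pts else np.zeros((0, 2))
    table = pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1]})
    return table, contours, band_area_um2


# ---------------------------------------------------------------------------
# photophysics traces
# ---------------------------------------------------------------------------

@dataclass
class DecayTraceSpec:
    """Bi-exponential ensemble bleaching trace parameters.

    Intensity(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + baseline, with
    tau1 < tau2 (fast phase first) and Gaussian sampling noise."""

    A1: float
    tau1_s: float
    A2: float = 0.0
    tau2_s: float = np.inf
    baseline: float = 0.0
    dt_s: float = 0.01
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.A1, self.tau1_s, self.A2, self.baseline, self.dt_s, self.noise):
            if not np.isfinite(v):
                raise ValueError("decay parameters must be finite")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.A2 > 0 and not self.tau1_s < self.tau2_s:
            raise ValueError("fast time constant must be smaller than the slow one")


def simulate_decay(spec: DecayTraceSpec, duration_s: float) -> pd.DataFrame:
    """Sampled decay trace with columns t_s, intensity."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, duration_s, spec.dt_s)
    y = spec.A1 * np.exp(-t / spec.tau1_s) + spec.baseline
    if spec.A2 > 0:
        y = y + spec.A2 * np.exp(-t / spec.tau2_s)
    if spec.noise > 0:
        y = y + rng.normal(0.0, spec.noise, t.shape)
    return pd.DataFrame({"t_s": t, "intensity": y})


def simulate_switching_trace(pulse_times_s, duration_s: float, dt_s: float = 0.05,
                             tau_off_s: float = 1.0, amplitude: float = 1.0,
                             recovery_fractions=None, baseline: float = 0.0,
                             noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Ensemble trace under alternating off-switching and activation pulses.

    The intensity decays exponentially toward ``baseline``; at each activation
    pulse it is reset to baseline + fraction x amplitude (default full
    recovery), emulating reversible photoswitching."""
    rng = np.random.default_rng(seed)
    pulses = sorted(float(p) for p in pulse_times_s)
    if recovery_fractions is None:
        recovery_fractions = [1.0] * len(pulses)
    t = np.arange(0.0, duration_s, dt_s)
    y = np.empty_like(t)
    level = amplitude
    t_last = 0.0
    pi = 0
    for i, ti in enumerate(t):
        while pi < len(pulses) and pulses[pi] <= ti:
            level = level * math.exp(-(pulses[pi] - t_last) / tau_off_s)
            level = recovery_fractions[pi] * amplitude
            t_last = pulses[pi]
            pi += 1
        y[i] = baseline + level * math.exp(-(ti - t_last) / tau_off_s)
    if noise > 0:
        y = y + rng.normal(0.0, noise, y.shape)
    return pd.DataFrame({"t_s": t, "intensity": y})
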