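# Methods

This note documents the models, numerical choices and known limitations of
`cryopalm`.  Everything quantitative here is either a model definition or a
default parameter; measured behaviour is produced by the test suite and
`scripts/acceptance.py`, not restated as fact.

## Imaging model

A movie frame is a field of pixel-integrated elliptical Gaussians on a
constant background.  For an emitter at `(x, y, z)` the per-axis widths
follow the astigmatic (cylindrical-lens) defocus model

    w(z) = w0 * sqrt(1 + u^2 + a3 u^3 + a4 u^4),   u = (z - c) / d

with an independent parameter set per axis.  The default calibration uses
`w0 = 140 nm`, focal offsets `c = -200 / +200 nm` (x/y), depth scale
`d = 300 nm`, no higher-order corrections, and a valid range of ±400 nm.
The astigmatism strength was chosen so that a Dronpa-level photon budget
(~2000 photons) yields an axial precision near 17 nm — i.e. the ~40 nm FWHM
axial resolution reported for real cylindrical-lens cryo-systems — while
keeping the focal PSF (σ ≈ 168 nm at z = 0) consistent with an NA 0.8 air
objective at ~160 nm/pixel (16 µm camera pixels through a 100× objective;
this pixel size is a documented assumption, not a measured value).

The camera applies Poisson shot noise to signal + background, a scalar gain
(counts/photon), and additive Gaussian read noise, then rounds to uint16.
The EMCCD excess-noise factor is deliberately omitted; `SceneConfig` is the
extension point if a √2 noise inflation is wanted.  Because of this omission
the synthetic per-molecule precisions are ~2× better than the cryo
instrument's reported errors at the same photon count, and tests compare
them at order-of-magnitude (same-decade) level only.

## Photophysics model

Photon budgets are lognormal with the mean/median fixed to the Dronpa
single-molecule statistics (2203/1576 photons), which determines the
lognormal σ uniquely.  Each emitter activates once at a uniformly random
frame, emits its budget spread evenly over a geometric number of consecutive
frames (mean 2 at 20 Hz), and then photobleaches.  This single-activation
model makes the per-molecule total photons of a reconstructed movie follow
the configured budget distribution directly, matching the semantics of
per-molecule photon statistics tables.  The cryogenic duty cycle of Dronpa
is not quantitatively characterized, so no re-activation model is attempted
at the movie level; reversible ensemble switching is modeled separately by
the switching-trace generator (exponential off-switching with programmable
405 nm re-activation pulses and per-pulse recovery fractions).

Ensemble bleaching traces are bi-exponential,
`I(t) = A_f exp(-t/tau_f) + A_s exp(-t/tau_s) + c`.  The fitter uses
bounded nonlinear least squares with multi-start initialization (τ pairs
log-spaced over 1–100% of the trace duration), orders components fast-first,
and flags fits with `tau_slow/tau_fast < 1.5` or a vanishing component as
degenerate.  The slow-phase fraction is reported both raw,
`100·A_s/(A_f + A_s)`, and normalized by the initial intensity including the
baseline; published amplitude pairs that sum below 1 are consistent with
either reading at integer rounding.

## Detection and localization

Detection runs an à-trous B3-spline wavelet decomposition (kernel
[1,4,6,4,1]/16, dilated by 2^j) and takes local maxima of the second wavelet
plane above `k = 3` times a robust noise scale.  The noise scale is the
scaled median absolute deviation of the **first** plane, where pixel noise
concentrates — thresholding a plane by its own MAD passes correlated noise
bumps.  Duplicate maxima within ~1 PSF radius (2 px) merge to the brighter.
Saturated frames are flagged, not dropped.

Fitting is a bounded least-squares elliptical Gaussian (pixel-integrated,
axis-aligned, constant background) on a 9×9 px window.  Residuals are
weighted by √(expected counts) taken from a smoothed copy of the window:
unweighted LSQ over-weights the bright centre pixels (~30% efficiency loss),
while weights from the raw data are noise-correlated and bias the fit at low
counts.  Photons = fitted volume / gain.

Linking is greedy nearest-neighbour across frames (radius 160 nm ≈ 1 PSF σ,
gap ≤ 1 frame, ties broken by earlier index); merged records carry
photon-weighted positions/widths, summed photons and their frame span.  The
tracker the original analysis chain used is external MATLAB software, so
this linker is a documented re-implementation choice, as are the linking
radius, gap, wavelet `k` and the ellipticity bounds (0.5–2.0) — none of
which are published values.

z assignment minimizes the distance between measured `(√wx, √wy)` and the
calibration curves over a 2 nm grid with bounded refinement; records outside
the ellipticity bounds or the width envelope (+30% margin) are rejected with
reason codes.  Lateral precision uses the Thompson–Larson–Webb estimator
`s² = σ²/N + a²/(12N) + 8πσ⁴b²/(a²N²)` with `σ = sqrt(wx·wy)` and `b` the
background noise std per pixel; the original study states no formula, so
this standard estimator is a design choice.  Axial precision propagates a
`w/√N` width error through the calibration slope `d(wx − wy)/dz` — a
first-order approximation that degrades near the focal crossing where the
slope is smallest.

## Drift correction

Fiducial beads (always-on, default 20 000 photons/frame) are tracked per
frame from their last known position; beads lost in >20% of frames are
excluded with a warning and gaps are interpolated.  The drift trace is the
bead-averaged displacement from the first (reference) frame, smoothed with a
50-frame moving average, and subtracted from every localization.  The
residual per-axis bead scatter after correction is the stability figure of
merit; laterally it is limited by the per-frame bead localization noise
(~1–2 nm at default brightness), axially by per-frame astigmatic width noise
(~6 nm).  The ~5 nm stability target is asserted per lateral axis because
the corresponding instrument figure is quoted from lateral position
distributions.

## Rendering and resolution metrics

Each molecule renders as a unit-mass Gaussian with FWHM = 2.355 × its
precision, so image mass equals molecule count exactly (stamps are
normalized after truncation at 4σ).  z-sections split `[min z, max z]` into
8 equal bins by default.

Label density is count/area over membrane bands (curve length × band width,
default 50 nm) or over a coarse occupancy mask.  Nyquist resolution is the
2D criterion `R = 2/√ρ`; with ρ in µm⁻², `R[nm] = 2000/√ρ`.  This formula
reproduces both published density→resolution pairs (1850 → 46.5 ≈ 46;
744 → 73.3 ≈ ~74), which is why it was adopted although it is not printed in
the source study; note the median of a per-region Nyquist distribution need
not equal the Nyquist of the median density (Jensen gap), which accounts for
the remaining ~1 nm discrepancy at 744 µm⁻².

FRC splits molecules randomly in half, renders each half as a plain 2D
histogram (no precision blur — blurring both halves identically would
inflate correlation), ring-averages the cross-spectrum, smooths over 3
rings, and crosses the fixed 1/7 threshold.  Results are flagged
"not resolved" when the curve never crosses within the grid's frequency
range or when the crossing implies a resolution coarser than a quarter of
the field (pure-noise behaviour).  Gaussian fits to histograms (z extent,
line profiles) pad the histogram with 25% empty bins per side and omit a
baseline term, since empirical histograms vanish outside the data; fits with
R² < 0.95 should be treated as shape warnings (a uniform slab fitted by a
Gaussian optimizes to FWHM ≈ 0.86 × the slab width, with exactly such a
warning).

## Light→EM registration

Bead-constellation registration (similarity or affine) is delegated to
`skimage.transform.estimate_transform`; each step's RMS residual is its ε,
and the total error budget is the root-sum-of-squares of the three steps —
the independent-error propagation consistent with the narrative total of the
original three-step procedure, whose printed formula survives only as a
figure.

Curve registration minimizes `sum(D_i)`, the summed distances of molecules
to the segmented membrane polyline, over `(dx, dy, θ)` about the molecule
centroid (pivot configurable; the original work does not state one).
Distances are exact point-to-segment minima including the closure segment.
The optimizer is a coarse grid over the bounds (±200 nm, ±10° by default,
9 steps/axis) followed by Nelder-Mead refinements from the five best grid
seeds plus shrinking restarts — the sum of distances is non-smooth at zero
distance and a single simplex run can stall.  A soft penalty keeps the
simplex inside the stated bounds and boundary solutions raise a warning.
Outlier exclusion (default 100 nm; "too far" is unquantified in the source)
is re-evaluated against the current transform and the fit repeated until
the included set stabilizes — the iterative reading of an ambiguous
procedure; a single-pass exclusion typically differs only when outliers are
dense enough to bias the first fit.  Cross-validation fits on a random 2/3
and reports held-out molecule-to-membrane distances.  z alignment fits a
Gaussian to the z histogram: the peak locates the section mid-plane, the
FWHM estimates the section thickness, and agreement with the
tomogram-measured thickness within 30 nm (default slack) is flagged as
consistent.

An exhaustive grid search (1 nm / 0.1° default steps) over a rasterized
Euclidean distance map of the contour serves as an independent optimizer
oracle in the tests; its distance look-ups are accurate to about one raster
pixel (1 nm).

Registration fixtures use a smooth irregular closed contour (low-order
radial harmonics on a circle) rather than a perfect circle: rotation about
the centre of a circle is unidentifiable, and sectioned organelle outlines
are not circular.

## Synthetic-data scope: what passing tests do and do not show

The generators emulate: astigmatic PSF shape vs z, Poisson+read camera
noise, lognormal photon budgets, sparse single-activation blinking, smooth
3D stage drift, always-on fiducials, membrane-bound label geometry with a
radial label offset, and bi-exponential ensemble kinetics.  They do **not**
emulate: EMCCD excess noise or pixel-dependent gain, dipole/vectorial PSF
effects and aberrations beyond astigmatism, structured autofluorescence
background, bead bleaching or vibration spectra, EM segmentation error in
the contour (the contour is exact), sample warping between light and EM
(the true transform is exactly rigid), or photoswitching duty-cycle
structure.  Passing tests therefore validate the analysis chain under its
own model assumptions; they do not certify performance on instrument data,
where model mismatch (especially non-rigid light↔EM deformation and camera
noise) dominates.

Problem sizes were chosen to exercise each property at meaningful statistics
while keeping the default suite fast: 32 px / 2000-frame movies for
end-to-end runs, 400-frame single-emitter movies per photon level for the
precision-scaling law (measured at 2 background photons/px — the
photon-limited regime appropriate to vitreous sections' very low
out-of-focus background; at 10 photons/px the Thompson background term
`∝ 1/N²` itself steepens the 3-point exponent beyond −0.5), 200 noisy
traces for kinetics recovery, and 300-molecule fixtures for registration.

## Known limitations

* The z-assignment inverts widths independently per record; no global
  (spline-PSF or maximum-likelihood) refinement, no multi-emitter fitting —
  overlapping activations on dense structures merge or reject rather than
  resolve.
* Axial precision is a slope-propagation estimate, least reliable near the
  focal crossing and at the range edges.
* The drift smoother (50-frame moving average) attenuates drift components
  with periods below ~2 smoothing windows; fast vibration is out of model.
* FRC on very small fields (< ~1 µm) is dominated by the field-limit flag;
  density-based metrics assume the band/mask actually covers the labeled
  structure.
* `simulate_multiring_scene` defines density over a band of ±2 transverse σ
  around each membrane; density values are only comparable across scenes
  using the same band convention.
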