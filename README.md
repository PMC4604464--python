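# cryopalm

Reconstruction and correlation tools for **cryogenic super-resolution
correlative light and electron microscopy (csCLEM)**: 3D single-molecule
localization microscopy (PALM/STORM) of vitreous cryo-sections, followed by
registration of the localizations onto membranes segmented from cryo-electron
tomograms.

The package is aimed at microscopists and image analysts who need the full
computational chain behind such an experiment without instrument data:

* **`cryopalm.synthetic`** — ground-truthed scene generation: raw movies of
  blinking, membrane-decorating emitters with astigmatic PSFs, camera noise,
  fiducial beads and stage drift; membrane/contour registration fixtures;
  bi-exponential bleaching and photoswitching traces.
* **`cryopalm.detection` / `cryopalm.localization`** — à-trous B3-spline
  wavelet spot detection, background-subtracted elliptical-Gaussian fitting,
  trajectory linking, ellipticity-filtered astigmatic z assignment, and
  Thompson–Larson–Webb precision estimates.
* **`cryopalm.drift`** — post-hoc 3D drift estimation from fiducial-bead
  traces and its subtraction from the localization table.
* **`cryopalm.rendering` / `cryopalm.metrics`** — Gaussian-spot rendering into
  z-sections, line profiles, label density, Nyquist (labeling-density)
  resolution `R = 2/sqrt(rho)`, and Fourier ring correlation (1/7 threshold).
* **`cryopalm.registration`** — fiducial-bead registration with a quadrature
  error budget `eps_total = sqrt(eps_l^2 + eps_le^2 + eps_e^2)`, and rigid
  in-plane registration of molecules onto an EM membrane contour by
  minimizing the summed point-to-curve distances `sum(D_i)` over
  `(dx, dy, theta)` with iterative outlier exclusion, 2/3–1/3
  cross-validation, and z alignment via the peak/FWHM of the z histogram.
* **`cryopalm.photophysics`** — bi-exponential decay fitting
  `I(t) = A_f exp(-t/tau_f) + A_s exp(-t/tau_s) + c`, switching-cycle
  counting, per-protein photon-budget statistics.
* **`cryopalm.cli`** — `cryopalm simulate | reconstruct | correlate |
  photophysics`.

## Worked example

Simulate a mitochondrion-like ring scene with a Dronpa-level photon budget
(mean/median 2203/1576 photons per molecule), reconstruct it, and print the
resolution metrics:

```python
from cryopalm.calibration import ZCalibration
from cryopalm.pipeline import ReconstructionParams, reconstruct_movie
from cryopalm.synthetic import MovieTruthSpec, SceneConfig, simulate_movie

cfg = SceneConfig(field_size_px=32, n_frames=2000, seed=7)
spec = MovieTruthSpec(geometry="ring", radius_nm=400, n_emitters=120)
stack, truth = simulate_movie(cfg, spec)

out = reconstruct_movie(stack, ReconstructionParams(),
                        calibration=ZCalibration.default(),
                        bead_seeds_nm=truth.bead_xyz_nm,
                        membrane=truth.membrane, seed=1)
r = out.report
print(f"{r.n_molecules} molecules, "
      f"density {r.density_mean_per_um2:.0f}/um^2, "
      f"Nyquist {r.nyquist_mean_nm:.1f} nm, "
      f"median precision {r.precision_median_nm:.1f} nm")
```

prints

```
108 molecules, density 852/um^2, Nyquist 68.5 nm, median precision 4.8 nm
```

i.e. the 2000-frame movie yields 108 linked molecules on the 400 nm ring, a
labeling density of ~850 per µm² of membrane band, hence a density-limited
(Nyquist) structural resolution of ~69 nm, with a median per-molecule
localization precision of ~5 nm.  Registering a simulated membrane
localization set back onto its EM contour
(`cryopalm.registration.register_points_to_curve`) recovers an injected
(20 nm, −10 nm, 2°) offset to within (0.3 nm, 0.1 nm, 0.19°).

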