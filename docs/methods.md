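# Methods

This note documents the models, conventions and numerical choices behind
`phasorquant`, and what its synthetic benchmarks do and do not demonstrate.

## Time-domain signal models

A delay scan sweeps the arrival-time difference between two pulse trains
and records the demodulated signal at each delay. Two trace shapes carry
the contrast:

* **SRS (lipid) trace** — stimulated Raman scattering exists only during
  pulse overlap, so the trace is the pulse cross-correlation, modeled as a
  Gaussian `A·exp(−(t−t0)²/2σ²)`. Default σ = 0.25 ps, a typical
  picosecond-laser cross-correlation width.
* **Pigment (pump-probe) trace** — a transient-absorption component that
  decays within the first picosecond plus a photothermal plateau that
  persists over the scan window:
  `sign·(a_ta·e^{−(t−t0)/τ} + a_pt)` for `t ≥ t0`, zero before onset.
  `sign = +1` for eumelanin-like pigment and `−1` for pheomelanin-like
  pigment, which produces a negative-going trace. This
  single-exponential-plus-plateau form is the minimal model reproducing a
  fast decay that settles onto a constant level; no excited-state kinetics
  are modeled. Defaults: a_ta = 0.8, τ = 0.3 ps, a_pt = 0.2 (plateau at
  20% of the onset amplitude).

An optional Gaussian instrument response (σ = `irf_width`) is applied by
discrete convolution with a unit-sum kernel, which preserves the summed
intensity of any trace that decays fully inside the scan window — the
property the phasor transform depends on. `irf_width = 0` bypasses the
convolution exactly.

The decay fitter estimates (a_ta, τ, a_pt) by bounded nonlinear least
squares. The sign is fixed beforehand from the post-onset mean (a free
sign creates a flip degeneracy), and initialisation is deterministic:
plateau from the tail samples, decay amplitude from the peak-to-plateau
excursion, τ from the time the trace crosses 1/e of that excursion. No
random restarts. A fit is reported `converged=False` when the relative
residual exceeds 25%; a post-onset dynamic range at or below the noise
floor raises a no-decay error instead of returning a meaningless τ.

The delay axis default (−1 to +10 ps in 0.1 ps steps) is a configuration
choice, not a measured instrument fact.

## Phasor transform and segmentation

Each pixel's trace `I_k (k = 0..K−1)` maps to
`g = Σ I_k cos(2πnk/K) / Σ I_k`, `s = Σ I_k sin(2πnk/K) / Σ I_k`
with harmonic n = 1 by default. Treating the scan window as one period
makes two identities exact: a constant trace maps to (0, 0) (orthogonality
to DC) and an impulse in the first frame to (1, 0). The transform is
linear in nonnegative mixtures — the phasor of a sum of traces is the
total-intensity-weighted mean of the component phasors — which is what
makes reference-based gating meaningful. The same transform applied along
a wavenumber axis gives the spectral phasor used to separate LD, ER,
cytoplasm and nucleus in hyperspectral stacks.

Segmentation is nearest-reference-centroid in (g, s) with a maximum
assignment radius (default 0.15); pixels beyond every radius become
`other`. Optional polygon gates take precedence over centroid distance.
Ties go to the lower reference index. Two guards precede gating:

* **Intensity floor** — pixels with `|Σ I|` below the floor are
  background; (g, s) is numerically unstable there. The generic default is
  3× the median absolute deviation of the darkest-decile totals; when the
  additive noise level σ of a simulated scene is known, the pipeline uses
  4σ√K (four standard deviations of a pure-noise pixel's summed trace),
  which is the better-calibrated choice at high noise.
* **Sign routing** — strongly negative totals are assigned to the
  pheomelanin-like class before distance gating, because a signed
  denominator makes (g, s) unstable.

Reference centroids are built as intensity-weighted means over user ROIs,
or directly from a scene's own class signal models in simulation; by
linearity a noise-free pure-class ROI lands exactly on the class's
analytic phasor, which is why noise-free rendered scenes segment with
100% pixel accuracy. With the default signal parameters the LD and
pigment centroids are separated by ≈ 0.95 in (g, s), far above the 0.2
separation used as the operational meaning of "well separated".

## Particle quantification

Droplets are 8-connected components of each class in the label map;
components under `min_area` (default 4 px) are dropped. Class area
fractions are percentages of the field area and depend only on the label
geometry; droplet counts and summed C-D channel intensity are divided by
the cell count, which is a supplied input (automatic nucleus counting is
out of scope). Ratiometric ordered/disordered maps mask pixels whose
denominator falls below a floor, and a fully masked map reports its mean
as undefined rather than NaN-propagating.

## Two-sample statistics

`compare_groups` reproduces a normality-gated test choice: Shapiro-Wilk on
each sample at α; if neither is detectably non-Gaussian, a Student's
t-test with a caller-supplied tail, otherwise a one-sided Mann-Whitney U.
No multiple-testing correction is applied, and the tail direction is a
scientific choice the caller must make per comparison. Calibration of the
gate is checked by simulation with 30 observations per group and 2000
replicates: at that size the U statistic's discreteness is negligible and
the empirical type-I error sits within Monte-Carlo error of the nominal
0.05 under both Gaussian and Cauchy nulls (a long-run check at 20 000
replicates gives 0.050 under the Gaussian null). At very small n (≈10 per
group) the exact attainable levels of the U test make such a check
meaningless; that regime is intentionally not used for calibration.

## Raman composition estimation

Peak intensity is the maximum of the spectrum over the band window after
subtracting the straight line through the window endpoints; this is
exactly invariant to global offsets and linear ramps, and an
integrated-area mode is available behind a flag. Substrate background is
removed by fitting a single scale factor to a reference (glass) profile
over analyte-free regions (defaults 600–650 and 1750–1800 cm⁻¹).

Two linear calibrations are fitted by ordinary least squares (intercept
free, not forced through the origin):

* **Unsaturation** — 1654/1445 band ratio against the number of C=C bonds
  per chain, standards at 0, 1, 2 (palmitate-, oleate-, linoleate-like).
* **CE percentage** — 702/1445 ratio against mol% CE, emulsion standards
  at 0–100% in steps of 20. The sterol band is quoted at both 702 and
  704 cm⁻¹ in the literature; the band centre default is 702 cm⁻¹ with a
  ±8 cm⁻¹ window covering both.

Estimates are reported raw and clamped (at 0 for unsaturation, to
[0, 100] for CE) so downstream statistics can choose. A fitted slope ≤ 0
is flagged as a non-increasing calibration and refuses inversion.

## Synthetic data: what it emulates and what it does not

Scenes are fields of non-overlapping cell disks containing disk-shaped
droplets with an enforced edge gap, so rasterised droplets are pairwise
8-disconnected and particle counts/areas have exact ground truth. Default
scene: 128×128 px at 0.5 µm/px, 4 cells, 10 LD + 5 eumelanin-like + 4
pheomelanin-like droplets of radius 2–3.5 px, additive Gaussian noise
σ = 0.02 on a unit peak signal. Hyperspectral scenes reuse the geometry
with nucleus / ER-annulus / cytoplasm regions and distinct C-H-region
band templates per class.

Raman spectra are sums of Gaussian bands (default width σ = 10 cm⁻¹) on a
1 cm⁻¹ grid over 600–1800 cm⁻¹. The 1654 (and optional 3002) amplitudes
are proportional to the mean C=C count, the 702 amplitude to the CE mol
fraction, and the 1445 amplitude is composition-independent per unit
lipid. The amplitude anchors (oleate-like 1654/1445 ratio of 0.4 at one
C=C; 702 amplitude equal to the 1445 amplitude at pure CE) are internal
conventions of realistic magnitude, not measured cross-sections. Because
the bands are well separated, the measured ratio is affine in composition
to better than 1e−6, and the generator exposes the closed-form
slope/intercept of that line (`analytic_calibration`) as an independent
oracle for the fitted calibration.

The spectral noise model has three components: a per-spectrum
multiplicative gain fluctuation (acquisition-to-acquisition laser-power /
focus variation — the dominant multiplicative error in ratio
calibrations, which band ratios are designed to cancel), optional
per-point signal-proportional noise, and additive detector noise. The
noisy-recovery benchmark uses a 2% gain sigma plus an additive floor of
0.002 (peak signal-to-noise ≈ 500, attainable in minute-scale confocal
Raman acquisitions of a droplet). Per-point multiplicative noise at the
percent level is deliberately not the benchmark condition: with a
max-based peak reading, per-point noise at the band top inflates the
ratio error several-fold (the 702 window reads only ~27% of the band
amplitude), and recovery tolerances of a few percent are then
statistically unreachable regardless of implementation — the
`noise_relative` field remains available for studying exactly that
degradation.

Not emulated: optical point-spread blurring, shot-noise statistics
(lock-in outputs are near-Gaussian), melanin excited-state photophysics,
droplet shape irregularity, touching/overlapping droplets, tissue
autofluorescence, and cosmic-ray spikes. Passing benchmarks therefore
demonstrate correctness of the transforms, gating geometry, bookkeeping
and calibration algebra under controlled conditions — not robustness to
every artifact of real acquisitions.

## Benchmark problem sizes

The repeated-measure benchmarks use 20 seeded scenes per condition, 200
seeded spectra per calibration grid, 100 seeded decay fits, and 2000
replicates per null distribution — sizes at which the Monte-Carlo error
of each reported rate is small compared to its tolerance while the whole
suite runs in well under a minute.

## Known limitations

* Phasor gating uses centroids/polygons only; no probabilistic or
  multi-harmonic unmixing of partial-volume pixels.
* The decay fitter assumes a single exponential; multi-exponential
  pigment kinetics would bias τ toward an effective value.
* Cell count is an input; fields where cells cannot be counted reliably
  propagate that uncertainty into per-cell quantities.
* The CE and unsaturation estimators share the 1445 cm⁻¹ normaliser, so
  a corrupted CH₂ band biases both estimates in the same direction.
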