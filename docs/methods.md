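# Methods

This note documents the models, algorithms, parameter choices, and
known limitations of the pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Measurement model and layer separation

A measurement is a Z-stack: planes of W×H pixel spectra (wavenumber in
cm⁻¹, intensity in counts) at focal depths a constant `z_step` apart
(0.5 μm in the reference geometry, 75×75 px over 15×15 μm², 3 cm⁻¹
spectral sampling). The plane with the highest total intensity is
designated Z = 0 (ties break toward the lowest z); depths are
re-expressed relative to it. Planes whose total falls below
`signal_fraction_threshold` (default 0.1) × the Z = 0 total are
excluded as unmeasurably low — the literature gives no number for
"unmeasurably low", so the 10 % cutoff is this package's choice.
Among retained planes, the top `n_upper` (default 1: the endothelium is
a single cell layer, though thickness varies — hence configurable) are
labeled `upper`, all others `lower`; the Z = 0 plane itself counts as
`lower` unless it is the topmost retained plane. Compartment aggregates
(`upper`, `lower`, `all` = every retained plane) are unweighted means
over member planes.

## Preprocessing chain

Order: **despike → baseline → normalize**, applied per pixel spectrum.
Spikes are removed first because a cosmic ray corrupts both the
polynomial fit and the Euclidean norm; pixel-level (not
average-spectrum) preprocessing is used because cosmic rays are
per-pixel events. The band-ratio statistic is scale-invariant, so the
position of normalization relative to integration cannot change R; it
is asserted in the tests.

### Cosmic-ray removal

A channel is flagged when its residual from the running median (window
7 channels) exceeds `threshold` (default 8) × a local scale, and is
replaced by the running-median value; all other channels are returned
bit-identical. The local scale is the windowed median absolute residual
(local MAD) with two floors:

* a machine-epsilon floor, so all-constant spectra never divide by zero;
* `rel_floor` (default 0.05) × the spectrum's robust signal maximum
  (the largest running-median value).

The second floor matters in the low-noise limit: a resolution-limited
real band — phenylalanine at 1007 cm⁻¹ has σ ≈ 4.5 cm⁻¹, i.e. ~3
channels at 3 cm⁻¹ sampling — produces running-median residuals of a
few tenths of the signal scale, while the local MAD tends to zero with
the noise. Without a signal-scale floor such bands would be
misclassified as spikes and clipped. Cosmic-ray spikes exceed the
signal scale (detector physics), so the floor costs no sensitivity:
on 100 seeded phantoms the suite measures >99 % of planted spikes
corrected and ~0 clean channels altered. Setting `rel_floor = 0`
restores the pure MAD criterion.

### Baseline correction

Degree-2 polynomial in the normalized coordinate u ∈ [0, 1].

* `poly2` (fixed dialect): unweighted OLS fit over all channels,
  subtracted. This is an exact linear projection: it annihilates every
  degree ≤ 2 polynomial to machine precision and is idempotent. Being
  unweighted, it also removes the projection of the *signal* itself —
  a known, deterministic distortion of band integrals discussed under
  "recovered percent changes" below.
* `autopoly2` (unfixed dialect): iterative peak-clipped fit. Each round
  the working spectrum is clipped to (current fit + residual standard
  deviation) and the polynomial refit, until the coefficients change by
  < 1e-8 relative or 100 rounds. The spread term prevents the clipping
  from eroding baseline channels below the true baseline; with it, a
  planted degree-2 baseline under a narrow band (<5 % of channels) is
  recovered to ~1e-9 relative in the noiseless limit, and band peak
  heights are preserved. (A plain clip-to-fit iteration converges a few
  percent low — measured during development — which is why the
  dev-aware variant is used.) `autopoly2` is not exactly idempotent
  under noise; idempotence of the chain is asserted for the fixed
  dialect.

### Vector normalization

Each spectrum is divided by the Euclidean norm of its channels inside
the dialect's region (fixed 450–3200 cm⁻¹; unfixed 200–1500 cm⁻¹ —
taken verbatim from the protocol the pipeline reimplements). No mean
centering. A zero in-region norm is an error naming the region and the
(plane, pixel) coordinate.

## Band integration and the ratio

Integrals are plain trapezoids over the dialect window, with linear
interpolation where a window edge falls between channels, and no local
chord subtraction (global baseline correction has already been
applied). R = I(2940)/I(1007) is computed on the per-plane average
spectrum; averaging and integration commute (both linear), asserted to
1e-10.

## Group comparison

The unit of replication is one 3D measurement (stack), matching a
design of several measurements per group across a handful of animals;
animal-level nesting is deliberately not modeled. Per compartment ×
measure: mean, SEM (n−1 sd / √n; absent at n = 1), two-sided two-sample
t-test, percent change, significance at α = 0.05. Welch's variant is
the default (robust to unequal variance at n ≈ 5–6); Student's is
available by flag. At n = 6 vs 5 with truly equal variances Welch is
slightly conservative (true type-I ≈ 0.045 at nominal 0.05) — the
calibration checks therefore assert exact calibration for the Student
variant and non-anticonservatism for Welch. No multiple-testing
correction by default (single-threshold reporting); a Bonferroni flag
exists. Degenerate inputs: both groups constant and equal → (t, p) =
(0, 1); constant and unequal → (±inf, 0), logged.

## The phantom

Each pixel spectrum is

```
a(z) · Σ_c conc_c(layer, condition) · S_c(ν)  +  c₀ + c₁u + c₂u²  +  ε  +  spikes
```

* **Component spectra** `S_c`: sums of Gaussian bands. Lipid: 2881
  (shoulder), 2940, 2968, 1660, 1452 cm⁻¹; protein: 2940, 2968, 3053,
  1660, 1452, 1007 cm⁻¹; water (unfixed only): a broad 3300 cm⁻¹ band,
  with amide I broadened (σ 11 → 17 cm⁻¹) in the aqueous dialect.
  There is deliberately **no band at 3005 cm⁻¹** (no unsaturated-lipid
  =CH stretch), asserted in the tests. Line shape is Gaussian and
  widths are chosen so the 2800–3100 cm⁻¹ region forms one broad
  envelope with a 2881 shoulder.
* **Layers**: media from −0.3 to 0.75 μm (lipid 0.70, protein 1.05),
  endothelium from 0.75 to 1.3 μm (lipid 1.55, protein 0.55) — the
  topmost 0.5 μm slab, i.e. exactly one plane at the default 3-plane,
  0.5 μm-step geometry. Concentrations are arbitrary units; no absolute
  intensities are published for this protocol, so amplitudes and
  compositions are chosen for testability: the control endothelium's
  ratio exceeds the media's by ≈ 2.7×, and the CH envelope is
  lipid-dominated in the endothelium (see below). A z outside every
  layer renders baseline + noise only.
* **Metastasis condition**: endothelial protein × 1.18 (+18 %) and
  lipid × 0.96 (−4 %) by default; the media is untouched. The ground
  truth records exactly 100 × (factor − 1).
* **Depth attenuation** `a(z) = exp(−|z − focus|/scale)` with focus at
  z = 0 (in the media) and scale 1.0 μm (≈ a confocal axial response);
  with this scale the attenuation dominates the layers' different raw
  spectral masses, so plane totals decrease monotonically away from the
  focus and Z = 0 designation lands in the media.
* **Baseline**: degree-2 coefficients drawn uniformly per pixel from
  configurable ranges (defaults c₀ ∈ [0.1, 0.3], c₁ ∈ [−0.2, 0.2],
  c₂ ∈ [0, 0.4] in u-coordinates — a smooth fluorescence-like
  background of order 10 % of the signal peak).
* **Noise**: additive Gaussian, sd 0.05 counts (signal peak ≈ 2), i.e.
  peak SNR ≈ 40 — plausible for sub-second confocal acquisition.
  Additive Gaussian rather than Poisson because the pipeline nowhere
  assumes a noise family and the tests need exact seed-reproducible
  noise arithmetic.
* **Spikes**: at most one per spectrum (probability 0.01), a
  single-channel +5-count delta — width 1 because despiking targets
  isolated channels. Coordinates, the pre-spike data, per-pixel
  baseline coefficients, and the noiseless mixture per plane are all
  recorded in the ground truth.

Everything is deterministic given (config, condition, seed), asserted
bitwise; with unit factors the metastasis stack is bitwise identical to
the control.

### What the phantom does *not* emulate

No optical PSF beyond the scalar depth factor, no surface roughness or
layer-thickness variation across the field, no inter-animal biological
variability (replicate stacks differ only by noise, baseline draws, and
spikes), no Poisson statistics, no detector etaloning or wavenumber
miscalibration. Passing tests therefore demonstrate that the *pipeline*
is correct and calibrated under its stated model — not that real-tissue
effect sizes would be recovered with the same accuracy.

## Recovered percent changes: known coupling

The pipeline measures band integrals on vector-normalized,
baseline-corrected spectra. Two deterministic effects couple a planted
concentration change into the measured percent change:

1. **Normalization coupling.** Raising endothelial protein by +18 %
   also raises the in-region norm (the CH envelope contains protein),
   shrinking the normalized 1007 cm⁻¹ integral. With the default
   composition (CH envelope lipid-dominated in the endothelium) the net
   recovery is ≈ +16.5 to +17 instead of +18 — a ~1.3-point bias,
   reported as-is by the acceptance script.
2. **Window mixing.** The 2940 cm⁻¹ window integrates lipid *and*
   protein CH stretches, so a planted −4 % lipid factor together with a
   +18 % protein factor produces a near-zero change of that window's
   integral. The CH-window change is thus not an estimator of the
   lipid factor alone; sign conventions are validated with
   single-factor planted effects instead.

The media compartment carries no planted effect and its recovered
change is ≈ 0 (|bias| ≪ 1 point), which is the structural point: the
composition change is confined to the endothelium.

## Simulation sizes

Scaled-down problem sizes keep the full suite and the acceptance script
at a few minutes on one CPU; all statistics are per-stack averages, so
pixel-grid size affects only noise levels, not estimands.

| check | size |
|---|---|
| despiking fidelity | 100 phantoms, 8×8 px × 2 planes, spike rate 0.02 |
| baseline recovery | 20 planted quadratics + narrow band, 918 channels |
| planted-effect recovery | 50 control/metastasis pairs, 12×12 px × 3 planes, default noise |
| null calibration | 10,000 replicates × (6 + 5) stacks, 1×2 px × 2 planes |
| structural fidelity | noiseless 4×4 px × 3 planes |

The null calibration runs through a batched harness
(`ramanstack.calibration`) that executes the identical generator and
per-spectrum preprocessing code as the stack-at-a-time pipeline;
exact agreement between the two routes is itself a test.

## Numerical choices

* In-memory wavenumber axes are always ascending; descending on-disk
  axes are reversed on read. All windows are [lo, hi] regardless of
  acquisition order.
* The default fixed-dialect axis is 449–3200 cm⁻¹ in 3 cm⁻¹ steps:
  the grid must reach 3200 exactly for the 450–3200 normalization
  region to lie within the axis.
* Cube TSVs are written with 17 significant digits (float64
  round-trips exactly; the reader is asserted to 1e-12 relative).
* Baseline polynomials use the basis 1, u, u² with u the axis mapped to
  [0, 1] (conditioning); convergence tolerance 1e-8 relative on
  coefficients, max 100 iterations.
* Z = 0 ties break toward the lowest z; `argmax` guarantees it.
* All randomness flows from a single top-level seed via
  `numpy.random.SeedSequence` spawning, so stages and individual stacks
  are reproducible in isolation.

## Limitations

* The fixed-dialect `poly2` baseline is an unweighted OLS fit and
  therefore subtracts part of the signal's own quadratic component — a
  deterministic, condition-independent distortion that cancels in
  comparisons but biases absolute integrals. It is kept because it is
  the stated protocol for fixed tissue; `autopoly2` can be selected per
  configuration when absolute integrals matter.
* Percent-change recovery is exact only up to the normalization
  coupling above; for the unfixed dialect (normalization region
  200–1500 cm⁻¹, which excludes the CH envelope but contains the
  protein fingerprint bands) the coupling is larger.
* The group comparison treats stacks as independent; nested
  animal/measurement designs are out of scope.
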