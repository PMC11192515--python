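# Methods

`fpvstag` implements the analysis chain used to quantify and test neural
discrimination responses in fast-periodic-visual-stimulation (FPVS) oddball
designs, together with a synthetic data generator that reproduces the
statistical structure the chain assumes. This note documents the models,
the defaults and the reasoning behind the open design choices.

## The paradigm and the response definition

Stimuli are presented by sinusoidal contrast modulation at a base rate
`f_base` (default 6 Hz, one stimulus per 166.66 ms cycle). In experimental
sequences two stimulus categories alternate (XYXY…), so one category recurs
at the oddball rate `f_odd = f_base / 2` (3 Hz, every 333.33 ms); baseline
sequences draw every token from a single category. A trial is 160 base
cycles — exactly 160/6 = 26.666… s, conventionally printed as 26.7 s. A
periodic neural response that distinguishes the two categories concentrates
at `f_odd` and its harmonics; general visual entrainment concentrates at
`f_base` and its harmonics.

The response of interest is the **baseline-corrected amplitude at the
oddball frequency**: trials within a condition are averaged coherently, the
average is Fourier-transformed, each frequency bin is corrected against its
surrounding bins, and the corrected amplitude at the 3 Hz bin is read out
per sensor. The discrimination question is whether this quantity is larger
in the experimental condition than in its baseline, across subjects.

### Bin alignment

All of this presumes the tagged frequencies fall exactly on FFT bins. The
epoch length is therefore defined as `n_cycles / f_base` seconds exactly
(frequency resolution 6/160 = 0.0375 Hz; the reciprocal of the rounded
duration, 1/26.7 = 0.0374 Hz, is the conventionally printed value), and the
sampling rate must make that an integer number of samples — which is why
the default simulation rates are 1200 Hz and 300 Hz rather than 1000/250:
at 1000 Hz, 26.666… s is not an integer sample count, and a misaligned
grid leaks the tagged energy across bins and breaks the single-bin response
definition. `extract_response` refuses targets farther than half a bin from
the grid rather than silently interpolating.

## Synthetic data generator

Each epoch is a sum of three parts:

1. **Base response** — sinusoids at configured harmonics of `f_base`,
   amplitudes in arbitrary field units (default harmonic 1, amplitude 1.0).
2. **Oddball response** (experimental condition only) — sinusoids at
   harmonics of `f_odd` *excluding* those coinciding with base harmonics
   (even oddball harmonics when the rate ratio is 2); coincident terms are
   unidentifiable and dropped with a warning. Default harmonic 1,
   amplitude 0.5.
3. **1/f^β noise** — Gaussian noise shaped in the frequency domain by
   `|H(f)| ∝ f^(−β/2)` (β default 1, the canonical resting MEG spectrum),
   normalized so the expected time-domain standard deviation equals
   `noise_sigma` (default 1.0) exactly.

Both responses are weighted spatially by unit-peak Gaussian profiles
`exp(−d²/2w²)` of great-circle distance `d` from a center sensor (width
default 0.04 m), producing the spatially smooth, contiguous effects that
cluster-based tests are designed for. Phases are drawn uniformly once per
run and shared across subjects and trials — amplitude spectra are
phase-invariant, and fixed phases keep coherent trial averaging lossless.
Per-subject gains are lognormal with mean 1 and coefficient of variation
`subject_cv` (default 0.2, a typical between-subject amplitude spread;
lognormal keeps gains positive). Every draw descends deterministically from
the run seed, and the cohort manifest records each drawn parameter.

The default sensor layout mimics a 306-channel helmet: 102 sites on a
Fibonacci lattice over a 9.5 cm hemisphere, each holding one magnetometer
and two planar gradiometers sharing a `pair_id`. The generator emits
unitless fields; sensor kind only matters for planar pair combination and
for keeping adjacency within one kind.

What the generator does **not** emulate: forward-modelled source-to-sensor
physics (gradiometers and magnetometers see the same fields), contrast
response nonlinearities and harmonic cross-talk, artifacts (blinks,
cardiac, movement), and non-stationary noise. Passing tests therefore show
that the analysis chain is correct and calibrated for
sinusoid-plus-1/f-noise data with smooth topographies — not that any
particular real-data effect will replicate.

## Spectral quantification

* FFT normalization is `2|X_k|/N` for k > 0, so a bin-aligned sinusoid of
  amplitude A reads exactly A at its bin and simulator amplitudes are
  directly recoverable.
* **Baseline correction**: for each bin, take the 12 nearest bins per side,
  skip the 1 immediately adjacent per side, pool the 22 candidates, drop
  the single largest and single smallest, and subtract the mean of the
  remaining 20. "Local minima and maxima" are read as the single pooled
  extremes: dropping *all* local extrema of a noisy vector would discard
  roughly half the candidates. All counts are configurable
  (`BaselineCorrectionConfig`), so the alternative reading (10 bins per
  side with exclusions inside the window) is one configuration away.
  Edge bins without a full two-sided window are marked undefined rather
  than corrected asymmetrically; the 3 Hz bin of a trial-length epoch is
  never near an edge.
* **Planar gradiometer pairs** are combined by root-sum-of-squares per bin,
  the standard Pythagorean combination of two orthogonal planar gradients.
* Trial averaging precedes the FFT (coherent averaging). An incoherent
  mode (average per-trial amplitude spectra) exists but is off by default;
  it does not benefit from phase-locked noise cancellation.
* Band-pass filtering (zero-phase Butterworth, order 8, default
  0.1–100 Hz) and integer-factor decimation (zero-phase FIR anti-alias)
  are available for imported data; the generator's band-limited output
  does not need them, so the default pipeline samples at 300 Hz directly.

### A known small bias

Amplitude-domain baseline correction subtracts the *mean amplitude* of the
neighbour bins — for pure noise a Rayleigh-distributed quantity with
positive mean — while a high-SNR signal bin carries the signal amplitude
plus a vanishing `σ²/2A` term rather than the additive noise floor. The
corrected response therefore underestimates the injected amplitude by
roughly the Rayleigh mean of the per-bin noise (about 1.25 σ_bin, i.e. one
replicate standard deviation; ~4% of the injected amplitude at the
simulation defaults). The bias scales with the noise floor exactly as the
replicate-to-replicate scatter does, so it is invisible at the single-
measurement level but detectable by averaging many replicates. This is a
property of the estimator as defined, not of the implementation; the
experimental-vs-baseline *contrast* that the inference stage tests is
unaffected under the null (both conditions share the floor).

## Statistical assessment

* **Paired cluster permutation test.** Node-wise paired t values (df =
  n − 1) above the one-tailed critical value at `cluster_forming_alpha`
  (default 0.05 — the ecosystem-standard choice; the threshold is
  configurable) are grouped into connected components of the adjacency
  graph; each component's mass (sum of member t values) is referred to the
  permutation null of the *maximum* cluster mass under per-subject sign
  flips of the difference maps — the exact exchangeability scheme for a
  paired design under H0. Monte Carlo p values use
  `(1 + #{null ≥ observed}) / (1 + n_permutations)` (never exactly zero);
  when `n_permutations ≥ 2^n` the engine switches to exhaustive
  enumeration of all sign assignments with `p = #{null ≥ observed} / 2^n`.
  The identity assignment's null entry is pinned to the observed maximum
  statistic (they are equal by definition; recomputing it through a
  different float summation path can otherwise lose the tie by one ulp).
  Cluster mass is the default statistic; cluster size is selectable.
* **Adjacency** is a plain distance threshold (edge iff Euclidean distance
  ≤ `max_dist`), built within one sensor kind at a time. The threshold is
  a free parameter: for real helmet layouts a few millimetres is typical,
  while the synthetic Fibonacci layout has ~24 mm site spacing, so the
  default pipeline uses 0.03 m to connect neighbouring sites.
* **Hedges g** = (mean/SD) × J(n−1) with J(ν) = 1 − 3/(4ν−1), computed on
  per-subject differences averaged over a cluster's members. The 95% CI
  inverts the noncentral-t distribution of the one-sample t statistic
  (a seeded percentile bootstrap is the configurable alternative).
* **JZS Bayes factor** for the paired t statistic: Cauchy(0, r) prior on
  the standardized effect (r default 0.707), BF10 evaluated as the ratio
  of the noncentral-t likelihood mixed over the prior to the central-t
  null likelihood, by adaptive quadrature; integration failure raises
  rather than degrading silently. Evidence classification uses the
  conventional thresholds — BF10 < 1/3 moderate evidence for the null,
  BF10 > 3 for the alternative, boundary values inconclusive — and
  `tabulate_evidence` counts nodes per class per region of interest.

`FPVSContrast` packages one experimental-vs-baseline comparison as a model
object; `fit()` returns a `ContrastResults` carrying the clusters, their
effect sizes, the per-node Bayes factor map and a `summary()` table.

## Pipeline and reproducibility

`run_experiment` replays the full design for a set of named contrasts
(default five, mirroring a five-property linguistic design in the abstract:
each contrast is an experimental/baseline condition pair with its own
oddball amplitude multiplier). Defaults are 21 subjects, 6 trials per
condition, 102-site layout, magnetometer analysis, 5000 permutations.
Every stage's seed descends from the master seed via seed-sequence
spawning, the run manifest records the config hash, stage seeds and a
SHA-256 checksum of every written file, and identical master seeds
reproduce the output tree byte for byte.

## Problem sizes in the validation suite

The test suite and the acceptance script exercise the same machinery at
desk scale, chosen so the full run stays interactive: calibration suites
use an 8-site layout, 12 subjects, one trial per condition, 60 Hz sampling
with base-harmonic-only content, 500 null cohorts at 500 permutations;
amplitude-recovery suites use 120 Hz sampling and 50 replicates; pipeline
demonstrations use 8 subjects, 2 trials and 200–500 permutations. These
sizes are the package's own validation choices; the analysis defaults
(5000 permutations, 21 subjects) remain the study-scale values.

## Limitations

* The generator's additive sinusoid model has no trial-to-trial amplitude
  or latency jitter beyond the noise term.
* Source-space analysis is supported only abstractly: cluster tests and
  Bayes maps run on any user-supplied vertex coordinate set/graph; no
  forward modelling or anatomical atlas is included.
* Only the one-tailed "greater" paired design is implemented, matching the
  directional discrimination hypothesis.
* The surrounding-bin correction is a local detrender; it assumes the
  noise floor varies smoothly over ~±0.45 Hz and will over-subtract near
  spectral edges of width comparable to the candidate window.
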