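# Methods

This note documents the models and procedures implemented in `gryllometry`,
the parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate.

## Input model and quality control

A recording is a DeepLabCut-dialect pose table: one row per frame at a fixed
interval (default 1 min), six bodyparts, each with image-pixel coordinates
(origin top-left, y downward) and a network confidence (*likelihood*) in
[0, 1]. Analyses work in Zeitgeber Time (ZT): ZT0 = lights-on, ZT12 =
lights-off for the default LD 12:12 photoperiod (720 + 720 min).

**Likelihood filter.** A coordinate pair is treated as missing when its
likelihood is strictly below the threshold (default 0.95); a value exactly at
the threshold is retained. The QC report gives per-bodypart retention
fractions overall and split by phase, because infrared-illuminated dark-phase
frames are systematically harder to label.

**Imputation.** Missing runs are filled with the *flanking mean*: every
frame of a maximal missing run receives the arithmetic mean of the nearest
valid coordinate before and after the run (a constant fill per run). Runs
touching either end of the recording take the single nearest valid value.
Linear interpolation across runs is available as an explicit option
(`method="linear"`), and behaves identically for single-frame gaps.
Likelihood values are never modified; imputed frames are tracked in a
boolean mask. The filter→impute composition is idempotent.

Imputed coordinates are used by the displacement classifiers (which need a
gap-free series) but excluded from posture statistics (a filled-in
coordinate carries no shape information). Both behaviours can be overridden.

## Behaviour definitions

All displacement rules act on consecutive frame pairs, i.e. 1-minute
displacements at the default frame rate:

| quantity | rule | boundary |
|---|---|---|
| body length `L` | median head↔abdominal-tip distance over non-imputed frames | — |
| locomotion | abdomen displacement `≥ L` | inclusive |
| immobility | abdomen displacement `< 3 px` | strict |
| SLS | maximal immobile run `≥ 5` pairs | inclusive |
| feeding | head inside the active feeding area | boundary-inclusive |

The body length is a per-animal constant (the median is robust to transient
mislabels); a per-frame mode is not provided because single-frame mislabels
would leak directly into the threshold. The `3 px` / `5 min` SLS parameters
are exposed (`disp_threshold`, `min_frames`). The immobility *run length* at
a frame is the number of consecutive immobile pairs ending there; it resets
to zero after any mobile pair.

Feeding areas are axis-aligned rectangles (polygons supported) attached to
time segments, because the arena — and with it the feeding-area
coordinates — can shift when food is replenished. Segments must jointly
cover the recording span; a frame outside every segment is a configuration
error, not silently non-feeding.

## Posture

The hind-leg opening angle is the unsigned planar angle at the abdomen
vertex between the two hind-leg keypoints, in [0°, 180°] (the cosine is
clamped before `arccos`; top-down symmetric geometry makes reflex angles
meaningless). It is invariant to translation, rotation and uniform scaling.

The per-animal angle distribution over the whole recording is trimmed at the
2.5th/97.5th linear-interpolation percentiles — extreme openings mostly
reflect grooming-like postures — and checked with Shapiro–Wilk,
Kolmogorov–Smirnov (against a normal with the sample moments) and a Q-Q
plot. The tests are diagnostic only; no branching to non-parametric
procedures occurs.

Two couplings with the sleep-like state are computed:

1. hourly mean angle (trimmed) regressed on hourly mean SLS count over the
   24 ZT-hour points;
2. mean angle per current immobility duration d = 0…20 min, with durations
   above 20 pooled into the top bin (a drop mode exists), regressed on d.

**Trimming bias.** The global lower 2.5% trim removes, by construction, the
lowest angles — which under a relaxation process are concentrated in the
longest-immobility bins. On simulated data with a known 1.5°/min relaxation
this attenuates the fitted slope to about −1.2°/min. The Fig-style analyses
therefore keep the trim (it is part of the procedure), while parameter
recovery of the relaxation rate is assessed on the untrimmed series, where
the slope CI covers the generator value.

## Rhythm analysis

**Slot averaging.** Event counts are summed per ZT slot (24 hourly or two
12-h slots) within each day, then averaged across days. Series must start at
ZT0 and span whole days unless truncation is requested explicitly.

**Chi-square periodogram** (Sokolove–Bushell). For integer candidate period
`P`, the first `K·P` samples (`K = ⌊N/P⌋`) are folded into a `K×P` array
with column means `M_h`, grand mean `M̄` and population variance `s²`; then
`Q_P = K Σ_h (M_h − M̄)² / s²`, compared with the `χ²` quantile at `P − 1`
degrees of freedom. The scan is 1200–1680 min at 1-min steps by default,
bracketing 24 h as is customary for checking LD 12:12 entrainment.
Significance across the scan uses a Bonferroni-corrected α by default
(measured family-wise false-positive rate 0.025 at nominal 0.05 over
white-noise replicates); a `pointwise` mode reproduces the classic
single-period test of actogram software. The peak is the maximal `Q_P` among
significant periods.

**Lomb–Scargle periodogram.** Classical normalized power `z = P_LS/s²` with
mean subtraction, evaluated by an exact vectorised implementation of the
phase-offset (τ) formulation (verified against `scipy.signal.lombscargle`
to machine precision and against the DFT periodogram on evenly sampled
sinusoids). The peak's false-alarm probability is `1 − (1 − e^{−z})^M` with
`M` the number of scanned frequencies. This correction assumes roughly
independent frequencies (spacing of order `1/T`): it is exact on
Fourier-spaced grids — where the measured false-alarm rate is 0.04 at
α = 0.05 — and conservative on the default finely oversampled period grid,
which contains only ≈5 independent frequencies among 481 scanned.

**Peak localisation precision.** For a 14-day record the frequency
resolution corresponds to a period width of `P²/T ≈ 103 min` around 24 h.
With the stochastic activity levels the simulator produces, the noise-driven
displacement of the periodogram argmax within that lobe has a standard
deviation of a few minutes (measured: chi-square peaks 1438–1440,
Lomb–Scargle 1439–1443 across seeds). Peaks should therefore be read as
"≈1440 min", not as minute-exact period estimates; tests assert localisation
within 1% of 24 h.

**Acrophase.** Each minute's event count is a unit vector at angle
`2π·ZT/1440`; the acrophase is the direction of the count-weighted resultant
(the standard vector method of circular statistics), with resultant length
`r` as a concentration measure; `r ≈ 0` (uniform events) is reported as
undefined rather than returning an arbitrary phase. Per-day acrophases and
their unweighted circular mean are also reported.

**Light/dark contrast.** Two-sample pooled-variance Student's t-test of the
daily dark-phase totals against the daily light-phase totals (n = days per
phase, within one animal), two-sided. The day-within-animal unit of
replication is a deliberate choice; comparing animals instead is possible by
applying the test to per-animal means.

## Synthetic recordings

The generator is a time-inhomogeneous Markov chain over four states
(active / locomote / quiescent / feed), stepped once per minute:

| parameter | default | rationale |
|---|---|---|
| days, frame interval | 14 d, 1 min | recording design being emulated |
| photoperiod | LD 12:12 | idem |
| arena | 735 × 490 px | 150 × 100 mm case at ≈4.9 px/mm |
| body length | 147 px | ≈30 mm cricket at that scale |
| keypoint noise | 1 px (σ, isotropic) | order of a trained network's test error |
| p(locomote) | 0.30 dark / 0.03 light | nocturnal, 10:1 |
| p(quiescent entry) | 0.12 light / 0.03 dark | light-phase sleep-like state |
| quiescent bout mean | 10 min (geometric) | insect sleep-bout scale |
| feed entry / stay | 0.002 / 0.8 (×4 within ±2 h of transitions) | feeding peaks at light/dark transitions |
| dropout | 3% light / 10% dark per keypoint | dark-phase labelling is worse |
| angle model | 130° − 1.5°/min·min(d, 20), σ = 10° | hind-leg relaxation with immobility |

Locomotion is an unconditional per-minute arousal event that can interrupt
quiescent or feeding bouts, so the realised per-minute locomotion rate
equals `p(locomote)` in each phase and the generator's nominal 10:1
dark/light ratio is the ground truth the pipeline is asked to recover.
Quiescent minutes jitter the abdomen by σ = 0.4 px; feeding minutes jitter
by σ = 2.5 px around an anchor inside the feeding area (pecking
micro-movements — a feeding animal is stationary in place but not immobile
at the 3-px scale). Locomote steps jump 1.05–1.6 body lengths with
direction resampling away from walls. The six keypoints are laid out as a
rigid template along a heading vector, with the hind legs opened at the
state-dependent angle, then pixel noise is added and likelihoods are drawn
(`U[0.95, 1)` normally, `U[0.3, 0.95)` on dropout).

**What passing tests show, and what they do not.** The simulator reproduces
the *structure* of a real recording — LD-driven rhythms, phase-dependent
behaviour rates, dropout asymmetry, posture–immobility coupling — so
recovery tests demonstrate that the pipeline measures what the definitions
say, at realistic noise levels. It does not emulate temporally correlated
network errors, occlusion-driven (position-dependent) dropout, anticipatory
activity before lights-off, the late-dark-phase SLS peak seen in real
crickets, grooming/courtship micro-behaviours, or inter-individual
variability. Classifier-fidelity results on synthetic data are therefore
upper bounds on real-data performance.

Known quantitative biases at the default conditions: dark-phase dropout plus
imputation halves the apparent displacement of jumps adjacent to missing
frames, depressing the measured dark/light locomotion ratio by ≈10–15%
(measured 8.0–8.8 vs 10 nominal, within the 25% recovery band); keypoint
noise fragments immobile runs (the per-minute displacement noise is ≈1.4 px
at 1 px keypoint noise, against a 3 px threshold), so detected SLS
undercounts true SLS pairs at 1 px noise (per-pair recall ≈0.7, precision
≈1.0; both ≥0.98 at 0.5 px noise). The undercount is phase-symmetric and
leaves the light/dark contrast and the 24-h periodicity intact.

## Numerical choices and degenerate inputs

* Percentiles use linear interpolation; ties at a percentile are retained
  (trim comparisons are strict).
* The arccos argument is clamped to [−1, 1]; a zero-length leg vector is a
  degenerate-geometry error for the scalar API and an undefined (NaN) angle
  in the vectorised series.
* Constant series are rejected by both periodograms (zero variance); a
  constant angle sample is reported as a degenerate normality result rather
  than raising.
* The light/dark t-test returns `t = 0, p = 1` when both phases have zero
  variance and equal means, and raises otherwise-undefined cases.
* Event series must be non-negative and, for slot averaging, start at ZT0
  and span whole days (explicit truncation otherwise).
* Problem sizes in the test-suite simulations: full 14-day recordings
  (20,160 frames) for recovery tests; 200 replicates for Monte-Carlo
  calibration checks; 2–3-day recordings for structural and CLI tests.
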