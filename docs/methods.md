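# Methods

This note documents the models, estimator conventions and numerical
choices behind `cuedpain`, and what the synthetic-data validation does
and does not establish about real recordings.

## Design model

The experiment crosses six equally frequent cues (2 modalities × 3
intensities) with six stimulus classes. Cue validity is modelled with two
independent probabilities: the cued modality is delivered with probability
`p_modality_valid` (default 0.70) and the cued intensity level with
probability `p_intensity_valid` (default 0.60); invalid intensity mass is
split equally between the two other levels, and invalid-modality trials
keep the cued intensity distribution in the other modality. This is the
unique minimal completion of the two stated marginals under the row-sum
constraint (each cue row totals 1/6); the exact within-row distribution of
invalid trials is an independence assumption, not an observed quantity.

Integer trial counts come from largest-remainder rounding of the cell
probabilities within each cue row over the session, then a least-loaded
split across blocks so every block holds exactly `trials_per_block`
non-catch trials with equal cue frequencies. Every cell count is within
one trial of probability × session length. Note a consequence: rounding
is deterministic, so aggregate derived counts (e.g. the total number of
intensity-valid trials, target 0.6 × 504 = 302.4) land where the per-cell
rounding puts them (300 for the default table), not at the independently
rounded aggregate. Pseudorandomization is a uniform shuffle constrained to
at most three consecutive identical cues (configurable), with catch trials
(cue only, no stimulus) inserted at random positions.

Factor codes are derived from the ordinal stimulus and cue codes
*s*, *c* ∈ {−1, 0, +1}: INT = *s*, EXP = *c*, PE = |*s* − *c*|,
signedPE = *s* − *c*, onesidedPE = max(*s* − *c*, 0). The reduced pain
model simply drops the *s* = −1 cells (42 °C, frequently not painful) and
keeps the original codes.

## Synthetic EEG model

Per trial and channel the signal is

```
x(t) = pink(t) + Σ_k  topo_k(channel) · g_k(subject) ·
        sqrt(1 + a_k · f_k(trial)) · osc_k · env_k(t) · b_k(t)
```

- `pink`: 1/f^e Gaussian noise (default e = 1, SD 1 µV-equivalent),
  independent across trials and channels.
- `b_k`: band-limited Gaussian noise (hard spectral mask, unit SD),
  independent across trials and channels — *induced*, non-phase-locked
  activity; evoked (phase-locked) potentials are deliberately absent.
- `env_k`: a raised-cosine-edged gate over the component's time window,
  positioned relative to the cue onset or to the stimulus plateau.
- `a_k · f_k`: the ground-truth effect — fractional power change per unit
  factor code. A configuration where `1 + a·code ≤ 0` for any reachable
  code is rejected.
- `g_k`: per-subject log-normal power gain (log-SD 0.2) so that the
  between-subject variance of the within-subject effects is non-degenerate
  (pure z-scoring would otherwise cancel subject scale entirely).
- `topo_k`: Gaussian gain map over the 2-D electrode positions
  (azimuthal projection, unit head radius).

Default components mirror the expected physiology: theta (2–7 Hz) and
gamma (46–100 Hz) power increasing with stimulus intensity, alpha-to-beta
(8–30 Hz) power decreasing with intensity (all stimulus-locked),
alpha-to-beta (8–20 Hz) power increasing with cued expectation
(cue-locked), and gamma (51–100 Hz) power decreasing with the absolute
prediction error; amplitudes ±0.3 to ±0.4. Because cue-locked components
extend into the stimulus period and the stimulus-locked frame shifts by
the intensity-dependent ramp time, a cue-locked effect acquires a small
intensity-dependent offset near its temporal edges in the stimulus-locked
frame — a realistic property of the paradigm, diluted by the jittered
cue-to-trigger interval (1.5–1.9 s by default).

Ratings follow u = β_INT·INT + β_EXP·EXP + β_PE·PE + subject intercept +
ε, discretized at equidistant thresholds (−0.9, 0, 0.9) into 1–4; defaults
β = (1.6, 0.3, 0.12), σ_ε = 0.6, σ_subject = 0.3 produce mean ratings
spanning roughly 1.5–3.5 across intensity with a visible expectation
modulation, matching the qualitative pattern a strong intensity
manipulation yields on a four-point scale. The 4-point scale itself
carries no threshold calibration information, hence the equidistant
default.

## Spectral estimation

Low band (1–30 Hz): squared magnitude of the Fourier coefficient of a
300 ms Hanning-tapered segment centred on each output time, 50 ms steps.
High band (31–100 Hz): 200 ms windows averaged over K = 2·T·W − 1 = 5
discrete prolate spheroidal (Slepian) tapers at half-bandwidth W = 15 Hz.
Both windows are shorter than the 1 Hz output grid's native resolution
(3.33 and 5 Hz), so segments are zero-padded to a 1 s equivalent length;
the padding length is a dialect choice and only interpolates the
spectrum. Output times without full window support raise rather than pad.
Power is scaled as a per-taper spectral density; the absolute scale
cancels in all downstream statistics.

Baseline normalization is the classical additive model: per
channel × frequency, the mean and SD of the trial-averaged power over the
baseline window are computed *pooling all condition cells*, then every
sample is z-scored by them. Pooling is load-bearing: with per-cell
baseline SDs over the few baseline time points, cells with fewer trials
(which in a 60/20/20 validity design are exactly the high-PE cells) get
systematically larger SD estimates and hence shrunken z values, which
masquerades as a negative prediction-error effect. Baseline windows end
150 ms before the cue because the half-window of the low-band taper would
otherwise leak post-cue activity into the baseline; cue-locked and
stimulus-locked analyses are normalized independently with their own
windows.

## Statistics

Each factor is a single-df within-subject linear contrast: weights are
the centred, unit-norm factor codes over the model's cells; per subject
the cell means are projected to a score d; F = n·mean(d)²/var(d) with
df (1, n − 1), identical to the squared paired t statistic. All reported
main effects therefore carry df (1, n − 1) — e.g. (1, 28) at n = 29 —
which is also why the cluster-forming threshold is the F(1,28) upper-5%
quantile 4.196. Per-subject intercepts cancel in the contrast; multi-df
omnibus effects, interactions and sphericity corrections are out of
scope. Parametric p values are used only for the behavioral rating ANOVA;
EEG inference is exclusively permutation-based.

Cluster formation: samples with F above threshold are connected under
(±1 time step) ∪ (±1 frequency bin) ∪ (montage-neighbor channel at the
same time–frequency point), after a single pass removing samples without
at least one supra-threshold channel neighbor (evaluated on the unsigned
supra-threshold mask; vacuous for a single-channel montage, where the
procedure reduces to plain 2-D time–frequency clustering). Samples are
split by the sign of the contrast slope before connectivity; a cluster's
mass is the sum of its F values.

Permutation scheme: condition-cell labels are permuted independently
within every subject (cells are exchangeable within subject under the
null), whole label vectors jointly across all samples. Per permutation
the maximum cluster mass over clusters of *both* signs is recorded, and
every observed cluster is compared against this single max-statistic
distribution with the add-one estimator p = (1 + b)/(1 + m). Comparing
each sign against its own-sign null at α = 0.05 would double the
family-wise rate over the two directions; the combined null controls the
family-wise error over the whole tested volume at the nominal level, at
the cost of a mild conservatism per sign. When the requested permutation
count exceeds the number of distinct within-subject relabelings the test
enumerates them exhaustively (with a warning).

The channel neighborhood is shipped as a versioned JSON template: the 60
recorded scalp electrodes plus the recovered FCz reference, 2-D positions
from the standard 10–20 sphere, adjacency from a Delaunay triangulation
with rim edges longer than 0.62 head radii pruned (2–8 neighbors per
channel, symmetric, connected).

## Numerical and engineering choices

- Band-pass filtering (1–100 Hz Butterworth order 4) is zero-phase
  (`sosfiltfilt`) and applied to continuous data before epoching, keeping
  filter transients outside the epochs; the filter direction of the
  original acquisition chain is unknown, so zero-phase is the package's
  choice.
- Re-locking shifts are rounded to the nearest sample; the common time
  axis is cropped to the range supported by every trial, making the
  operation exactly invertible on that range.
- Contrast scores whose magnitude is below 10⁻¹² of the data scale are
  snapped to zero so that constant-across-cells inputs yield F = 0 rather
  than a ratio of rounding residues; a genuinely zero score variance with
  nonzero mean reports F = +∞ with a warning.
- Permuted F maps with zero score variance contribute mass 0 (they carry
  no evidence against exchangeability).
- Epoch rejection (too close to a recording edge) is logged per trigger;
  visual/ICA artifact screening is out of scope and enters only as an
  external boolean keep-mask per trial.
- All randomness flows through numpy `default_rng` seeded from explicit
  integers; per-subject streams derive from (seed, subject), so any
  subject subset is reproducible in isolation.

## Validation scale and limitations

The statistical validation in the test suite runs the full pipeline at
reduced scale — 8–13 channels of the template, 250 Hz, coarsened
frequency/time grids, 72–90 heat-valid trials per subject, 8–12 subjects,
200–500 permutations — chosen as the smallest sizes at which the
family-wise error calibration (200 null studies against the exact
binomial band around 5%) and the injected-effect localization (≥90% of
replicates) are meaningful. The full-scale defaults (29 subjects, 60
channels, 500 Hz, 1 Hz grids, 1000 permutations) use the same code paths.

Passing these checks shows the pipeline is calibrated and sensitive for
data generated by its own model: induced band-limited power changes on a
1/f background with smooth topographies and exchangeable condition
labels. They do not establish robustness to properties the generator
omits: evoked (phase-locked) components, eye-blink/muscle artifacts,
non-stationary noise, volume-conduction correlation structure between
channels, picture-modality trials, or learning/habituation drifts across
blocks. The behavioral oracle equivalence (contrast F vs. a reference
repeated-measures ANOVA) is checked on the two-level reduced-model
factor, where the single-df contrast and the classical main effect
coincide exactly.
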