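# cuedpain

Analysis pipeline for cued heat/pain EEG experiments framed as predictive
coding, together with a ground-truth synthetic data generator used to
validate every stage of the chain.

## The problem

In a cued pain paradigm, each trial starts with a probabilistic visual cue
announcing the modality (heat or picture) and the intensity (low / medium /
high, e.g. 42/46/48 °C) of the upcoming stimulus. Because the cue is only
partly valid (70% for modality, 60% for intensity), the design dissociates
three quantities for every validly cued heat trial with stimulus code
*s* ∈ {−1, 0, +1} and cue code *c* ∈ {−1, 0, +1}:

| factor | code | meaning |
| --- | --- | --- |
| INT | *s* | physical stimulus intensity |
| EXP | *c* | cued (expected) intensity |
| PE  | \|*s* − *c*\| | absolute prediction error |
| signedPE | *s* − *c* | signed prediction error |
| onesidedPE | max(*s* − *c*, 0) | error only for stronger-than-expected stimuli |

Over the nine equally weighted cue × stimulus cells the centred INT, EXP and
PE codes are mutually orthogonal, so each factor can be tested as a
single-degree-of-freedom within-subject linear contrast. The scientific
question is where in time, frequency and electrode space oscillatory EEG
power tracks each factor — expectation effects in the alpha-to-beta band
after the cue, prediction-error effects in the gamma band after the
stimulus.

## What the package does

- **design** — builds the 6 × 6 cue × stimulus contingency table from the
  validity probabilities (every cue row sums to 1/6) and generates
  pseudorandomized, largest-remainder-balanced trial sequences
  (4 blocks × 126 trials + 4 catch trials by default).
- **simulate** — synthesizes per-subject multichannel epochs (60-channel
  extended 10–20 montage, 500 Hz): 1/f background noise plus band-limited
  oscillatory components whose power scales as `1 + amplitude · factor_code`
  with smooth Gaussian topographies, and ordinal 1–4 aversiveness ratings
  from a latent-variable model. All effect sizes are known ground truth.
- **preprocess** — epoching with centring/linear detrending, 1–100 Hz
  Butterworth band-pass contract, common-average re-referencing (recovering
  the FCz reference as a data channel), and re-time-locking to the cue onset
  or to the thermode plateau (ramp delay = (T − 33 °C)/(40 °C/s), i.e.
  225/325/375 ms).
- **tfr** — sliding-window power: 300 ms Hanning taper for 1–30 Hz and
  200 ms multitaper (±15 Hz Slepian smoothing, 5 tapers) for 31–100 Hz,
  both on a 1 Hz × 50 ms grid via zero-padding, followed by z-baseline
  normalization against a pre-cue window (−650…−150 ms cue-locked,
  −2950…−2450 ms stimulus-locked).
- **rm_stats** — per-sample repeated-measures F maps
  (`F = n·mean(d)²/var(d)`, df (1, n−1), where `d` are per-subject contrast
  scores), the behavioral rating ANOVA (full 9-cell and reduced 6-cell pain
  models), and F-distribution quantiles (the cluster-forming threshold
  F(1,28) = 4.196 at α = 0.05).
- **cluster** — sign-split cluster formation over channels × frequencies ×
  times (±1 time step, ±1 frequency bin, montage neighbor channels, plus the
  requirement of at least one supra-threshold channel neighbor) and a
  Monte-Carlo permutation test that relabels condition cells within each
  subject and compares every observed cluster mass against the permutation
  distribution of the maximum cluster mass.
- **pipeline / cli** — end-to-end orchestration with YAML configs,
  reproducible seeds, config-hash stamping and CSV/JSON/plain-text reports.

## Worked example

Simulate a 12-subject study with the default injected effects (alpha-to-beta
power increasing with cued expectation after the cue; gamma power decreasing
with the absolute prediction error after the stimulus) and analyse both:

```bash
cuedpain run-all --config examples/scaled_study.yaml --seed 1 --out example_out
```

prints, among the per-test cluster listings:

```
cuedpain analysis report (model=full, n=12, seed=1, config=0732ee5858690e9e)

[EXP_low] threshold F(1,11) > 4.844, 500 permutations
 * positive cluster: p=0.0020, mass=198335.0, 3377 samples, 0.05-1.60 s,
   4-26 Hz, 13 channels, peak Pz (F=403.04 at 0.65 s, 18 Hz)
...
[PE_high] threshold F(1,11) > 4.844, 500 permutations
 * negative cluster: p=0.0020, mass=734056.8, 4453 samples, 0.00-1.20 s,
   40-100 Hz, 13 channels, peak Oz (F=1640.34 at 0.20 s, 92 Hz)

behavioral rm-ANOVA (ratings):
  INT: F(1,11) = 4675.27, p = 8.1e-16
  EXP: F(1,11) = 88.09, p = 1.4e-06
  PE: F(1,11) = 7.03, p = 0.023
```

The expectation effect is recovered as a *positive* low-frequency cluster
covering the injected 8–20 Hz band (the cluster extends a few bins further
because the 300 ms window smooths the spectrum), and the prediction-error
effect as a *negative* gamma-band cluster; the Monte-Carlo p of 0.002 is the
smallest value 1/(n_perm + 1) attainable with 500 permutations. The
behavioral table shows the intended strong intensity effect, a clear
expectation effect and a weak prediction-error effect on ratings. The same
run writes `clusters.json`, `clusters.csv`, `behavioral.csv` and
`report.txt` to the output directory, stamped with the seed and a hash of
the full configuration.

The library surface mirrors the CLI; the equivalent Python is

```python
from cuedpain import AnalysisConfig, SyntheticConfig, run
bundle = run(AnalysisConfig(seed=1), synth=SyntheticConfig(seed=1))
```

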