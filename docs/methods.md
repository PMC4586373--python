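# Methods

This document specifies the generative model, the analysis pipeline, and the
numerical choices made in `ushrv`, including one known limitation of the
null-simulation design.

## 1. Synthetic cohort generator (`ushrv.synth`)

There is no public cohort of raw resting NN-interval recordings matching the
study design this package implements, so the package ships a calibrated
generator. Each subject's beat-to-beat interval sequence is produced beat by
beat until the cumulative beat time covers the requested duration. Interval
*i*, placed at cumulative time *t_i* (seconds), is

```
x_i = mean_nn
    + lf_amp * sin(2π · lf_freq · t_i + φ_LF)
    + hf_amp * sin(2π · hf_freq · t_i + φ_HF)
    + drift_i            (Gaussian random walk, step SD = drift_sd)
    + ε_i                (white Gaussian, SD = noise_sd)
```

clamped below at 200 ms (physiologic floor; the clamp never fires in the
calibrated regime). Phases φ are drawn uniformly per subject. Oscillations
are evaluated at cumulative *beat* time (point-process sampling), not on a
uniform grid, because that is how variability manifests in beat-indexed
data. The beat loop terminates at `t < duration − 1e-9`; the epsilon
prevents float accumulation from emitting one beat past the target (e.g.
ten 800 ms beats sum to 7.999999…s, not 8 s).

### Per-subject parameters (single-subject defaults)

| field | default | unit | role |
|---|---|---|---|
| `mean_nn` | 882 | ms | mean interval (≈68 bpm) |
| `hf_amp` | 21.5 | ms | fast (respiratory-band) oscillation amplitude |
| `hf_freq` | 0.25 | Hz | respiratory frequency |
| `lf_amp` | 30.0 | ms | slow oscillation amplitude |
| `lf_freq` | 0.015 | Hz | slow-oscillation frequency (~67 s period) |
| `drift_sd` | 0.5 | ms/beat | random-walk step SD |
| `noise_sd` | 8.0 | ms | white beat-to-beat noise |
| `duration` | 295 | s | recording length |
| `artifact_rate` | 0 | — | per-beat artifact probability |

### Across-subject population (`default_population_spec`)

`mean_nn` ~ Normal(882, 115) clipped to [450, 1500] ms; `hf_amp`, `lf_amp`,
`noise_sd`, `drift_sd` log-normal around the defaults (σ_log 0.40–0.55);
`duration` ~ Uniform(240, 300) s. The log-normal amplitudes produce the
right-skewed cohort HRV distributions that motivate the natural-log
transform in the analysis.

### Calibration

The defaults were tuned **once**, before the acceptance suite existed, and
frozen. Targets: cohort median SDNN(total) ≈ 32 ms, median RMSSD(total)
≈ 24.5 ms, mean heart rate ≈ 68 bpm, and — critically — SDNN must *grow*
with segment length (10 s → 30 s → 120 s → total) while RMSSD stays nearly
length-invariant. The growth pattern requires slow power spread across
periods longer than 30 s but shorter than the recording; a first attempt
with `lf_freq = 0.04` Hz (25 s period) saturated SDNN by 30 s, so the slow
oscillation was moved to 0.015 Hz and the drift reduced. On the default
500-subject cohort the mean SDNN rises ≈ 23 → 28 → 34 → 34 ms across
segment lengths.

### What the generator emulates, and what it does not

It emulates the *statistical structure* the downstream analysis must
detect: fast vs slow variability with realistic cohort dispersion, and
optional flagged artifacts. It does **not** model ECG/pulse waveforms, beat
detection, arrhythmia dynamics, 1/f spectra, or autonomic physiology; slow
variability is the simplest mechanism (one sinusoid + random walk) that
produces length-dependent SDNN.

## 2. Preprocessing (`ushrv.preprocess`)

Flagged artifact runs are replaced by interpolation: the run's total
duration is preserved exactly, the number of replacement beats is the gap
divided by the mean of the two anchor intervals, and replacement values lie
on the line between the anchors (constant offset to preserve the sum).
Subjects with more than **5%** interpolated intervals are excluded.
Segment-level rules for 10 s segments: a single artifact at the first or
last interval is trimmed; any interior artifact excludes the segment, which
excludes the subject from the complete-table analysis.

## 3. Segments and measures (`ushrv.segments`, `ushrv.metrics`)

From each recording (duration must lie in [239, 302] s): three
non-overlapping 10 s segments at random starts (rejection sampling from the
seeded stream), one 30 s and one 120 s segment from the start, and the full
recording as gold standard. An interval belongs to a window if its
*terminating* beat time falls inside it.

SDNN is the sample SD (ddof = 1); RMSSD is the root mean square of
successive differences with an N−1 divisor. Both are analysed on the
natural-log scale (`ln_sdnn`, `ln_rmssd`). `Avg10s` is the arithmetic mean
of the three raw 10 s values, log-transformed after averaging, with the
mean interval count as its N.

## 4. Agreement statistics (`ushrv.agreement`)

Against the gold standard, per metric and segment label:

- **Pearson r** with Fisher z CI: z = atanh r, SE = 1/√(n−3) (hence n ≥ 4
  is required); matches `scipy.stats.pearsonr.confidence_interval` exactly.
- **Bland–Altman**: differences d = gold − short; bias = mean(d); 95% LoA =
  bias ± 1.96·SD(d) (ddof = 1); bias CI = bias ± 1.96·SD(d)/√n. Plot data
  put the gold value on x.
- **Cohen's d** = bias / SD of the gold-standard values across subjects,
  with a percentile bootstrap CI (2,000 resamples, seeded).
- **ICC (two-way, absolute agreement, single measures)** among the three
  10 s segments, from the ANOVA mean squares, with the F-based CI;
  cross-checked in the tests against `pingouin` and a from-first-principles
  mean-squares computation.

## 5. Part-whole null simulation (`ushrv.nullsim`)

Because a short segment is contained in the recording it is compared with,
nonzero agreement is expected under the null of "no subject-specific
information beyond overlap". The simulation quantifies that floor.

**Decomposition** (per subject, raw-ms scale): given the total statistic T
over N_T intervals and the short statistic S over N_S,

```
R² = [T²(N_T − 1) − S²(N_S − 1)] / (N_T − N_S − 1),   N_R = N_T − N_S
```

**Recombination** (its exact algebraic inverse):

```
C² = [S²(N_S − 1) + R²(N_R − 1)] / (N_S + N_R − 1)
```

Each repetition draws subjects' shorts and remainders *independently* (with
replacement), recombines them into simulated totals, and recomputes r,
bias, LoA and d on the log scale; 1,000 repetitions give 95% reference
ranges (2.5th/97.5th percentiles, linear interpolation). Observed values
are classified below / inside / above their range. Negative radicands
(possible for RMSSD, which is not a variance share) drop that subject from
the decomposition and are counted, not clamped.

Two algebraic notes:

1. The round trip decompose→recombine is exact (verified to 1e-9 relative
   over 10,000 random inputs).
2. The split loses one degree of freedom, so "equal inputs give the same
   output" holds only asymptotically: recombine(c, N_S, c, N_R) =
   c·√((N_S+N_R−2)/(N_S+N_R−1)), and decompose(c, N_T, c, N_S) =
   c·√((N_T−N_S)/(N_T−N_S−1)).

### Known limitation: the Jensen gap at 120 s

The null recombines **raw-scale** statistics from independently drawn
subjects, but bias is assessed on the **log** scale.
ln C = f(ln S, ln R) is convex (a log-sum-exp in disguise), so by Jensen's
inequality independent pairing inflates the expected simulated log total
relative to the matched pairing: E[f(lnS_i, lnR_j)] > E[f(lnS_i, lnR_i)]
whenever the across-subject spread is nonzero. The gap grows with the
weight of the remainder term and with the between-subject log SD. At 10 s
and 30 s the gap (~0.01–0.03) is small against the width of the bias
reference range, but at 120 s the short segment carries most of the
variance weight, the range is narrow (half-width ≈ 0.04 at n = 500), and
the gap (~0.07–0.12 for cohort log SDs of 0.40–0.55) dominates: the
simulated bias range sits above the observed bias, which therefore
classifies **"below"** — even under perfect within-subject concordance,
as verified numerically. This is a property of the raw-scale recombination
design, not of the data or the implementation; the corresponding
acceptance sub-check (`test_observed_bias_inside_null_everywhere`) is
expected to fail at the 120 s label and is left failing rather than
papered over. The correlation verdicts ("above" everywhere) are unaffected.

## 6. Determinism and problem sizes

Every stochastic step is a pure function of explicit integer seeds
(`numpy.random.default_rng`); per-subject sub-seeds are drawn as
`rng.integers(0, 2**31 − 1)` from the stage seed. Typical sizes: 500
subjects × ~340 beats; the full analysis runs in seconds, the
1,000-repetition null simulation for all 12 (metric, label) pairs in under
ten seconds, because each repetition is vectorised across subjects.
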