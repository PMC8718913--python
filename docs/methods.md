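# Methods

## Data model

A test is a set of channels on a uniform 10-s grid: V̇O₂, V̇CO₂, V̇E
(L/min, mandatory), and optional HR, RER, P\_ETO₂/P\_ETCO₂, work rate,
RPE. Timestamps mark the **end** of each 10-s averaging interval (the
first sample is at t = 10 s): a cart that averages breaths into a bin can
only stamp the bin once it is complete, and it makes the warm-up boundary
arithmetic exact. The ramp protocol is (warm-up watts, warm-up duration,
increment, stage length); the two standard variants are 50 W/180 s/+25 W/60 s
("nominal") and 45 W/180 s/+15 W/60 s ("light"). A sample stamped exactly on
a stage boundary belongs to the stage it averaged, i.e. the earlier one.
The first 3 min of warm-up are excluded from all detection.

Validation is strict (constant grid step, V̇O₂ > 0, V̇E > 0, V̇CO₂ ≥ 0,
RER consistent with V̇CO₂/V̇O₂ to 1e-6) and names the first offending
sample. Missing optional channels never abort detection; only readouts
that need them return nothing.

## Detection

Both thresholds use the same primitive: the single most significant
change in a 1-D sequence under the Gaussian variance cost
`C = n·log(max(σ̂², 1e-12))` per segment, variance about the segment's own
mean, minimum segment length 3, ties to the smallest index, one change
allowed. The variance floor guards constant segments; a split must beat
the no-split cost by more than 1e-9 to count as *significant*. The
pipeline always uses the argmin even when not significant, but propagates
an indeterminate flag, because downstream quality control — not the
optimiser — is the right place to reject a test.

Inputs per threshold (post-warm-up record, time order):

* VT1: ExCO₂ = V̇CO₂²/V̇O₂ − V̇CO₂ and the V-slope y-sequence (V̇CO₂),
  each trimmed to the 30th–80th percentile of the record length;
* VT2: ExVE = V̇E²/V̇CO₂ − V̇E and the V-slope y-sequence (V̇E), trimmed
  to the 50th–100th percentile.

The percentile windows encode the prior that VT1 falls at roughly 50–65%
and VT2 at 75–87% of peak V̇O₂; they also shield the search from edge
artefacts. Trimming is by sample count; on a uniform grid that is
identical to trimming by elapsed time. The detected index maps back as
`global = index + lo_index − 1`.

Design choices worth stating:

* **Time order, not a resampled scattergram.** The V-slope methods are
  defined on V̇CO₂-vs-V̇O₂ and V̇E-vs-V̇CO₂ scattergrams, but during a
  ramp the x-variable increases monotonically, so the y-sequence in time
  order is the same ordering; no resampling step is applied. The x-channel
  is kept as signal metadata. Sensitivity of this choice is discussed
  under *Limitations*.
* **No pre-smoothing.** The cart's 10-s breath averaging is treated as
  the implicit smoothing; a centred rolling-mean helper exists for
  noisier exports but defaults off.
* **Combination averages the method TIMES**, then reads all channels at
  the one rounded instant. Averaging channel values read at two different
  instants would produce a physiologically inconsistent tuple (an HR from
  nowhere on the record, for instance). Halfway times round to the later
  sample: deterministic, and conservative for intensity prescriptions.
* **QC mirror.** A combined threshold at or before the end of the first
  post-warm-up stage (≤ 240 s nominal) is flagged indeterminate, mirroring
  the visual rule that a threshold must appear after the 75 W stage.

Peak values are maxima of a 30-s (3-sample) rolling mean per channel — a
conventional window that keeps a single noisy breath bin from defining
peak V̇O₂; the window is a parameter. Relative intensities are
100·value(VT)/value(peak) for V̇O₂ and work rate.

## Consensus quality control

Three independent evaluator values per test/threshold pass a cascade:
(1) any evaluator marking the test indeterminate rejects it; (2) if the
three agree within one stage (50 W absolute — the historical rule is
stated in watts even where stages are 25 W) or within 15% of their mean,
they are averaged; (3) otherwise, if exactly one value is an outlier and
the closest pair agree within 15% of each other, the pair is averaged;
(4) a consensus below 75 W (or 240 s) is rejected. Values are sorted
before pair selection, making the cascade permutation-invariant by
construction. Rejection is a result with a reason, never an exception.
Visual and automated values are paired by inner join on (test id,
threshold) with rejected/indeterminate rows dropped.

## Validation statistics

* Bland–Altman: bias = mean difference, limits = bias ± 1.96·SD with the
  sample SD (n−1). The difference direction defaults to automated −
  visual and is recorded in every report.
* Paired TOST with bounds ±b: t_lower = (m + b)/se against the upper
  tail, t_upper = (m − b)/se against the lower tail, df = n − 1,
  p_equiv = max of the two one-sided p values; equivalent iff
  p_equiv < α. Both one-sided statistics are always reported. Zero
  variance is resolved by the position of the mean relative to the bounds.
* ICC(2,1): two-way random effects, absolute agreement, single measures,
  `(MSR − MSE)/(MSR + (k−1)·MSE + k·(MSC − MSE)/n)` from the two-way
  ANOVA mean squares; 95% CI by the F-distribution method. This form is
  chosen because two fixed methods are compared on their absolute values;
  it matches pingouin's ICC(A,1) to double precision in the tests.
* Student t tests: paired, and independent with pooled variance;
  degenerate (zero-variance) inputs raise rather than returning an
  infinite statistic.

## Synthetic test generator

The generator emulates the study conditions end to end:

| parameter | default | meaning |
|---|---|---|
| protocol | nominal | 50 W/3 min warm-up, +25 W/min |
| peak_vo2 | 3.3 L/min | cohort-mean peak V̇O₂ |
| vo2_rest / vo2_gain | 0.5 L/min, 0.010 L/min/W | aerobic cost of the ramp |
| tau | 30 s | V̇O₂ on-kinetics time constant |
| vt1_frac / vt2_frac | 0.58 / 0.79 | planted thresholds as fractions of peak V̇O₂ |
| slope_below/above_vt1 | 0.85 / 1.20 | V-slope break at VT1 |
| vco2_intercept | 0.05 L/min | V̇CO₂ offset; keeps RER < 1 below VT1 and lets it cross 1.0 above |
| ve_gain_below/above_vt2 | 27 / 40 | V̇E per V̇CO₂ break at VT2 |
| noise_sd (V̇O₂, V̇CO₂, V̇E) | 0.05, 0.05, 2.0 L/min | per-channel breath noise |
| hr_rest / hr_slope | 88 beat/min, 0.31 beat/min/W | HR ramp, capped at 207 − 0.67·age |
| age / mass | 41 y / 76.8 kg | cohort-mean subject |

Noise-free V̇O₂ is a first-order response to the protocol's steady-state
demand, truncated at peak_vo2; the test ends one stage after the response
reaches peak. V̇CO₂ is continuous piecewise-linear in noise-free V̇O₂
with the knot at vt1_frac·peak_vo2; V̇E is continuous piecewise-linear in
noise-free V̇CO₂ with the knot at the V̇CO₂ value attained when V̇O₂
crosses vt2_frac·peak_vo2 (the VT2 knot lives in V̇CO₂ coordinates
because that is the V-slope definition of VT2). Ground truth records the
knot-crossing times of the lagged noise-free response, so on-kinetics lag
is part of the truth rather than a detection error. Per-test streams are
seeded from (base seed, test index); identical seeds are bit-identical.
HR and RER anchors (137/155/177 beat/min at VT1/VT2/peak for the default
subject) reproduce typical cohort means on this protocol.

What the generator does **not** model: breath-by-breath timing
variability, cardiovascular drift, P\_ETO₂/P\_ETCO₂ channels, plateau-free
(sub-maximal) tests, treadmill protocols. Passing recovery tests on this
generator therefore demonstrates pipeline correctness under idealised
piecewise-linear physiology, not field accuracy on real carts.

## Numerical choices

Grid tolerance 1e-6 s; RER consistency tolerance 1e-6; variance floor
1e-12; significance margin 1e-9; minimum segment 3 samples; minimum
post-warm-up record 12 samples; combined-time rounding half-up to the
later sample; CSV round-trips use shortest-repr floats and the
round-trip float parser, so write→read is bit-identical.

## Limitations

**The variance-cost search is systematically late on idealised trending
signals.** On a monotone ramp the within-segment variance is dominated by
segment *length* (a linear trend of length m contributes variance ∝ m²),
so the two-segment cost of a trending signal is minimised near the window
midpoint and a slope knot only weakly perturbs the argmin. On the
generator's clean piecewise-linear geometry the recovery experiment
(100 seeded default tests, reported by `scripts/acceptance.py` and the
acceptance suite) finds combined detections a median of ~140 s (VT1) and
~100 s (VT2) after the planted knots — about two ramp stages — with the
threshold ordering VT1 < VT2 nonetheless preserved in 100% of runs.
Feeding first differences (turning a slope break into a level shift)
removes the bias for VT1 in the noise-free case but is defeated by the
end-of-test V̇O₂ plateau inside the VT2 window and by default breath noise,
so the raw-signal formulation is retained. Real recordings are friendlier
to the method than this idealisation: pre-threshold signals are flat and
noisy rather than cleanly trending, which is precisely the regime where a
variance change localises well. Conclusions about absolute accuracy on
real data should rest on method-comparison statistics against human
raters, which this package provides.

**Other known limits.** The TOST variant used to produce a published
paired t statistic from a given bias/SD pair is not uniquely recoverable;
both one-sided statistics are therefore always reported. Whether evaluator
agreement is judged on work rate, V̇O₂ or time is a convention; work rate
is the default (the rule tolerances are stated in watts) with a seconds
mode available. Lactate-based confirmation of the thresholds is out of
scope.
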