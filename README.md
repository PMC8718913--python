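# cpetvt

Automated determination of the **ventilatory threshold (VT1)** and the
**respiratory compensation point (VT2)** from incremental cardiopulmonary
exercise test (CPET) gas-exchange data, for exercise physiologists and
sports scientists who today locate these inflection points by eye.

During a progressive cycle-ergometer ramp, two inflections partition
exercise intensity into moderate / heavy / severe domains:

* **VT1** — V̇E and V̇CO₂ begin rising out of proportion to V̇O₂ as
  bicarbonate buffering of lactic acid adds non-metabolic CO₂; the
  V̇CO₂-vs-V̇O₂ slope passes from < 1 to > 1 (V-slope).
* **VT2** — falling blood pH drives V̇E out of proportion to V̇CO₂; the
  V̇E-vs-V̇CO₂ slope breaks upward and P\_ETCO₂ starts to decline.

## Method

Each threshold is located twice on the post-warm-up record (10-s
breath-averaged samples, the first 3 min of warm-up excluded) and the two
detections are averaged:

| threshold | signal 1 | signal 2 | search window |
|---|---|---|---|
| VT1 | ExCO₂ = V̇CO₂²/V̇O₂ − V̇CO₂ | V-slope (V̇CO₂ vs V̇O₂) | 30th–80th length percentile |
| VT2 | ExVE = V̇E²/V̇CO₂ − V̇E | V-slope (V̇E vs V̇CO₂) | 50th–100th length percentile |

Each detection is the single most significant distribution change under the
Gaussian variance cost: the split index *k* minimising

```
C(k) = n₁·log σ̂₁² + n₂·log σ̂₂²
```

with σ̂² the maximum-likelihood variance of each segment about its own mean
(one change allowed, "std" statistic). The two method times are averaged,
rounded to the 10-s grid, and every channel (V̇O₂, work rate, HR, RER, V̇E)
is read at that one instant. A threshold whose sub-detections are not
significant, or that falls within the first post-warm-up stage, is flagged
indeterminate.

The package also ships:

* the method-comparison statistics used to validate such detectors —
  Bland–Altman limits of agreement (bias ± 1.96·SD), paired TOST
  equivalence against ±25 W bounds, ICC(2,1) with F-method CI, Student t
  tests;
* the evaluator-consensus quality-control cascade for visual annotations
  (three raters; averaging within 1 stage / 15%, rejection otherwise, and
  rejection of thresholds inside the warm-up stage);
* a synthetic CPET generator with planted, continuous piecewise-linear
  thresholds and per-channel breath noise, so the whole pipeline is
  testable end to end without any cohort data.

## Worked example

Simulate one nominal-protocol test (50 W warm-up, +25 W/min) and detect
both thresholds:

```bash
cpetvt simulate --n 1 --seed 42 --out-dir demo
cpetvt detect --input demo/test_000.csv --protocol nominal --mass 76.8
```

prints (abridged):

```json
{
  "vt1": {"time_s": 550.0, "work_w": 225.0, "vo2_abs_l_min": 2.52,
          "hr_beat_min": 157.8, "rer": 0.936,
          "method_times_s": {"exco2": 530.0, "vslope": 570.0},
          "indeterminate": false},
  "vt2": {"time_s": 670.0, "work_w": 275.0, "vo2_abs_l_min": 3.03,
          "method_times_s": {"exve": 670.0, "vslope": 670.0},
          "indeterminate": false},
  "peak": {"vo2_abs_l_min": 3.32, "vo2_rel_ml_kg_min": 43.26, "work_w": 316.7},
  "pct_peak_vo2_at_vt1": 75.8, "pct_peak_vo2_at_vt2": 91.1,
  "ordering_ok": true
}
```

VT1 is placed at 550 s (225 W, V̇O₂ 2.52 L/min) as the grid-rounded mean
of the ExCO₂ (530 s) and V-slope (570 s) changepoints, VT2 at 670 s where
both methods agree; the exit status is 0 because both thresholds are
determinate (2 means indeterminate). The ground truth written alongside
(`demo/ground_truth.csv`) plants the knots at 400 s and 570 s — the
detected times sit systematically later; see `docs/methods.md` for why the
variance-cost search is late on idealised trending signals and what that
implies for real recordings.

Method-comparison statistics for a batch of paired visual/automated values
(`test_id, threshold, visual, automated` CSV):

```bash
cpetvt validate --pairs pairs.csv --threshold vt1 --bound 25
```

emits bias, limits of agreement, TOST t/p, ICC with 95% CI and the paired
t test as JSON.

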