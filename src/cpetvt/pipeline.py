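"""Threshold-detection pipeline: warm-up exclusion, per-method changepoint
detection, method averaging, and physiological readouts.

VT1 (ventilatory threshold) is the mean of two detections run on the
post-warm-up record trimmed to its 30th-80th length percentile: the ExCO2
signal and the V-slope y-sequence (VCO2).  VT2 (respiratory compensation
point) is the mean of ExVE and the VE V-slope sequence on the 50th-100th
percentile window.  The two method TIMES are averaged and the result
rounded to the sample grid (half up, i.e. toward the later sample), so
every reported channel value is read at one physical instant.

Quality control mirrors the visual-analysis rejection rule: a combined
threshold at or before the end of the first post-warm-up stage (t <= 240 s
on the nominal protocol) is flagged indeterminate, as is any threshold
whose sub-detections were not significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .changepoint import ChangepointResult, changepoint_in_window
from .data import (
    GRID_STEP_S,
    GasExchangeSeries,
    MaximalityCriteria,
    MaximalityVerdict,
    ProtocolSpec,
    check_maximality,
    exclude_warmup,
    work_rate_at_time,
)
from .errors import DetectionError
from .signals import excess_co2, excess_ve, vslope_signal

#: Percentile trim windows per threshold (fractions of post-warm-up length).
VT1_WINDOW = (0.30, 0.80)
VT2_WINDOW = (0.50, 1.00)

#: Minimum usable post-warm-up length (samples) for detection.
MIN_POST_SAMPLES = 12

#: Rolling window (samples) for peak readouts; 3 x 10 s = 30 s.
PEAK_WINDOW_SAMPLES = 3


@dataclass
class ThresholdEstimate:
    """One ventilatory threshold with every channel read at its instant."""

    threshold: str  # "vt1" | "vt2"
    method: str  # "exco2" | "exve" | "vslope" | "combined"
    time: float
    vo2_abs: float
    vo2_rel: float | None
    work: float | None
    hr: float | None
    rer: float | None
    ve: float
    indeterminate: bool
    parts: dict = field(default_factory=dict)
    changepoint: ChangepointResult | None = None


@dataclass
class PeakValues:
    vo2_abs: float
    vo2_rel: float | None
    work: float | None
    hr: float | None
    rer: float | None
    ve: float


@dataclass
class VTReport:
    """Full per-test result: both thresholds, peaks, relative intensities."""

    vt1: ThresholdEstimate
    vt2: ThresholdEstimate
    peak: PeakValues
    pct_peak_vo2_at_vt1: float | None
    pct_peak_vo2_at_vt2: float | None
    pct_peak_w_at_vt1: float | None
    pct_peak_w_at_vt2: float | None
    maximality: MaximalityVerdict | None
    ordering_ok: bool

    def to_dict(self) -> dict:
        def _est(e: ThresholdEstimate) -> dict:
            return {
                "method": e.method,
                "time_s": _r(e.time, 1),
                "vo2_abs_l_min": _r(e.vo2_abs, 2),
                "vo2_rel_ml_kg_min": _r(e.vo2_rel, 2),
                "work_w": _r(e.work, 1),
                "hr_beat_min": _r(e.hr, 1),
                "rer": _r(e.rer, 3),
                "ve_l_min": _r(e.ve, 2),
                "indeterminate": e.indeterminate,
                "method_times_s": {m: _r(p.time, 1) for m, p in e.parts.items()},
            }

        return {
            "vt1": _est(self.vt1),
            "vt2": _est(self.vt2),
            "peak": {
                "vo2_abs_l_min": _r(self.peak.vo2_abs, 2),
                "vo2_rel_ml_kg_min": _r(self.peak.vo2_rel, 2),
                "work_w": _r(self.peak.work, 1),
                "hr_beat_min": _r(self.peak.hr, 1),
                "rer": _r(self.peak.rer, 3),
                "ve_l_min": _r(self.peak.ve, 2),
            },
            "pct_peak_vo2_at_vt1": _r(self.pct_peak_vo2_at_vt1, 1),
            "pct_peak_vo2_at_vt2": _r(self.pct_peak_vo2_at_vt2, 1),
            "pct_peak_w_at_vt1": _r(self.pct_peak_w_at_vt1, 1),
            "pct_peak_w_at_vt2": _r(self.pct_peak_w_at_vt2, 1),
            "maximal": None if self.maximality is None else self.maximality.maximal,
            "ordering_ok": self.ordering_ok,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)


def _r(x, nd):
    return None if x is None else round(float(x), nd)


def _round_to_grid(t: float, t0: float, step: float = GRID_STEP_S) -> float:
    """Round to the nearest grid instant; exact halves go to the later sample."""
    k = int(np.floor((t - t0) / step + 0.5))
    return t0 + k * step


def _read_at(series: GasExchangeSeries, i: int, protocol: ProtocolSpec | None):
    t = float(series.time[i])
    work = None
    if series.work is not None:
        work = float(series.work[i])
    elif protocol is not None:
        work = work_rate_at_time(t, protocol)
    rer = float(series.rer[i]) if series.rer is not None else float(
        series.vco2[i] / series.vo2[i]
    )
    hr = float(series.hr[i]) if series.hr is not None else None
    return t, float(series.vo2[i]), work, hr, rer, float(series.ve[i])


def _estimate_at(
    post: GasExchangeSeries,
    i: int,
    threshold: str,
    method: str,
    protocol: ProtocolSpec | None,
    mass: float | None,
    indeterminate: bool,
    cp: ChangepointResult | None = None,
) -> ThresholdEstimate:
    t, vo2, work, hr, rer, ve = _read_at(post, i, protocol)
    vo2_rel = 1000.0 * vo2 / mass if mass else None
    return ThresholdEstimate(
        threshold, method, t, vo2, vo2_rel, work, hr, rer, ve, indeterminate,
        changepoint=cp,
    )


def _detect(
    series: GasExchangeSeries,
    protocol: ProtocolSpec,
    threshold: str,
    mass: float | None,
) -> ThresholdEstimate:
    post = exclude_warmup(series, protocol)
    if len(post) < MIN_POST_SAMPLES:
        raise DetectionError(
            f"only {len(post)} post-warm-up samples; need >= {MIN_POST_SAMPLES}"
        )
    if threshold == "vt1":
        window = VT1_WINDOW
        sigs = {"exco2": excess_co2(post), "vslope": vslope_signal(post, "vt1")}
    else:
        window = VT2_WINDOW
        sigs = {"exve": excess_ve(post), "vslope": vslope_signal(post, "vt2")}

    parts = {}
    for name, sig in sigs.items():
        cp = changepoint_in_window(sig.values, *window)
        i = cp.global_index - 1
        parts[name] = _estimate_at(
            post, i, threshold, name, protocol, mass, not cp.significant, cp
        )

    mean_time = float(np.mean([p.time for p in parts.values()]))
    t_comb = _round_to_grid(mean_time, float(post.time[0]))
    i_comb = int(round((t_comb - post.time[0]) / GRID_STEP_S))
    i_comb = min(max(i_comb, 0), len(post) - 1)

    indeterminate = any(p.indeterminate for p in parts.values())
    # Mirror of visual QC rule: a threshold within the first post-warm-up
    # stage is physiologically implausible and rejected.
    if t_comb <= protocol.warmup_duration + protocol.stage_duration:
        indeterminate = True

    est = _estimate_at(post, i_comb, threshold, "combined", protocol, mass, indeterminate)
    est.parts = parts
    return est


def detect_vt1(
    series: GasExchangeSeries, protocol: ProtocolSpec, mass: float | None = None
) -> ThresholdEstimate:
    """Combined VT1: mean of the ExCO2 and V-slope changepoint times."""
    return _detect(series, protocol, "vt1", mass)


def detect_vt2(
    series: GasExchangeSeries, protocol: ProtocolSpec, mass: float | None = None
) -> ThresholdEstimate:
    """Combined VT2: mean of the ExVE and V-slope changepoint times."""
    return _detect(series, protocol, "vt2", mass)


def _rolled(v: np.ndarray, w: int) -> np.ndarray:
    return np.convolve(v, np.ones(w) / w, mode="valid")


def peak_values(
    series: GasExchangeSeries,
    body_mass: float | None = None,
    window: int = PEAK_WINDOW_SAMPLES,
) -> PeakValues:
    """Peak readouts as maxima of a 30-s (3-sample) rolling mean per channel."""
    if len(series) < window:
        raise DetectionError(f"need >= {window} samples for peak values")
    if body_mass is not None and body_mass <= 0:
        raise DetectionError("body_mass must be positive")
    vo2 = float(_rolled(series.vo2, window).max())
    ve = float(_rolled(series.ve, window).max())
    rer_raw = series.rer if series.rer is not None else series.vco2 / series.vo2
    rer = float(_rolled(rer_raw, window).max())
    hr = float(_rolled(series.hr, window).max()) if series.hr is not None else None
    work = float(_rolled(series.work, window).max()) if series.work is not None else None
    vo2_rel = 1000.0 * vo2 / body_mass if body_mass else None
    return PeakValues(vo2, vo2_rel, work, hr, rer, ve)


def relative_intensity(report: VTReport) -> dict:
    """Threshold intensities as percentages of peak VO2 and peak work rate."""
    out = {}
    for name, est in (("vt1", report.vt1), ("vt2", report.vt2)):
        if report.peak.vo2_abs <= 0:
            raise DetectionError("peak VO2 must be positive")
        out[f"pct_peak_vo2_at_{name}"] = 100.0 * est.vo2_abs / report.peak.vo2_abs
        if report.peak.work and est.work is not None:
            out[f"pct_peak_w_at_{name}"] = 100.0 * est.work / report.peak.work
        else:
            out[f"pct_peak_w_at_{name}"] = None
    return out


def build_report(
    series: GasExchangeSeries,
    protocol: ProtocolSpec,
    body_mass: float | None = None,
    criteria: MaximalityCriteria | None = None,
    plateau: bool = False,
    rpm_fall: bool = False,
) -> VTReport:
    """Run the full pipeline on one test and assemble the report."""
    vt1 = detect_vt1(series, protocol, mass=body_mass)
    vt2 = detect_vt2(series, protocol, mass=body_mass)
    peak = peak_values(series, body_mass=body_mass)
    maximality = None
    if criteria is not None:
        maximality = check_maximality(series, criteria, plateau=plateau, rpm_fall=rpm_fall)
    report = VTReport(
        vt1=vt1,
        vt2=vt2,
        peak=peak,
        pct_peak_vo2_at_vt1=None,
        pct_peak_vo2_at_vt2=None,
        pct_peak_w_at_vt1=None,
        pct_peak_w_at_vt2=None,
        maximality=maximality,
        ordering_ok=vt1.time < vt2.time,
    )
    pct = relative_intensity(report)
    report.pct_peak_vo2_at_vt1 = pct["pct_peak_vo2_at_vt1"]
    report.pct_peak_vo2_at_vt2 = pct["pct_peak_vo2_at_vt2"]
    report.pct_peak_w_at_vt1 = pct["pct_peak_w_at_vt1"]
    report.pct_peak_w_at_vt2 = pct["pct_peak_w_at_vt2"]
    return report
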