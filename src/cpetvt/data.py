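"""Gas-exchange test data: series container, ramp protocol, warm-up handling,
and maximal-effort criteria.

A cardiopulmonary exercise test (CPET) is represented as a set of channels
sampled on a uniform 10-s grid by the metabolic cart: oxygen uptake (VO2),
CO2 output (VCO2), minute ventilation (VE), and optionally heart rate,
respiratory exchange ratio (RER = VCO2/VO2), end-tidal pressures, work rate
and perceived exertion.  Timestamps mark the END of each 10-s averaging
interval, so the first sample carries time = 10 s.

The ramp protocol is a constant warm-up wattage followed by fixed wattage
steps every stage.  Stage boundaries are half-open with the boundary instant
belonging to the earlier sample's stage (a sample stamped at the boundary
averaged the preceding interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Sampling interval of the breath-averaged export, seconds.
GRID_STEP_S = 10.0

_GRID_TOL = 1e-6
_RER_TOL = 1e-6

#: Channel columns of the canonical CSV dialect, in writing order.
CHANNELS = ("time", "vo2", "vco2", "ve", "hr", "rer", "peto2", "petco2", "work", "rpe")
MANDATORY = ("time", "vo2", "vco2", "ve")


@dataclass(frozen=True)
class ProtocolSpec:
    """Wattage schedule of an incremental cycle-ergometer ramp test."""

    warmup_watts: float
    warmup_duration: float
    increment: float
    stage_duration: float
    variant: str = "custom"

    def __post_init__(self) -> None:
        if self.warmup_duration < 0:
            raise ValidationError("warmup_duration must be >= 0")
        if self.increment <= 0:
            raise ValidationError("increment must be > 0")
        if self.stage_duration <= 0:
            raise ValidationError("stage_duration must be > 0")

    @classmethod
    def nominal(cls) -> "ProtocolSpec":
        """50 W warm-up for 3 min, then +25 W every minute."""
        return cls(50.0, 180.0, 25.0, 60.0, variant="nominal")

    @classmethod
    def light(cls) -> "ProtocolSpec":
        """45 W warm-up for 3 min, then +15 W every minute (light protocol)."""
        return cls(45.0, 180.0, 15.0, 60.0, variant="light")

    def to_dict(self) -> dict:
        return {
            "warmup_watts": self.warmup_watts,
            "warmup_duration": self.warmup_duration,
            "increment": self.increment,
            "stage_duration": self.stage_duration,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            float(d["warmup_watts"]),
            float(d["warmup_duration"]),
            float(d["increment"]),
            float(d["stage_duration"]),
            str(d.get("variant", "custom")),
        )


def work_rate_at_time(t, protocol: ProtocolSpec):
    """Prescribed ergometer wattage at time ``t`` seconds from test start.

    Warm-up wattage for ``t <= warmup_duration``; afterwards the ramp
    increases by ``increment`` each ``stage_duration``.  A sample stamped
    exactly at a stage boundary belongs to the stage it averaged (the
    earlier one).  Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("work_rate_at_time: negative time")
    eps = 1e-9
    stage = 1 + np.floor((t_arr - protocol.warmup_duration - eps) / protocol.stage_duration)
    w = np.where(
        t_arr <= protocol.warmup_duration,
        protocol.warmup_watts,
        protocol.warmup_watts + protocol.increment * stage,
    )
    return float(w) if np.isscalar(t) or t_arr.ndim == 0 else w


_OPTIONAL = ("hr", "rer", "peto2", "petco2", "work", "rpe")


@dataclass
class GasExchangeSeries:
    """One incremental test's channels on a uniform 10-s grid.

    Mandatory channels: ``time`` (s), ``vo2``/``vco2``/``ve`` (L/min).
    Optional: ``hr`` (beat/min), ``rer``, ``peto2``/``petco2`` (mmHg),
    ``work`` (W), ``rpe`` (Borg 6-20, may be NaN-sparse), ``subject_age`` (y).
    """

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    hr: np.ndarray | None = None
    rer: np.ndarray | None = None
    peto2: np.ndarray | None = None
    petco2: np.ndarray | None = None
    work: np.ndarray | None = None
    rpe: np.ndarray | None = None
    subject_age: float | None = None

    def __post_init__(self) -> None:
        for f in ("time", "vo2", "vco2", "ve") + _OPTIONAL:
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, np.asarray(v, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        for f in ("vo2", "vco2", "ve") + _OPTIONAL:
            v = getattr(self, f)
            if v is not None and len(v) != n:
                raise ValidationError(f"channel '{f}' has length {len(v)}, expected {n}")
        steps = np.diff(self.time)
        bad = np.nonzero(np.abs(steps - GRID_STEP_S) > _GRID_TOL)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise ValidationError(
                f"non-uniform time grid: step of {steps[bad[0]]:g} s at sample index {i}"
            )
        for f, strict in (("vo2", True), ("vco2", False), ("ve", True)):
            v = getattr(self, f)
            viol = np.nonzero(v < 0 if not strict else v <= 0)[0]
            if viol.size:
                op = "<= 0" if strict else "< 0"
                raise ValidationError(f"{f} {op} at sample index {int(viol[0])}")
        if self.rer is not None:
            resid = np.abs(self.rer - self.vco2 / self.vo2)
            viol = np.nonzero(resid > _RER_TOL)[0]
            if viol.size:
                raise ValidationError(
                    f"rer inconsistent with vco2/vo2 at sample index {int(viol[0])}"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    def restrict(self, mask: np.ndarray) -> "GasExchangeSeries":
        """New series containing the masked samples (channels copied)."""
        kw = {}
        for f in ("time", "vo2", "vco2", "ve") + _OPTIONAL:
            v = getattr(self, f)
            kw[f] = v[mask].copy() if v is not None else None
        return GasExchangeSeries(subject_age=self.subject_age, **kw)

    def with_rer(self) -> "GasExchangeSeries":
        """Copy with RER filled as VCO2/VO2 when absent."""
        if self.rer is not None:
            return self
        out = self.restrict(np.ones(len(self), dtype=bool))
        out.rer = self.vco2 / self.vo2
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for f in CHANNELS:
            v = getattr(self, f)
            if v is not None:
                cols[f] = v
        return pd.DataFrame(cols)


def exclude_warmup(series: GasExchangeSeries, protocol: ProtocolSpec) -> GasExchangeSeries:
    """Drop the warm-up: keep samples with ``time > warmup_duration``.

    The original series is left intact.  Raises :class:`ValidationError`
    if nothing remains (test shorter than the warm-up).
    """
    mask = series.time > protocol.warmup_duration
    if not mask.any():
        raise ValidationError(
            f"test ends at {series.duration:g} s, within the "
            f"{protocol.warmup_duration:g} s warm-up"
        )
    return series.restrict(mask)


@dataclass(frozen=True)
class MaximalityCriteria:
    """The 4-of-5 maximal-effort criteria for an incremental test."""

    rer_threshold: float = 1.10
    hr_tolerance: float = 10.0
    hrmax_intercept: float = 207.0
    hrmax_age_slope: float = 0.67
    rpe_threshold: float = 19.0
    required_count: int = 4

    def __post_init__(self) -> None:
        if self.required_count > 5:
            raise ValidationError("required_count must be <= 5")

    def predicted_hrmax(self, age: float) -> float:
        return self.hrmax_intercept - self.hrmax_age_slope * age


@dataclass(frozen=True)
class MaximalityVerdict:
    maximal: bool
    n_met: int
    criteria: dict
    predicted_hrmax: float | None


def check_maximality(
    series: GasExchangeSeries,
    criteria: MaximalityCriteria = MaximalityCriteria(),
    plateau: bool = False,
    rpm_fall: bool = False,
) -> MaximalityVerdict:
    """Evaluate the 4-of-5 maximal-effort checklist on one test.

    Criteria: peak RER >= 1.10; VO2 plateau (supplied flag); cadence fall
    (supplied flag); peak HR within 10 beats of the age-predicted maximum
    207 - 0.67*age; peak RPE >= 19.  A criterion whose channel (or the
    subject's age) is unavailable counts as not met.
    """
    rer = series.rer if series.rer is not None else series.vco2 / series.vo2
    rer_ok = bool(np.nanmax(rer) >= criteria.rer_threshold)

    hrmax = None
    hr_ok = False
    if series.hr is not None and series.subject_age is not None:
        hrmax = criteria.predicted_hrmax(series.subject_age)
        hr_ok = bool(np.nanmax(series.hr) >= hrmax - criteria.hr_tolerance)

    rpe_ok = False
    if series.rpe is not None and np.isfinite(series.rpe).any():
        rpe_ok = bool(np.nanmax(series.rpe) >= criteria.rpe_threshold)

    met = {
        "rer": rer_ok,
        "plateau": bool(plateau),
        "rpm_fall": bool(rpm_fall),
        "hr": hr_ok,
        "rpe": rpe_ok,
    }
    n_met = sum(met.values())
    return MaximalityVerdict(n_met >= criteria.required_count, n_met, met, hrmax)


def read_cpet_csv(
    path,
    protocol: ProtocolSpec | None = None,
    column_map: dict | None = None,
) -> GasExchangeSeries:
    """Read a breath-averaged metabolic-cart export in the canonical dialect.

    Canonical dialect: comma-separated, dot decimals, one named header row
    with lower-case channel names.  ``column_map`` maps vendor header names
    to canonical ones (e.g. ``{"VO2 (L/min)": "vo2"}``).  When ``protocol``
    is given and the file has no ``work`` column, work rate is filled from
    the schedule; RER is recomputed as VCO2/VO2 when absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_map.items()})
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    kw = {c: df[c].to_numpy(dtype=float) for c in CHANNELS if c in df.columns}
    series = GasExchangeSeries(**kw)
    if series.work is None and protocol is not None:
        series.work = np.asarray(work_rate_at_time(series.time, protocol), dtype=float)
    if series.rer is None:
        series.rer = series.vco2 / series.vo2
    return series


def write_cpet_csv(series: GasExchangeSeries, path) -> None:
    """Write the canonical CSV with full float precision (round-trip exact)."""
    df = series.to_frame()
    Path(path).write_text(df.to_csv(index=False, lineterminator="\n"))
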