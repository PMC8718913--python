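"""Detection signals derived from one test's gas-exchange channels.

Four signals drive threshold detection:

* ExCO2 = VCO2^2/VO2 - VCO2 — excess CO2 output; zero when RER = 1,
  negative below, positive above.  Takes off at the ventilatory threshold
  (VT1) when buffering of lactic acid adds non-metabolic CO2.
* ExVE = VE^2/VCO2 - VE — excess ventilation, the analogous signal for the
  respiratory compensation point (VT2), when falling pH drives VE out of
  proportion to VCO2.
* V-slope pair — the VCO2 series (against VO2, for VT1) and the VE series
  (against VCO2, for VT2).  During a ramp the x-variable rises
  monotonically with time, so the y-sequence in time order is what the
  changepoint search consumes; the x-variable is kept as metadata.

The ventilatory equivalents VE/VO2 and VE/VCO2 are computed for display
and quality control only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GasExchangeSeries
from .errors import ValidationError


@dataclass
class DerivedSignal:
    """Per-sample detection signal aligned to its parent series."""

    name: str
    values: np.ndarray
    source_time: np.ndarray
    x_name: str | None = None
    x_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_time = np.asarray(self.source_time, dtype=float)
        if len(self.values) != len(self.source_time):
            raise ValidationError("signal and time must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def _require_positive(v: np.ndarray, name: str) -> None:
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        raise ValidationError(f"{name} <= 0 at sample index {int(bad[0])}")


def excess_co2(series: GasExchangeSeries) -> DerivedSignal:
    """ExCO2 = VCO2^2/VO2 - VCO2 (L/min)."""
    _require_positive(series.vo2, "vo2")
    values = series.vco2**2 / series.vo2 - series.vco2
    return DerivedSignal("exco2", values, series.time)


def excess_ve(series: GasExchangeSeries) -> DerivedSignal:
    """ExVE = VE^2/VCO2 - VE (L/min)."""
    _require_positive(series.vco2, "vco2")
    values = series.ve**2 / series.vco2 - series.ve
    return DerivedSignal("exve", values, series.time)


def vslope_signal(series: GasExchangeSeries, which: str) -> DerivedSignal:
    """V-slope y-sequence: VCO2 (``which='vt1'``) or VE (``which='vt2'``).

    The paired x-variable (VO2 or VCO2) rides along as metadata; the
    changepoint search runs on the y-sequence in time order, which during
    a ramp is also x order.
    """
    if which == "vt1":
        return DerivedSignal(
            "vslope_vt1", series.vco2.copy(), series.time, "vo2", series.vo2.copy()
        )
    if which == "vt2":
        return DerivedSignal(
            "vslope_vt2", series.ve.copy(), series.time, "vco2", series.vco2.copy()
        )
    raise ValueError(f"which must be 'vt1' or 'vt2', got {which!r}")


def ventilatory_equivalents(series: GasExchangeSeries):
    """(VE/VO2, VE/VCO2) as dimensionless per-sample signals."""
    _require_positive(series.vo2, "vo2")
    _require_positive(series.vco2, "vco2")
    return (
        DerivedSignal("ve_over_vo2", series.ve / series.vo2, series.time),
        DerivedSignal("ve_over_vco2", series.ve / series.vco2, series.time),
    )


def rolling_mean(signal: DerivedSignal, window: int) -> DerivedSignal:
    """Centered running mean for noisier-than-usual exports (off by default;
    the cart's 10-s breath averaging is normally smoothing enough).
    Edges use shrunken windows so length and alignment are preserved."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(signal)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = signal.values[lo:hi].mean()
    return DerivedSignal(signal.name, out, signal.source_time, signal.x_name, signal.x_values)
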