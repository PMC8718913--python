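"""Quality-control rules for combining independent evaluator annotations
and pairing visual with automated threshold values.

Three trained evaluators each supply a threshold location (work rate in W,
or time in s); a consensus is formed by a four-rule cascade:

1. any evaluator marking the test indeterminate rejects it;
2. if all three agree within one exercise stage (50 W) or within 15% of
   their mean, the three are averaged;
3. otherwise, if exactly one value is an outlier and the remaining pair
   agree within 15% of each other, the pair is averaged;
4. a consensus earlier than the first post-warm-up stage (below 75 W, or
   before 240 s) is rejected as indeterminate.

Rejection is a result, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .errors import ValidationError


@dataclass
class AnnotationSet:
    """Three independent evaluator values for one test and threshold."""

    threshold: str  # "vt1" | "vt2"
    values: tuple  # three floats, any of which may be None (indeterminate)
    unit: str = "watts"  # "watts" | "seconds"
    stage_tolerance: float = 50.0
    relative_tolerance: float = 0.15
    min_work: float = 75.0
    min_time: float = 240.0

    def __post_init__(self) -> None:
        if len(self.values) != 3:
            raise ValidationError("exactly three evaluator values are required")
        if self.stage_tolerance <= 0 or self.relative_tolerance <= 0:
            raise ValidationError("tolerances must be positive")
        if self.unit not in ("watts", "seconds"):
            raise ValidationError("unit must be 'watts' or 'seconds'")


@dataclass(frozen=True)
class ConsensusResult:
    accepted: bool
    value: float | None
    rule: int  # rule that decided the outcome
    reason: str


def combine_annotations(a: AnnotationSet) -> ConsensusResult:
    """Apply the consensus cascade to one annotation set."""
    if any(v is None for v in a.values):
        return ConsensusResult(False, None, 1, "an evaluator marked the test indeterminate")

    vals = sorted(float(v) for v in a.values)
    spread = vals[-1] - vals[0]
    mean3 = sum(vals) / 3.0

    candidate = None
    rule = 0
    if spread <= a.stage_tolerance or spread < a.relative_tolerance * mean3:
        candidate, rule = mean3, 2
    else:
        # exactly-one-outlier reading: keep the closest pair if its members
        # agree within the relative tolerance of each other
        best = None
        for x, y in combinations(vals, 2):
            rel = abs(x - y) / ((x + y) / 2.0) if (x + y) else 0.0
            if rel < a.relative_tolerance and (best is None or rel < best[0]):
                best = (rel, (x + y) / 2.0)
        if best is not None:
            candidate, rule = best[1], 3
        else:
            return ConsensusResult(
                False, None, 3, f"evaluator spread {spread:g} exceeds tolerances"
            )

    floor = a.min_work if a.unit == "watts" else a.min_time
    label = "min_work" if a.unit == "watts" else "min_time"
    if candidate < floor:
        return ConsensusResult(
            False, None, 4, f"consensus {candidate:g} below {label} = {floor:g}"
        )
    return ConsensusResult(True, candidate, rule, "consensus of evaluators")


def pair_visual_automated(visual: pd.DataFrame, automated: pd.DataFrame) -> pd.DataFrame:
    """Inner-join accepted visual consensus values with determinate automated
    estimates on (test_id, threshold).

    ``visual`` needs columns ``test_id, threshold, value`` and optionally
    ``accepted`` (rejected rows dropped); ``automated`` needs
    ``test_id, threshold, value`` and optionally ``indeterminate``.
    Returns columns ``test_id, threshold, visual, automated``.
    """
    v = visual.copy()
    a = automated.copy()
    if "accepted" in v.columns:
        v = v[v["accepted"].astype(bool)]
    v = v.dropna(subset=["value"])
    if "indeterminate" in a.columns:
        a = a[~a["indeterminate"].astype(bool)]
    a = a.dropna(subset=["value"])

    for name, df in (("visual", v), ("automated", a)):
        dup = df.duplicated(subset=["test_id", "threshold"])
        if dup.any():
            key = df.loc[dup, ["test_id", "threshold"]].iloc[0].tolist()
            raise ValidationError(f"duplicate {name} entry for test {key[0]} / {key[1]}")

    merged = v[["test_id", "threshold", "value"]].merge(
        a[["test_id", "threshold", "value"]],
        on=["test_id", "threshold"],
        suffixes=("_visual", "_automated"),
    )
    merged = merged.rename(columns={"value_visual": "visual", "value_automated": "automated"})
    return merged.reset_index(drop=True)
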