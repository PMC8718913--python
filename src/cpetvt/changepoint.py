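"""Single most-significant changepoint under the Gaussian variance cost.

The detector mirrors a standard-deviation changepoint search with exactly
one change allowed: each candidate split scores the two segments with the
Gaussian log-likelihood cost ``n * log(max(sigma2_mle, eps))`` where the
variance is taken about the segment's own mean, and the reported index is
the argmin of the summed cost.  Because the mean is per-segment, both
spread changes and level shifts register.  A floor ``eps = 1e-12`` guards
degenerate (constant) segments.

A detection window is expressed as a fraction pair of the input length
(percentile trimming); :func:`trim` resolves it to 1-based inclusive
bounds so detected indices can be mapped back to the untrimmed series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Variance floor for degenerate segments.
VAR_FLOOR = 1e-12

#: Minimum samples per segment; variance needs two points, three adds
#: stability at 10-s sampling.
DEFAULT_MIN_SEG = 3

#: A split must beat the no-split cost by this much to count as significant.
SIGNIFICANCE_TOL = 1e-9


@dataclass
class ChangepointResult:
    """Location and costs of the best single split.

    ``index`` is the 1-based position of the first sample of the second
    segment in the (possibly trimmed) input; ``global_index`` is the same
    point mapped to the untrimmed series (equal to ``index`` when no
    trimming was applied).
    """

    index: int
    global_index: int
    cost_split: float
    cost_nosplit: float
    significant: bool


@dataclass(frozen=True)
class TrimWindow:
    """Resolved percentile-trim bounds (1-based inclusive)."""

    lo_fraction: float
    hi_fraction: float
    lo_index: int
    hi_index: int

    def __len__(self) -> int:
        return self.hi_index - self.lo_index + 1


def segment_cost_std(y, min_seg: int = DEFAULT_MIN_SEG) -> float:
    """Gaussian variance cost of one segment: ``n * log(max(var, 1e-12))``.

    ``var`` is the maximum-likelihood variance about the segment mean, so
    the cost is invariant to adding a constant.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_seg:
        raise ValidationError(f"segment of length {n} < min_seg = {min_seg}")
    return n * float(np.log(max(float(np.var(y)), VAR_FLOOR)))


def single_changepoint_std(y, min_seg: int = DEFAULT_MIN_SEG) -> ChangepointResult:
    """Best single split of ``y`` under the summed variance cost.

    Scans every admissible split (each segment at least ``min_seg`` samples)
    with O(1) per-split cost via prefix sums; ties break to the smallest
    index.  ``significant`` is true when the best split improves on the
    one-segment cost by more than :data:`SIGNIFICANCE_TOL`.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_seg:
        raise ValidationError(f"need at least {2 * min_seg} samples, got {n}")
    yc = y - y.mean()  # center for numerical stability; cost is shift-invariant
    s1 = np.concatenate(([0.0], np.cumsum(yc)))
    s2 = np.concatenate(([0.0], np.cumsum(yc * yc)))

    cost_nosplit = segment_cost_std(y, min_seg=min_seg)
    best_cost = np.inf
    best_k = -1
    for k in range(min_seg, n - min_seg + 1):  # k = 0-based first index of 2nd segment
        m1, m2 = k, n - k
        v1 = s2[k] / m1 - (s1[k] / m1) ** 2
        v2 = (s2[n] - s2[k]) / m2 - ((s1[n] - s1[k]) / m2) ** 2
        c = m1 * np.log(max(v1, VAR_FLOOR)) + m2 * np.log(max(v2, VAR_FLOOR))
        if c < best_cost:
            best_cost = c
            best_k = k
    significant = bool(best_cost < cost_nosplit - SIGNIFICANCE_TOL)
    return ChangepointResult(
        index=best_k + 1,
        global_index=best_k + 1,
        cost_split=float(best_cost),
        cost_nosplit=float(cost_nosplit),
        significant=significant,
    )


def trim(y, lo_fraction: float, hi_fraction: float, min_seg: int = DEFAULT_MIN_SEG):
    """Percentile-trim ``y`` to the (lo, hi] fraction window of its length.

    ``lo_index = floor(lo * N) + 1`` and ``hi_index = floor(hi * N)``
    (1-based inclusive; ``hi = 1`` keeps the final sample).  Returns the
    subsequence and the resolved :class:`TrimWindow`; a detected index in
    the subsequence maps back as ``global = index + lo_index - 1``.
    """
    if not (0 <= lo_fraction < hi_fraction <= 1):
        raise ValidationError("need 0 <= lo_fraction < hi_fraction <= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    lo_index = int(np.floor(lo_fraction * n)) + 1
    hi_index = n if hi_fraction >= 1.0 else min(n, int(np.floor(hi_fraction * n)))
    if hi_index - lo_index + 1 < 2 * min_seg:
        raise ValidationError(
            f"trim window [{lo_index}, {hi_index}] shorter than 2*min_seg = {2 * min_seg}"
        )
    window = TrimWindow(lo_fraction, hi_fraction, lo_index, hi_index)
    return y[lo_index - 1 : hi_index], window


def changepoint_in_window(
    y, lo_fraction: float, hi_fraction: float, min_seg: int = DEFAULT_MIN_SEG
) -> ChangepointResult:
    """Trim, detect, and map the index back to the untrimmed coordinates."""
    sub, window = trim(y, lo_fraction, hi_fraction, min_seg=min_seg)
    res = single_changepoint_std(sub, min_seg=min_seg)
    res.global_index = res.index + window.lo_index - 1
    return res
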