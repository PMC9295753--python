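"""Core loop statistics: distances, TAD crossing, nucleation classification.

The headline summaries of a two-class HiChIP loop analysis live here: how
far apart loop anchors sit, how many TADs a loop crosses, whether the two
distance distributions differ (Wilcoxon rank-sum), and what fraction of
long Polycomb loops carry PRC2 nucleation points at one or both anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomicInterval,
    IntervalSet,
    Loop,
    anchor_distance,
    count_contained,
)

__all__ = [
    "LoopSetSummary",
    "NucleationClassification",
    "tads_crossed",
    "summarize_loops",
    "compare_distributions",
    "classify_nucleation",
    "anchor_peak_overlap_fraction",
]

# exact Wilcoxon enumeration cap: C(20,10) = 184,756 assignments
EXACT_WILCOXON_MAX_N = 20


def tads_crossed(loop: Loop, tads: IntervalSet) -> int:
    """Number of TADs fully contained strictly between a loop's anchors.

    "Between" is read as the interior interval [left.end, right.start):
    a TAD straddling an anchor is not counted.  Loops with abutting or
    overlapping anchors have no interior and cross zero TADs.
    """
    if not loop.is_intrachromosomal:
        raise ValueError("tads_crossed requires an intrachromosomal loop")
    lo = loop.left.interval.end
    hi = loop.right.interval.start
    if hi <= lo:
        return 0
    return count_contained(GenomicInterval(loop.chrom, lo, hi), tads)


@dataclass
class LoopSetSummary:
    """Distance and TAD-crossing summary of one loop set.

    ``top_percentile_median_distance`` is the median distance among the
    ceil(percentile * n) loops with the largest distances; the TAD variant
    ranks independently by TAD count.  Medians use the midpoint rule for
    even counts.
    """

    n_loops: int
    percentile: float
    convention: str
    median_distance: float
    top_percentile_median_distance: float
    median_tads_crossed: float
    top_percentile_median_tads: float
    per_loop: pd.DataFrame  # columns: distance, tads_crossed


def _top_k_median(values: np.ndarray, percentile: float) -> float:
    k = math.ceil(percentile * len(values))
    top = np.sort(values)[-k:]
    return float(np.median(top))


def summarize_loops(
    loops: Sequence[Loop],
    tads: IntervalSet,
    percentile: float = 0.01,
    convention: str = "midpoint",
) -> LoopSetSummary:
    """Per-loop distances and TAD counts with overall and top-percentile medians."""
    if not loops:
        raise ValueError("summarize_loops requires a nonempty loop list")
    if not (0.0 < percentile <= 1.0):
        raise ValueError("percentile must lie in (0, 1]")
    distances = np.array([anchor_distance(lp, convention) for lp in loops])
    crossed = np.array([tads_crossed(lp, tads) for lp in loops])
    per_loop = pd.DataFrame({"distance": distances, "tads_crossed": crossed})
    return LoopSetSummary(
        n_loops=len(loops),
        percentile=percentile,
        convention=convention,
        median_distance=float(np.median(distances)),
        top_percentile_median_distance=_top_k_median(distances, percentile),
        median_tads_crossed=float(np.median(crossed)),
        top_percentile_median_tads=_top_k_median(crossed.astype(float), percentile),
        per_loop=per_loop,
    )


def _rank_sum_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (U, p).

    For pooled sample sizes up to 20 the p-value is computed by full
    enumeration of rank assignments (a permutation test on midranks, valid
    under ties); larger samples use the normal approximation with tie
    correction and a continuity correction of 1/2.  If every pooled value is
    tied the test is uninformative and p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = _rank_sum_u(ranks[:n1], n1)

    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    n = n1 + n2
    if n <= EXACT_WILCOXON_MAX_N:
        us = np.array(
            [
                _rank_sum_u(ranks[list(idx)], n1)
                for idx in combinations(range(n), n1)
            ]
        )
        total = us.size
        p_le = np.count_nonzero(us <= u_obs + 1e-9) / total
        p_ge = np.count_nonzero(us >= u_obs - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    diff = u_obs - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u_obs, p


@dataclass
class NucleationClassification:
    """Nucleation-point status of a distance-filtered loop subset.

    Fractions are over the ``n_considered`` loops passing the distance
    filter; ``frac_one_given_any`` conditions on having at least one
    nucleation anchor (the "X% of these" reading).
    """

    min_distance: int
    n_considered: int
    labels: pd.DataFrame  # columns: loop_index, label in {both, one, neither}
    frac_both: float
    frac_one: float
    frac_neither: float

    @property
    def frac_at_least_one(self) -> float:
        return self.frac_both + self.frac_one

    @property
    def frac_one_given_any(self) -> float:
        denom = self.frac_at_least_one
        return self.frac_one / denom if denom > 0 else float("nan")


def classify_nucleation(
    loops: Sequence[Loop],
    nucleation: IntervalSet,
    min_distance: int = 1_000_000,
    convention: str = "midpoint",
) -> NucleationClassification:
    """Label loops spanning > min_distance by nucleation-anchor overlap."""
    rows = []
    for idx, lp in enumerate(loops):
        if anchor_distance(lp, convention) <= min_distance:
            continue
        left_hit = nucleation.any_overlap(lp.left.interval)
        right_hit = nucleation.any_overlap(lp.right.interval)
        if left_hit and right_hit:
            label = "both"
        elif left_hit or right_hit:
            label = "one"
        else:
            label = "neither"
        rows.append({"loop_index": idx, "label": label})
    labels = pd.DataFrame(rows, columns=["loop_index", "label"])
    n = len(labels)
    counts = labels["label"].value_counts() if n else {}
    frac = lambda key: (counts.get(key, 0) / n) if n else float("nan")
    return NucleationClassification(
        min_distance=min_distance,
        n_considered=n,
        labels=labels,
        frac_both=frac("both"),
        frac_one=frac("one"),
        frac_neither=frac("neither"),
    )


def anchor_peak_overlap_fraction(
    loops: Sequence[Loop],
    peaks: IntervalSet,
    unit: str = "per_anchor",
) -> float:
    """Fraction of anchors (or loops) overlapping at least one peak."""
    if unit not in ("per_anchor", "per_loop"):
        raise ValueError("unit must be 'per_anchor' or 'per_loop'")
    if not loops:
        raise ValueError("need at least one loop")
    if unit == "per_anchor":
        hits = sum(
            peaks.any_overlap(anc.interval)
            for lp in loops
            for anc in (lp.left, lp.right)
        )
        return hits / (2 * len(loops))
    hits = sum(
        peaks.any_overlap(lp.left.interval) or peaks.any_overlap(lp.right.interval)
        for lp in loops
    )
    return hits / len(loops)
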