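"""Binned contact-map analyses: virtual 4C, caller concordance, conservation.

A ``ContactMatrix`` stores the upper triangle (i <= j) of a symmetric
binned count matrix together with its bin table and the total number of
filtered read pairs, which is the scaling denominator for virtual 4C
(counts per million filtered read pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, Loop

__all__ = [
    "ContactMatrix",
    "Virtual4CProfile",
    "LoopMatchResult",
    "virtual_4c",
    "match_loops",
    "conserved_loops",
]


@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact counts with a bin table.

    ``bins`` has columns (chrom, start, end); its row index is the global
    bin index used by ``bin_i``/``bin_j`` (upper triangle, i <= j, each
    unordered pair stored once).
    """

    bins: pd.DataFrame
    bin_i: np.ndarray
    bin_j: np.ndarray
    count: np.ndarray
    total_pairs: int
    bin_size: int

    def __post_init__(self) -> None:
        if np.any(self.bin_i > self.bin_j):
            raise ValueError("contact matrix must be stored upper-triangle (i <= j)")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_bin_range(self, chrom: str) -> Tuple[int, int]:
        """Half-open [first, last) global bin-index range of a chromosome."""
        mask = (self.bins["chrom"] == chrom).to_numpy()
        if not mask.any():
            raise KeyError(f"chromosome {chrom!r} absent from bin table")
        idx = np.flatnonzero(mask)
        return int(idx[0]), int(idx[-1]) + 1

    def bins_overlapping(self, region: GenomicInterval) -> np.ndarray:
        """Global indices of bins overlapping a region (half-open)."""
        mask = (
            (self.bins["chrom"] == region.chrom)
            & (self.bins["start"] < region.end)
            & (self.bins["end"] > region.start)
        ).to_numpy()
        return np.flatnonzero(mask)

    def dense_cis(self, chrom: str) -> np.ndarray:
        """Dense symmetric cis matrix for one chromosome (small matrices only)."""
        lo, hi = self.chrom_bin_range(chrom)
        n = hi - lo
        out = np.zeros((n, n))
        sel = (self.bin_i >= lo) & (self.bin_i < hi) & (self.bin_j >= lo) & (self.bin_j < hi)
        ii = self.bin_i[sel] - lo
        jj = self.bin_j[sel] - lo
        cc = self.count[sel]
        out[ii, jj] += cc
        off = ii != jj
        out[jj[off], ii[off]] += cc[off]
        return out


@dataclass
class Virtual4CProfile:
    """One-viewpoint cis interaction profile in counts per million.

    ``values`` covers every bin of the viewpoint chromosome, in order;
    ``viewpoint_bins`` are chromosome-local indices whose self-interaction
    values are reported but flagged.
    """

    viewpoint: GenomicInterval
    chrom: str
    bin_size: int
    values: np.ndarray
    raw_values: np.ndarray
    viewpoint_bins: np.ndarray
    smooth_bins: int
    total_pairs: int
    bin_starts: np.ndarray = field(repr=False, default=None)


def virtual_4c(
    matrix: ContactMatrix,
    viewpoint: GenomicInterval,
    smooth_bins: int = 1,
) -> Virtual4CProfile:
    """Cis interaction profile of a viewpoint, scaled per million read pairs.

    Sums matrix rows over all bins overlapping the viewpoint (cis only),
    scales by 1e6 / total filtered read pairs, and optionally applies a
    centred running mean of ``smooth_bins`` (odd) bins.  Edge bins average
    over the bins actually inside the window.
    """
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise ValueError("smooth_bins must be a positive odd integer")
    vbins = matrix.bins_overlapping(viewpoint)
    if vbins.size == 0:
        raise ValueError(f"viewpoint {viewpoint} maps to no bin")
    lo, hi = matrix.chrom_bin_range(viewpoint.chrom)
    n = hi - lo
    raw = np.zeros(n)
    vset = set(int(v) for v in vbins)
    on_chrom = (matrix.bin_i >= lo) & (matrix.bin_i < hi)
    ii = matrix.bin_i[on_chrom]
    jj = matrix.bin_j[on_chrom]
    cc = matrix.count[on_chrom]
    i_in = np.isin(ii, vbins)
    j_in = np.isin(jj, vbins)
    # row sum of the symmetric matrix: each stored pair contributes to the
    # partner bin; a diagonal entry inside the viewpoint contributes once.
    np.add.at(raw, jj[i_in] - lo, cc[i_in])
    off_diag = j_in & (ii != jj)
    np.add.at(raw, ii[off_diag] - lo, cc[off_diag])
    raw *= 1e6 / matrix.total_pairs

    if smooth_bins == 1:
        values = raw.copy()
    else:
        kernel = np.ones(smooth_bins)
        values = np.convolve(raw, kernel, mode="same") / np.convolve(
            np.ones(n), kernel, mode="same"
        )
    return Virtual4CProfile(
        viewpoint=viewpoint,
        chrom=viewpoint.chrom,
        bin_size=matrix.bin_size,
        values=values,
        raw_values=raw,
        viewpoint_bins=vbins - lo,
        smooth_bins=smooth_bins,
        total_pairs=matrix.total_pairs,
        bin_starts=matrix.bins["start"].to_numpy()[lo:hi],
    )


# ---------------------------------------------------------------------------
# Loop matching
# ---------------------------------------------------------------------------

@dataclass
class LoopMatchResult:
    """One-to-one matching between two loop sets.

    ``pairs`` holds (index_a, index_b) matched pairs; fractions are
    relative to each input set.
    """

    pairs: list[Tuple[int, int]]
    a_only: list[int]
    b_only: list[int]
    n_a: int
    n_b: int

    @property
    def frac_a_shared(self) -> float:
        return len(self.pairs) / self.n_a if self.n_a else 0.0

    @property
    def frac_b_shared(self) -> float:
        return len(self.pairs) / self.n_b if self.n_b else 0.0


def _anchors_match(a: GenomicInterval, b: GenomicInterval, slack: int) -> bool:
    return (
        a.chrom == b.chrom
        and a.start - slack < b.end + slack
        and b.start - slack < a.end + slack
    )


def match_loops(
    set_a: Sequence[Loop], set_b: Sequence[Loop], slack_bp: int = 10_000
) -> LoopMatchResult:
    """Greedy one-to-one loop matching by anchor overlap with symmetric slack.

    Two loops match when their left anchors overlap after extending both by
    ``slack_bp`` on each side, and their right anchors do likewise.
    Candidate pairs are assigned greedily in ascending order of combined
    anchor-midpoint offset (ties: leftmost coordinates), so each loop is
    used at most once and the shared count is symmetric.
    """
    if slack_bp < 0:
        raise ValueError("slack_bp must be nonnegative")
    by_chrom_b: dict[str, list[int]] = {}
    for ib, lb in enumerate(set_b):
        by_chrom_b.setdefault(lb.chrom, []).append(ib)
    candidates = []
    for ia, la in enumerate(set_a):
        for ib in by_chrom_b.get(la.chrom, ()):
            lb = set_b[ib]
            if _anchors_match(la.left.interval, lb.left.interval, slack_bp) and \
               _anchors_match(la.right.interval, lb.right.interval, slack_bp):
                offset = abs(la.left.midpoint - lb.left.midpoint) + abs(
                    la.right.midpoint - lb.right.midpoint
                )
                candidates.append(
                    (offset, la.left.interval.start, lb.left.interval.start, ia, ib)
                )
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[Tuple[int, int]] = []
    for _, _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib))
    return LoopMatchResult(
        pairs=pairs,
        a_only=[i for i in range(len(set_a)) if i not in used_a],
        b_only=[i for i in range(len(set_b)) if i not in used_b],
        n_a=len(set_a),
        n_b=len(set_b),
    )


def _chrom_style(loops: Sequence[Loop]) -> Optional[bool]:
    """True if chromosome names carry a 'chr' prefix, None for empty sets."""
    for lp in loops:
        return lp.chrom.startswith("chr")
    return None


def conserved_loops(
    set_native: Sequence[Loop],
    set_mapped: Sequence[Loop],
    slack_bp: int = 10_000,
) -> float:
    """Fraction of native loops with a counterpart in a mapped loop set.

    Both sets must already live in the same genome's coordinates (the
    cross-species projection happens upstream).  A mismatch in chromosome
    naming style ('chr1' vs '1') is detected and rejected with a hint,
    since it would silently produce zero sharing.
    """
    if not set_native:
        raise ValueError("native loop set is empty")
    if not set_mapped:
        return 0.0
    style_a, style_b = _chrom_style(set_native), _chrom_style(set_mapped)
    if style_a is not None and style_b is not None and style_a != style_b:
        raise ValueError(
            "chromosome naming styles differ between the two sets "
            "('chr1' vs '1'); normalize names before matching"
        )
    return match_loops(set_native, set_mapped, slack_bp).frac_a_shared
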