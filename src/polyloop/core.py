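"""Genomic coordinate primitives and exact interval algebra.

All coordinates are 0-based, half-open (BED convention).  A shared endpoint
is *not* an overlap.  Strand is ignored throughout: none of the analyses
built on top of these primitives are stranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Anchor",
    "Loop",
    "IntervalSet",
    "overlaps",
    "anchor_distance",
    "count_contained",
]

MARKS = ("H3K27me3", "H3K27ac", "unlabeled")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome.

    ``name`` is the optional BED name column; compartment segments use it to
    carry their A/B label.  Zero-length or negative intervals are rejected at
    construction time rather than silently dropped downstream.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share a chromosome and at least one base.

    Half-open semantics: [0,10) and [10,20) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Anchor:
    """One side of a chromatin loop."""

    interval: GenomicInterval
    side: str  # "left" or "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"anchor side must be 'left' or 'right', got {self.side!r}")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class Loop:
    """An ordered pair of loop anchors with an optional mark label and score.

    The left anchor precedes the right anchor (ordered by start, then end).
    Interchromosomal pairs can be represented so that readers can count and
    reject them, but every distance computation refuses them explicitly.
    """

    left: Anchor
    right: Anchor
    mark: str = "unlabeled"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        if self.left.interval.chrom == self.right.interval.chrom:
            li, ri = self.left.interval, self.right.interval
            if (li.start, li.end) > (ri.start, ri.end):
                raise ValueError("left anchor must precede right anchor")

    @property
    def chrom(self) -> str:
        return self.left.interval.chrom

    @property
    def is_intrachromosomal(self) -> bool:
        return self.left.interval.chrom == self.right.interval.chrom

    @classmethod
    def from_coords(
        cls,
        chrom1: str,
        start1: int,
        end1: int,
        chrom2: str,
        start2: int,
        end2: int,
        mark: str = "unlabeled",
        score: Optional[float] = None,
    ) -> "Loop":
        """Build a loop from raw BEDPE-style coordinates, ordering anchors."""
        a = GenomicInterval(chrom1, start1, end1)
        b = GenomicInterval(chrom2, start2, end2)
        if a.chrom == b.chrom and (a.start, a.end) > (b.start, b.end):
            a, b = b, a
        return cls(Anchor(a, "left"), Anchor(b, "right"), mark=mark, score=score)


def anchor_distance(loop: Loop, convention: str = "midpoint") -> int:
    """Genomic span of a loop under a stated convention.

    ``midpoint``: absolute difference of anchor midpoints (floor midpoints).
    ``inner_edge``: gap between the anchors' facing edges, floored at zero
    for abutting or overlapping anchors.
    """
    if not loop.is_intrachromosomal:
        raise ValueError(
            "anchor_distance undefined for interchromosomal loop "
            f"{loop.left.interval} / {loop.right.interval}"
        )
    if convention == "midpoint":
        return abs(loop.right.midpoint - loop.left.midpoint)
    if convention == "inner_edge":
        return max(0, loop.right.interval.start - loop.left.interval.end)
    raise ValueError(f"unknown distance convention {convention!r}")


class IntervalSet:
    """A labelled, chromosome-indexed collection of intervals.

    Queries are backed by one interval tree per chromosome; results are
    sorted, so they do not depend on insertion order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self._intervals: list[GenomicInterval] = []
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(sorted(self._intervals))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(node.data for node in tree)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals sharing >=1 bp with ``query`` (half-open)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return sorted(node.data for node in tree.overlap(query.start, query.end))

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return tree is not None and tree.overlaps(query.start, query.end)

    def contained_in(self, container: GenomicInterval) -> list[GenomicInterval]:
        """Stored intervals fully contained in ``container`` (same chrom)."""
        tree = self._trees.get(container.chrom)
        if tree is None:
            return []
        return sorted(node.data for node in tree.envelop(container.start, container.end))

    def containing(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """Stored intervals whose half-open span covers position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(node.data for node in tree.at(pos))


def count_contained(container: GenomicInterval, interval_set: IntervalSet) -> int:
    """Number of set members fully contained in ``container``."""
    return len(interval_set.contained_in(container))
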