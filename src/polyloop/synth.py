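"""Synthetic inputs with the statistical structure the loop analyses assume.

Every generator is driven by a ``numpy.random.Generator`` seeded through
``default_rng`` (PCG64), so a fixed seed gives bit-identical output across
runs and platforms.  Each generator also returns (or takes as input) an
explicit ground-truth record, so downstream recovery can be scored without
reaching back into generator internals.

The defaults emulate the study conditions of a Polycomb HiChIP experiment
in mouse embryonic stem cells:

* two loop classes — H3K27ac enhancer loops with a short log-normal
  distance distribution, and H3K27me3 Polycomb loops whose distances mix a
  log-normal body with a Pareto tail, so the top-percentile median of the
  Polycomb class sits in the several-megabase range (≈7.9 Mb vs ≈2.0 Mb
  under the defaults below);
* a TAD tiling (≈1 Mb domains) grouped into alternating A/B compartments
  whose boundaries coincide with TAD boundaries;
* nucleation-point flags on Polycomb loop anchors: 39.1% of loops carry a
  nucleation point at both anchors and 22.9% at exactly one, so 62% carry
  at least one and 37% of those have it at one anchor only;
* binned contact maps with power-law distance decay plus planted loop dots;
* per-cell 3D barcode positions (ORCA-style) with a controllable contact
  fraction; and
* differential-site tables where signal loss is planted only at sites that
  lack EZH2 occupancy and share the deletion's compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import Anchor, GenomicInterval, IntervalSet, Loop

__all__ = [
    "SyntheticGenomeSpec",
    "LoopGeneratorSpec",
    "LoopGroundTruth",
    "mouse_like_genome",
    "make_loops",
    "make_tads_and_compartments",
    "make_contact_matrix",
    "make_signal_track",
    "make_orca_traces",
    "make_sites",
    "make_differential_table",
    "make_ezh2_peaks",
    "jittered_loop_set",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SyntheticGenomeSpec:
    """Chromosome sizes and resolution parameters for a synthetic genome."""

    chrom_sizes: Dict[str, int]
    tad_mean_size: int = 1_000_000
    bin_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has nonpositive length {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)


def mouse_like_genome(seed: int = 0, bin_size: int = 10_000) -> SyntheticGenomeSpec:
    """A 19-autosome genome with mouse-scale chromosome lengths (~2.4 Gb).

    Large chromosomes are needed so multi-megabase Polycomb loops (up to the
    tens of megabases) fit without truncating the distance distribution.
    """
    sizes_mb = [195, 182, 160, 157, 152, 150, 145, 130, 124, 130,
                122, 120, 120, 125, 104, 98, 95, 91, 61]
    chrom_sizes = {f"chr{i + 1}": mb * 1_000_000 for i, mb in enumerate(sizes_mb)}
    return SyntheticGenomeSpec(chrom_sizes=chrom_sizes, seed=seed, bin_size=bin_size)


@dataclass
class LoopGeneratorSpec:
    """Parameters of the two-class loop generator.

    Distances are anchor-midpoint distances in bp.  The H3K27ac class is
    log-normal with median ``short_log_median``; the H3K27me3 class mixes a
    log-normal body (weight ``1 - long_tail_weight``) with a Pareto tail of
    shape ``long_tail_exponent`` and scale ``long_tail_scale``.  Nucleation
    probabilities apply per H3K27me3 loop: both anchors, exactly one, or
    neither carry a PRC2 nucleation point.
    """

    n_short: int = 2000
    n_long: int = 2000
    anchor_width: int = 10_000
    short_log_median: float = 200_000.0
    short_sigma: float = 0.9
    long_log_median: float = 500_000.0
    long_sigma: float = 1.0
    long_tail_weight: float = 0.10
    long_tail_exponent: float = 1.8
    long_tail_scale: float = 1_000_000.0
    frac_nucleation_both: float = 0.391
    frac_nucleation_one: float = 0.229
    nucleation_width: int = 1_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_nucleation_both <= 1.0
                and 0.0 <= self.frac_nucleation_one <= 1.0):
            raise ValueError("nucleation fractions must lie in [0, 1]")
        if self.frac_nucleation_both + self.frac_nucleation_one > 1.0 + 1e-12:
            raise ValueError("frac_nucleation_both + frac_nucleation_one must be <= 1")
        if self.anchor_width % 2:
            raise ValueError("anchor_width must be even so midpoints are exact")


@dataclass
class LoopGroundTruth:
    """Per-loop truth table plus the emitted nucleation-point set.

    ``table`` columns: loop_id, mark, chrom, distance (midpoint convention,
    bp), nucleation in {both, one, neither} (H3K27ac rows are 'neither').
    """

    table: pd.DataFrame
    nucleation_points: IntervalSet = field(
        default_factory=lambda: IntervalSet(label="nucleation points")
    )


class PlacementError(RuntimeError):
    """No chromosome can host a requested loop span after bounded retries."""


def _draw_short_distance(spec: LoopGeneratorSpec, rng: np.random.Generator) -> int:
    d = spec.short_log_median * math.exp(spec.short_sigma * rng.standard_normal())
    return max(int(round(d)), spec.anchor_width)


def _draw_long_distance(spec: LoopGeneratorSpec, rng: np.random.Generator) -> int:
    if rng.random() < spec.long_tail_weight:
        u = rng.random()
        d = spec.long_tail_scale * (1.0 - u) ** (-1.0 / spec.long_tail_exponent)
    else:
        d = spec.long_log_median * math.exp(spec.long_sigma * rng.standard_normal())
    return max(int(round(d)), spec.anchor_width)


def _place_loop(
    distance: int,
    width: int,
    genome: SyntheticGenomeSpec,
    used: Dict[str, IntervalTree],
    rng: np.random.Generator,
    max_retries: int = 50,
) -> Tuple[str, int, int]:
    """Pick a chromosome and left-anchor midpoint for a loop of given span.

    Chromosomes are sampled proportionally to how much room they offer; the
    anchor footprints avoid previously placed anchors for ``max_retries``
    attempts, after which an overlap is accepted (collisions are rare on a
    genome-scale simulation and never break ground-truth bookkeeping).
    """
    chroms = list(genome.chrom_sizes)
    half = width // 2
    room = np.array(
        [genome.chrom_sizes[c] - distance - width for c in chroms], dtype=float
    )
    feasible = room > 0
    if not feasible.any():
        raise PlacementError(
            f"no chromosome can host a loop spanning {distance} bp"
        )
    probs = np.where(feasible, room, 0.0)
    probs /= probs.sum()
    for attempt in range(max_retries):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        size = genome.chrom_sizes[chrom]
        m1 = int(rng.integers(half, size - distance - half + 1))
        m2 = m1 + distance
        tree = used.setdefault(chrom, IntervalTree())
        if not tree.overlaps(m1 - half, m1 + half) and not tree.overlaps(
            m2 - half, m2 + half
        ):
            break
    tree = used.setdefault(chrom, IntervalTree())
    tree.addi(m1 - half, m1 + half)
    tree.addi(m2 - half, m2 + half)
    return chrom, m1, m2


def make_loops(
    spec: LoopGeneratorSpec,
    genome: SyntheticGenomeSpec,
    seed=None,
    max_distance_retries: int = 100,
) -> Tuple[list[Loop], LoopGroundTruth]:
    """Generate the two loop classes plus ground truth.

    Anchors are ``anchor_width`` wide and centred on their midpoints, so the
    realized midpoint distance equals the drawn distance exactly and any
    downstream summary can be checked against the truth table to the base
    pair.  Nucleation flags are drawn per H3K27me3 loop and materialized as
    ``nucleation_width`` intervals centred on the flagged anchors.
    """
    rng = _rng(genome.seed if seed is None else seed)
    used: Dict[str, IntervalTree] = {}
    loops: list[Loop] = []
    rows = []
    nucleation = IntervalSet(label="nucleation points")
    half = spec.anchor_width // 2

    def _make_one(mark: str, idx: int, draw) -> None:
        for _ in range(max_distance_retries):
            d = draw(spec, rng)
            try:
                chrom, m1, m2 = _place_loop(d, spec.anchor_width, genome, used, rng)
                break
            except PlacementError:
                continue
        else:
            raise PlacementError(
                f"could not place a {mark} loop after {max_distance_retries} draws"
            )
        left = Anchor(GenomicInterval(chrom, m1 - half, m1 + half), "left")
        right = Anchor(GenomicInterval(chrom, m2 - half, m2 + half), "right")
        loops.append(Loop(left, right, mark=mark))

        label = "neither"
        if mark == "H3K27me3":
            u = rng.random()
            if u < spec.frac_nucleation_both:
                label = "both"
            elif u < spec.frac_nucleation_both + spec.frac_nucleation_one:
                label = "one"
        flagged: Sequence[Anchor]
        if label == "both":
            flagged = (left, right)
        elif label == "one":
            flagged = (left,) if rng.random() < 0.5 else (right,)
        else:
            flagged = ()
        nhalf = spec.nucleation_width // 2
        for anc in flagged:
            mid = anc.midpoint
            nucleation.add(GenomicInterval(chrom, mid - nhalf, mid + nhalf))
        rows.append(
            {
                "loop_id": f"{mark}_{idx:05d}",
                "mark": mark,
                "chrom": chrom,
                "distance": d,
                "nucleation": label,
                "left_flagged": left in flagged,
                "right_flagged": right in flagged,
            }
        )

    for i in range(spec.n_short):
        _make_one("H3K27ac", i, _draw_short_distance)
    for i in range(spec.n_long):
        _make_one("H3K27me3", i, _draw_long_distance)

    truth = LoopGroundTruth(table=pd.DataFrame(rows), nucleation_points=nucleation)
    return loops, truth


# ---------------------------------------------------------------------------
# TADs and compartments
# ---------------------------------------------------------------------------

def make_tads_and_compartments(
    genome: SyntheticGenomeSpec,
    seed=None,
    mean_tads_per_compartment: float = 4.0,
) -> Tuple[IntervalSet, IntervalSet]:
    """Tile each chromosome with TADs and group them into A/B compartments.

    TAD sizes are drawn around ``tad_mean_size`` (truncated normal, sd 35% of
    the mean); the final TAD is trimmed to the chromosome end, so the tiling
    covers each chromosome exactly, without gaps or overlap.  Compartments
    are alternating A/B runs each spanning a geometric number of consecutive
    TADs, so every compartment boundary coincides with a TAD boundary.
    """
    rng = _rng(genome.seed if seed is None else seed)
    tads = IntervalSet(label="TADs")
    comps = IntervalSet(label="compartments")
    mean = genome.tad_mean_size
    for chrom in genome.chroms:
        size = genome.chrom_sizes[chrom]
        edges = [0]
        while edges[-1] < size:
            draw = rng.normal(mean, 0.35 * mean)
            draw = int(np.clip(draw, 0.3 * mean, 2.5 * mean))
            edges.append(min(edges[-1] + draw, size))
        chrom_tads = [
            GenomicInterval(chrom, a, b) for a, b in zip(edges[:-1], edges[1:])
        ]
        for t in chrom_tads:
            tads.add(t)

        label = "A" if rng.random() < 0.5 else "B"
        i = 0
        p_stop = 1.0 / mean_tads_per_compartment
        while i < len(chrom_tads):
            n = max(1, min(int(rng.geometric(p_stop)), len(chrom_tads) - i))
            start = chrom_tads[i].start
            end = chrom_tads[i + n - 1].end
            comps.add(GenomicInterval(chrom, start, end, name=label))
            label = "B" if label == "A" else "A"
            i += n
    return tads, comps


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def make_contact_matrix(
    genome: SyntheticGenomeSpec,
    loops: Sequence[Loop],
    depth: float = 2_000_000,
    decay_exponent: float = 1.0,
    dot_enrichment: float = 8.0,
    seed=None,
    max_pairs: int = 5_000_000,
):
    """Simulate a binned cis contact map with distance decay and loop dots.

    The expected count between bins i and j on the same chromosome is
    proportional to ``(1 + |i - j|) ** -decay_exponent``, multiplied by
    ``dot_enrichment`` for bin pairs holding a loop's two anchor midpoints.
    Expected counts are scaled so their genome-wide sum equals ``depth``,
    then Poisson-sampled.  The realized total is recorded as the matrix's
    filtered-read-pair count.
    """
    from .contacts import ContactMatrix

    rng = _rng(genome.seed if seed is None else seed)
    bs = genome.bin_size
    bin_rows = []
    offsets: Dict[str, int] = {}
    n_bins_by_chrom: Dict[str, int] = {}
    offset = 0
    total_pairs_count = 0
    for chrom in genome.chroms:
        size = genome.chrom_sizes[chrom]
        n = (size + bs - 1) // bs
        offsets[chrom] = offset
        n_bins_by_chrom[chrom] = n
        total_pairs_count += n * (n + 1) // 2
        for k in range(n):
            bin_rows.append((chrom, k * bs, min((k + 1) * bs, size)))
        offset += n
    if total_pairs_count > max_pairs:
        raise ValueError(
            f"contact simulation would touch {total_pairs_count} bin pairs; "
            f"use a smaller genome or larger bin size (cap {max_pairs})"
        )
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end"])

    weights = []
    index_i = []
    index_j = []
    for chrom in genome.chroms:
        n = n_bins_by_chrom[chrom]
        ii, jj = np.triu_indices(n)
        w = (1.0 + (jj - ii)) ** (-decay_exponent)
        # plant loop dots: multiply the (anchor, anchor) bin pair
        for lp in loops:
            if lp.chrom != chrom or not lp.is_intrachromosomal:
                continue
            bi = lp.left.midpoint // bs
            bj = lp.right.midpoint // bs
            if bi > bj:
                bi, bj = bj, bi
            if bj >= n:
                continue
            flat = bi * n - bi * (bi - 1) // 2 + (bj - bi)
            w[flat] *= dot_enrichment
        weights.append(w)
        index_i.append(ii + offsets[chrom])
        index_j.append(jj + offsets[chrom])
    w_all = np.concatenate(weights)
    scale = depth / w_all.sum()
    counts = rng.poisson(w_all * scale)
    nz = counts > 0
    return ContactMatrix(
        bins=bins,
        bin_i=np.concatenate(index_i)[nz],
        bin_j=np.concatenate(index_j)[nz],
        count=counts[nz].astype(np.int64),
        total_pairs=int(counts.sum()),
        bin_size=bs,
    )


# ---------------------------------------------------------------------------
# 1D signal tracks
# ---------------------------------------------------------------------------

def make_signal_track(
    peaks: IntervalSet,
    genome: SyntheticGenomeSpec,
    peak_height: float = 5.0,
    background: float = 0.1,
    seg_bp: int = 50,
    noise: bool = False,
    seed=None,
) -> pd.DataFrame:
    """Piecewise-constant bedGraph-like track: background plus triangular bumps.

    Each peak contributes a triangular bump of apex ``peak_height`` (units:
    depth per bp) over its footprint, discretized into ~``seg_bp`` runs whose
    values are the triangle evaluated at the run midpoint.  Because each half
    of the triangle is linear and run boundaries include the apex, the track
    integral over an isolated peak equals background*width + height*width/2
    exactly.  Peaks are assumed disjoint (the generators guarantee this).
    With ``noise=True``, each run's mass is Poisson-resampled.
    """
    rng = _rng(seed) if noise else None
    rows = []
    for chrom in genome.chroms:
        size = genome.chrom_sizes[chrom]
        cursor = 0
        for peak in peaks.on_chrom(chrom):
            if peak.start > cursor:
                rows.append((chrom, cursor, min(peak.start, size), background))
            w = peak.width
            apex = peak.start + w / 2.0
            for lo, hi in ((peak.start, peak.start + w // 2),
                           (peak.start + w // 2, peak.end)):
                if hi <= lo:
                    continue
                n_seg = max(1, int(round((hi - lo) / seg_bp)))
                bounds = np.unique(np.round(np.linspace(lo, hi, n_seg + 1)).astype(int))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    m = (a + b) / 2.0
                    tri = peak_height * (1.0 - abs(m - apex) / (w / 2.0))
                    rows.append((chrom, int(a), int(b), background + max(tri, 0.0)))
            cursor = peak.end
        if cursor < size:
            rows.append((chrom, cursor, size, background))
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if noise:
        lengths = (track["end"] - track["start"]).to_numpy()
        mass = track["value"].to_numpy() * lengths
        track["value"] = rng.poisson(mass) / lengths
    return track


# ---------------------------------------------------------------------------
# ORCA traces
# ---------------------------------------------------------------------------

def make_orca_traces(
    n_cells: int,
    barcodes: Sequence[str],
    contact_pairs: Dict[Tuple[str, str], float],
    contact_radius: float = 150.0,
    step_sd: float = 400.0,
    missing_rate: float = 0.05,
    seed=None,
    genotype: str = "WT",
    cell_id_offset: int = 0,
):
    """Simulate per-cell 3D barcode positions with planted contacts.

    Each cell is a Gaussian random walk over the ordered barcodes (step sd
    ``step_sd`` nm per axis).  For each designated pair, with its contact
    probability, the second barcode is resampled uniformly inside a ball of
    radius ``contact_radius`` around the first, so planted contacts satisfy
    the strict <radius criterion.  Barcodes are then dropped independently
    with ``missing_rate`` (real correlated dropout is not modelled).
    """
    from .orca import OrcaTraceSet

    rng = _rng(seed)
    barcodes = list(barcodes)
    b_index = {b: k for k, b in enumerate(barcodes)}
    for (a, b), p in contact_pairs.items():
        if a not in b_index or b not in b_index:
            raise ValueError(f"contact pair ({a}, {b}) not in barcode list")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"contact probability for ({a}, {b}) must be in [0, 1]")

    n_b = len(barcodes)
    steps = rng.normal(0.0, step_sd, size=(n_cells, n_b, 3))
    steps[:, 0, :] = 0.0
    pos = np.cumsum(steps, axis=1)

    for (a, b) in sorted(contact_pairs):
        p = contact_pairs[(a, b)]
        ia, ib = b_index[a], b_index[b]
        hit = rng.random(n_cells) < p
        n_hit = int(hit.sum())
        if n_hit:
            direction = rng.normal(size=(n_hit, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            radius = contact_radius * rng.random(n_hit) ** (1.0 / 3.0)
            pos[hit, ib, :] = pos[hit, ia, :] + direction * radius[:, None]

    keep = rng.random((n_cells, n_b)) >= missing_rate
    rows = []
    for c in range(n_cells):
        cid = f"{genotype}_{cell_id_offset + c:05d}"
        for k, bc in enumerate(barcodes):
            if keep[c, k]:
                x, y, z = pos[c, k]
                rows.append((cid, genotype, bc, x, y, z))
    df = pd.DataFrame(
        rows, columns=["cell_id", "genotype", "barcode_id", "x_nm", "y_nm", "z_nm"]
    )
    return OrcaTraceSet(df, barcodes=barcodes)


# ---------------------------------------------------------------------------
# Differential-site tables
# ---------------------------------------------------------------------------

def make_sites(
    genome: SyntheticGenomeSpec,
    n_sites: int,
    width: int = 2_000,
    seed=None,
    chrom_weights: Optional[Dict[str, float]] = None,
) -> IntervalSet:
    """Random non-overlapping candidate sites (e.g. H3K27me3 peaks)."""
    rng = _rng(seed)
    chroms = genome.chroms
    if chrom_weights is None:
        weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    else:
        weights = np.array([chrom_weights.get(c, 0.0) for c in chroms], dtype=float)
    weights /= weights.sum()
    used: Dict[str, IntervalTree] = {}
    sites = IntervalSet(label="sites")
    placed = 0
    attempts = 0
    while placed < n_sites:
        attempts += 1
        if attempts > 50 * n_sites:
            raise RuntimeError("could not place requested number of sites")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = genome.chrom_sizes[chrom]
        if size <= width:
            continue
        start = int(rng.integers(0, size - width))
        tree = used.setdefault(chrom, IntervalTree())
        if tree.overlaps(start, start + width):
            continue
        tree.addi(start, start + width)
        sites.add(GenomicInterval(chrom, start, start + width, name=f"site_{placed:05d}"))
        placed += 1
    return sites


def _compartment_label(
    compartments: IntervalSet, chrom: str, pos: int
) -> Optional[str]:
    hits = compartments.containing(chrom, pos)
    return hits[0].name if hits else None


def make_differential_table(
    sites: IntervalSet,
    ezh2: IntervalSet,
    compartments: IntervalSet,
    deletion: GenomicInterval,
    effect_size: float = 2.0,
    seed=None,
    noise_sd: float = 0.25,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Differential H3K27me3 table with effect planted by the spreading model.

    Sites that lack EZH2 occupancy AND share the deletion's compartment label
    receive log2FC = -effect_size + noise and a small adjusted p (10^-U(3,6));
    all other sites are null (noise around zero, uniform adjusted p).  Sites
    overlapping the deletion are emitted but marked for exclusion in the
    truth table.  Returns (table, truth); the table has columns chrom, start,
    end, log2fc, padj.
    """
    rng = _rng(seed)
    del_label = _compartment_label(compartments, deletion.chrom, deletion.midpoint)
    table_rows = []
    truth_rows = []
    for site in sites:
        in_deletion = site.chrom == deletion.chrom and (
            site.start < deletion.end and deletion.start < site.end
        )
        occupied = ezh2.any_overlap(site)
        label = _compartment_label(compartments, site.chrom, site.midpoint)
        same_comp = label is not None and label == del_label
        planted = (
            effect_size != 0.0 and not occupied and same_comp and not in_deletion
        )
        if planted:
            log2fc = -effect_size + rng.normal(0.0, noise_sd)
            padj = 10.0 ** (-rng.uniform(3.0, 6.0))
        else:
            log2fc = rng.normal(0.0, noise_sd)
            padj = rng.uniform(0.0, 1.0)
        table_rows.append((site.chrom, site.start, site.end, log2fc, padj))
        truth_rows.append(
            {
                "chrom": site.chrom,
                "start": site.start,
                "end": site.end,
                "planted": planted,
                "in_deletion": in_deletion,
                "ezh2_occupied": occupied,
                "same_compartment": same_comp,
            }
        )
    table = pd.DataFrame(
        table_rows, columns=["chrom", "start", "end", "log2fc", "padj"]
    )
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Peak sets and perturbed loop sets
# ---------------------------------------------------------------------------

def make_ezh2_peaks(
    loops: Sequence[Loop],
    truth: LoopGroundTruth,
    seed=None,
    base_prob: float = 0.45,
    max_prob: float = 0.95,
    log10_lo: float = 5.3,
    log10_hi: float = 7.3,
    peak_width: int = 2_000,
) -> IntervalSet:
    """EZH2 peak set: every nucleation point plus distance-dependent anchors.

    Emulates the observed pattern that EZH2 occupancy at Polycomb loop
    anchors rises with loop span: a non-nucleation H3K27me3 anchor carries an
    EZH2 peak with probability interpolating from ``base_prob`` to
    ``max_prob`` as log10(distance) runs from ``log10_lo`` to ``log10_hi``.
    Nucleation points are a strict subset of the result.
    """
    rng = _rng(seed)
    peaks = IntervalSet(label="EZH2 peaks")
    for iv in truth.nucleation_points:
        peaks.add(iv)
    half = peak_width // 2
    flags = truth.table
    me3 = [lp for lp in loops if lp.mark == "H3K27me3"]
    me3_rows = flags[flags["mark"] == "H3K27me3"].reset_index(drop=True)
    for lp, (_, row) in zip(me3, me3_rows.iterrows()):
        frac = np.clip(
            (math.log10(max(row["distance"], 1)) - log10_lo) / (log10_hi - log10_lo),
            0.0,
            1.0,
        )
        p = base_prob + (max_prob - base_prob) * frac
        for anc, flagged in (
            (lp.left, row["left_flagged"]),
            (lp.right, row["right_flagged"]),
        ):
            if flagged:
                continue  # already covered by its nucleation point
            if rng.random() < p:
                mid = anc.midpoint
                peaks.add(GenomicInterval(lp.chrom, mid - half, mid + half))
    return peaks


def jittered_loop_set(
    loops: Sequence[Loop],
    genome: SyntheticGenomeSpec,
    shared_fraction: float,
    jitter_bp: int,
    n_random: Optional[int] = None,
    seed=None,
) -> Tuple[list[Loop], np.ndarray]:
    """A comparison loop set: a jittered copy of a fraction plus random loops.

    Used to emulate a second loop caller or a cross-species loop set mapped
    into the native genome: ``shared_fraction`` of the input loops are copied
    with both anchors shifted by at most ``jitter_bp``; the remainder (or
    ``n_random`` if given) are placed uniformly at random with the same span
    distribution.  Returns the new set and a boolean mask over the *input*
    loops marking which ones have a true counterpart.
    """
    rng = _rng(seed)
    loops = list(loops)
    n = len(loops)
    shared_mask = rng.random(n) < shared_fraction
    out: list[Loop] = []
    for lp, is_shared in zip(loops, shared_mask):
        if not is_shared:
            continue
        w = lp.left.interval.width
        half = w // 2
        d1 = int(rng.integers(-jitter_bp, jitter_bp + 1))
        d2 = int(rng.integers(-jitter_bp, jitter_bp + 1))
        m1 = lp.left.midpoint + d1
        m2 = lp.right.midpoint + d2
        size = genome.chrom_sizes[lp.chrom]
        m1 = int(np.clip(m1, half, size - half))
        m2 = int(np.clip(m2, half, size - half))
        if m2 - m1 < w:  # keep anchors ordered and separated
            m2 = m1 + w
        out.append(
            Loop(
                Anchor(GenomicInterval(lp.chrom, m1 - half, m1 + half), "left"),
                Anchor(GenomicInterval(lp.chrom, m2 - half, m2 + half), "right"),
                mark=lp.mark,
            )
        )
    n_rand = (n - int(shared_mask.sum())) if n_random is None else n_random
    for _ in range(n_rand):
        src = loops[int(rng.integers(0, n))]
        d = src.right.midpoint - src.left.midpoint
        w = src.left.interval.width
        half = w // 2
        chroms = [c for c, s in genome.chrom_sizes.items() if s > d + w]
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        size = genome.chrom_sizes[chrom]
        m1 = int(rng.integers(half, size - d - half + 1))
        out.append(
            Loop(
                Anchor(GenomicInterval(chrom, m1 - half, m1 + half), "left"),
                Anchor(GenomicInterval(chrom, m1 + d - half, m1 + d + half), "right"),
                mark=src.mark,
            )
        )
    return out, shared_mask
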