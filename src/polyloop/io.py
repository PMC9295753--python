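"""Readers and writers for the plain-text formats the pipeline consumes.

BED-family files are tab-separated, 0-based, half-open.  Header lines
beginning with ``#`` or ``track`` are skipped.  Contact matrices travel as a
bin-table BED plus a (bin_i, bin_j, count) triplet file; ORCA traces and
differential-site tables are tab-separated tables with headers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet, Loop

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _data_lines(path: PathLike) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield line


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, label: str = "") -> IntervalSet:
    """Read a BED3+ file into an IntervalSet; column 4 becomes the name."""
    out = IntervalSet(label=label or Path(path).stem)
    for line in _data_lines(path):
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else None
        out.add(GenomicInterval(chrom, start, end, name=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: PathLike, mark: str = "unlabeled") -> list[Loop]:
    """Read a BEDPE loop file.

    Anchors are re-ordered so the left anchor precedes the right one.
    Interchromosomal rows are counted and excluded with a logged warning.
    """
    loops: list[Loop] = []
    n_trans = 0
    for line in _data_lines(path):
        f = line.split("\t")
        chrom1, start1, end1 = f[0], int(f[1]), int(f[2])
        chrom2, start2, end2 = f[3], int(f[4]), int(f[5])
        if chrom1 != chrom2:
            n_trans += 1
            continue
        score = float(f[7]) if len(f) > 7 and f[7] not in (".", "") else None
        loops.append(
            Loop.from_coords(chrom1, start1, end1, chrom2, start2, end2,
                             mark=mark, score=score)
        )
    if n_trans:
        logger.warning("%s: excluded %d interchromosomal loop rows", path, n_trans)
    return loops


def write_bedpe(loops: Iterable[Loop], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            li, ri = lp.left.interval, lp.right.interval
            score = "." if lp.score is None else f"{lp.score:.6g}"
            fh.write(
                f"{li.chrom}\t{li.start}\t{li.end}\t"
                f"{ri.chrom}\t{ri.start}\t{ri.end}\t"
                f"{lp.mark}_{i}\t{score}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph signal tracks
# ---------------------------------------------------------------------------

def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """Read a 4-column bedGraph into a (chrom, start, end, value) frame."""
    rows = []
    for line in _data_lines(path):
        f = line.split("\t")
        rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bedgraph(track: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


# ---------------------------------------------------------------------------
# Contact matrices (triplet text + bin table)
# ---------------------------------------------------------------------------

def write_contact_matrix(matrix, bins_path: PathLike, triplets_path: PathLike) -> None:
    """Write the bin table as BED4 (name = bin index) and counts as triplets.

    The first triplet line is a ``#total_filtered_read_pairs=N`` header so the
    scaling denominator survives the round trip.
    """
    with open(bins_path, "w") as fh:
        for idx, row in enumerate(matrix.bins.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{idx}\n")
    with open(triplets_path, "w") as fh:
        fh.write(f"#total_filtered_read_pairs={matrix.total_pairs}\n")
        fh.write(f"#bin_size={matrix.bin_size}\n")
        for i, j, c in zip(matrix.bin_i, matrix.bin_j, matrix.count):
            fh.write(f"{i}\t{j}\t{c}\n")


def read_contact_matrix(bins_path: PathLike, triplets_path: PathLike):
    from .contacts import ContactMatrix  # local import to avoid cycle

    bins = pd.read_csv(
        bins_path, sep="\t", header=None, names=["chrom", "start", "end", "index"],
        dtype={"chrom": str},
    )[["chrom", "start", "end"]]
    total = None
    bin_size = None
    ii, jj, cc = [], [], []
    with open(triplets_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#total_filtered_read_pairs="):
                total = int(line.split("=", 1)[1])
                continue
            if line.startswith("#bin_size="):
                bin_size = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            a, b, c = line.split("\t")
            ii.append(int(a))
            jj.append(int(b))
            cc.append(int(c))
    if total is None:
        total = int(sum(cc))
    if bin_size is None:
        bin_size = int((bins["end"] - bins["start"]).max())
    return ContactMatrix(
        bins=bins,
        bin_i=np.asarray(ii, dtype=np.int64),
        bin_j=np.asarray(jj, dtype=np.int64),
        count=np.asarray(cc, dtype=np.int64),
        total_pairs=total,
        bin_size=bin_size,
    )


# ---------------------------------------------------------------------------
# ORCA trace tables
# ---------------------------------------------------------------------------

ORCA_COLUMNS = ["cell_id", "genotype", "barcode_id", "x_nm", "y_nm", "z_nm"]


def read_orca_traces(path: PathLike, barcodes: Optional[list[str]] = None):
    from .orca import OrcaTraceSet

    df = pd.read_csv(path, sep="\t", dtype={"barcode_id": str, "genotype": str})
    missing = [c for c in ORCA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ORCA trace table missing columns {missing}; units must be nm")
    if barcodes is None:
        barcodes = sorted(df["barcode_id"].unique())
    return OrcaTraceSet(df[ORCA_COLUMNS].copy(), barcodes=barcodes)


def write_orca_traces(traces, path: PathLike) -> None:
    traces.df.to_csv(path, sep="\t", index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Differential-site tables
# ---------------------------------------------------------------------------

def read_differential_table(path: PathLike) -> pd.DataFrame:
    """Read a tab-separated differential table with a header.

    Requires either (chrom, start, end) site columns or a ``gene`` column,
    plus ``log2fc`` and ``padj``.  ``padj`` may contain missing values
    (rows filtered upstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str} if "chrom" in
                     pd.read_csv(path, sep="\t", nrows=0).columns else None)
    if "log2fc" not in df.columns or "padj" not in df.columns:
        raise ValueError("differential table needs 'log2fc' and 'padj' columns")
    has_site = {"chrom", "start", "end"}.issubset(df.columns)
    if not has_site and "gene" not in df.columns:
        raise ValueError("differential table needs site columns or a 'gene' column")
    return df


def write_differential_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(params: dict, path: PathLike) -> None:
    """Write a flat key=value manifest, keys sorted for reproducibility."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]}\n")


def read_manifest(path: PathLike) -> dict:
    out = {}
    for line in _data_lines(path):
        key, _, value = line.partition("=")
        out[key] = value
    return out
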