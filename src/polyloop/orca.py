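"""Pairwise 3D distance and contact-frequency analysis of ORCA traces.

ORCA (optical reconstruction of chromatin architecture) yields per-cell 3D
positions (nm) of sequentially imaged genomic barcodes.  A cell informs a
pair's statistics only when both barcodes were localized; imaging "contact"
means a pairwise distance strictly below a threshold (150 nm by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .loops import compare_distributions

__all__ = [
    "OrcaTraceSet",
    "PairDistanceResult",
    "pair_distances",
    "contact_frequency",
    "compare_genotypes",
]


class OrcaTraceSet:
    """Per-cell, per-barcode 3D localizations with genotype labels.

    Wraps a long-format table (cell_id, genotype, barcode_id, x_nm, y_nm,
    z_nm); missing barcodes are simply absent rows.  ``barcodes`` is the
    ordered probe design.
    """

    def __init__(self, df: pd.DataFrame, barcodes: Sequence[str]):
        required = {"cell_id", "genotype", "barcode_id", "x_nm", "y_nm", "z_nm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns {sorted(missing)}")
        coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("trace coordinates must be finite")
        self.df = df.reset_index(drop=True)
        self.barcodes = list(barcodes)

    @property
    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    def subset_genotype(self, genotype: str) -> "OrcaTraceSet":
        sub = self.df[self.df["genotype"] == genotype]
        return OrcaTraceSet(sub.copy(), barcodes=self.barcodes)

    def concat(self, other: "OrcaTraceSet") -> "OrcaTraceSet":
        if other.barcodes != self.barcodes:
            raise ValueError("cannot concatenate trace sets with different probes")
        return OrcaTraceSet(
            pd.concat([self.df, other.df], ignore_index=True), barcodes=self.barcodes
        )


@dataclass
class PairDistanceResult:
    """Per-cell 3D distances for one barcode pair."""

    pair: Tuple[str, str]
    cell_ids: np.ndarray
    genotypes: np.ndarray
    distances_nm: np.ndarray
    n_informative: int
    n_excluded: int

    @property
    def n_total(self) -> int:
        return self.n_informative + self.n_excluded


def pair_distances(traces: OrcaTraceSet, a: str, b: str) -> PairDistanceResult:
    """Euclidean 3D distance between two barcodes in every informative cell.

    Cells missing either barcode are excluded and counted; cells with both
    contribute one distance.
    """
    for bc in (a, b):
        if bc not in traces.barcodes:
            raise ValueError(f"barcode {bc!r} not in probe design {traces.barcodes}")
    df = traces.df
    sub = df[df["barcode_id"].isin([a, b])]
    wide = sub.pivot_table(
        index=["cell_id", "genotype"],
        columns="barcode_id",
        values=["x_nm", "y_nm", "z_nm"],
        aggfunc="first",
        observed=True,
    )
    total_cells = df["cell_id"].nunique()
    have_a = (a in sub["barcode_id"].values)
    have_both = wide.notna().all(axis=1) if have_a else pd.Series(dtype=bool)
    cols_needed = [(v, bc) for v in ("x_nm", "y_nm", "z_nm") for bc in (a, b)]
    if not all(c in wide.columns for c in cols_needed):
        # one barcode never localized anywhere
        return PairDistanceResult(
            pair=(a, b),
            cell_ids=np.array([], dtype=object),
            genotypes=np.array([], dtype=object),
            distances_nm=np.array([], dtype=float),
            n_informative=0,
            n_excluded=total_cells,
        )
    complete = wide.dropna()
    pa = complete[[("x_nm", a), ("y_nm", a), ("z_nm", a)]].to_numpy(dtype=float)
    pb = complete[[("x_nm", b), ("y_nm", b), ("z_nm", b)]].to_numpy(dtype=float)
    d = np.sqrt(((pa - pb) ** 2).sum(axis=1))
    cell_ids = np.array([idx[0] for idx in complete.index], dtype=object)
    genos = np.array([idx[1] for idx in complete.index], dtype=object)
    return PairDistanceResult(
        pair=(a, b),
        cell_ids=cell_ids,
        genotypes=genos,
        distances_nm=d,
        n_informative=len(complete),
        n_excluded=total_cells - len(complete),
    )


def contact_frequency(result: PairDistanceResult, threshold_nm: float = 150.0) -> float:
    """Fraction of informative cells with pair distance strictly < threshold."""
    if result.n_informative == 0:
        raise ValueError("no informative cells for this pair")
    return float(np.count_nonzero(result.distances_nm < threshold_nm)
                 / result.n_informative)


def compare_genotypes(
    traces: OrcaTraceSet,
    pair: Tuple[str, str],
    genotypes: Tuple[str, str],
) -> Tuple[float, float, float]:
    """Median pair distance per genotype plus a two-sided Wilcoxon p-value.

    Returns (median of first genotype, median of second, p).  Distances are
    pairwise-complete per genotype; an empty group is an error.
    """
    result = pair_distances(traces, *pair)
    groups = []
    for label in genotypes:
        d = result.distances_nm[result.genotypes == label]
        if d.size == 0:
            raise ValueError(f"genotype {label!r} has no informative cells")
        groups.append(d)
    _, p = compare_distributions(groups[0], groups[1])
    return float(np.median(groups[0])), float(np.median(groups[1])), p
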