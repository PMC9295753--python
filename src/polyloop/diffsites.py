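"""Classification and stratification of differential signal tables.

Consumes post-DESeq2 tables (site or gene, log2 fold change, BH-adjusted
p) and applies the downstream logic: strict significance thresholds,
deletion-overlap exclusion, cis/trans labelling, and stratification by
EZH2 occupancy and A/B compartment, with a Fisher exact test on the
(significant-down x EZH2-occupied) 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "classify_differential_sites",
    "annotate_sites",
    "stratified_summary",
    "expression_scatter_flags",
    "StratifiedSummary",
]

SITE_COLUMNS = ("chrom", "start", "end")


def classify_differential_sites(
    table: pd.DataFrame, fc_cut: float = 1.0, p_cut: float = 0.05
) -> pd.DataFrame:
    """Label each row up/down/ns using strict cutoffs on |log2FC| and padj.

    Significance requires |log2fc| > fc_cut AND padj < p_cut, both strict;
    rows with missing padj (upstream independent filtering) are 'ns'.
    Returns a copy of the table with a ``status`` column; thresholds are
    recorded in ``DataFrame.attrs``.
    """
    if fc_cut <= 0 or p_cut <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    log2fc = out["log2fc"].to_numpy(dtype=float)
    padj = out["padj"].to_numpy(dtype=float)
    sig = (~np.isnan(padj)) & (padj < p_cut) & (np.abs(log2fc) > fc_cut)
    status = np.where(sig & (log2fc > 0), "up", np.where(sig, "down", "ns"))
    out["status"] = status
    out.attrs["fc_cut"] = fc_cut
    out.attrs["p_cut"] = p_cut
    return out


def annotate_sites(
    cls: pd.DataFrame,
    deletion: GenomicInterval,
    ezh2: IntervalSet,
    compartments: IntervalSet,
) -> pd.DataFrame:
    """Add excluded / cis / ezh2_occupied / same_compartment flags per site.

    * ``excluded``: any-bp overlap with the deletion (these sites sit inside
      the engineered deletion and are omitted from downstream summaries);
    * ``cis``: same chromosome as the deletion;
    * ``ezh2_occupied``: any-bp overlap with the EZH2 peak set;
    * ``same_compartment``: the A/B label of the compartment containing the
      site midpoint equals the deletion's label (taken from the compartment
      containing the deletion midpoint; spanning a boundary logs a warning).
    """
    out = cls.copy()
    del_hits = compartments.containing(deletion.chrom, deletion.midpoint)
    del_label = del_hits[0].name if del_hits else None
    start_hits = compartments.containing(deletion.chrom, deletion.start)
    if start_hits and del_hits and start_hits[0] != del_hits[0]:
        logger.warning(
            "deletion %s spans a compartment boundary; using midpoint label %s",
            deletion, del_label,
        )
    excluded = []
    cis = []
    occupied = []
    same_comp = []
    for row in out.itertuples(index=False):
        site = GenomicInterval(row.chrom, row.start, row.end)
        excluded.append(
            site.chrom == deletion.chrom
            and site.start < deletion.end
            and deletion.start < site.end
        )
        cis.append(site.chrom == deletion.chrom)
        occupied.append(ezh2.any_overlap(site))
        hits = compartments.containing(site.chrom, site.midpoint)
        label = hits[0].name if hits else None
        same_comp.append(label is not None and label == del_label)
    out["excluded"] = excluded
    out["cis"] = cis
    out["ezh2_occupied"] = occupied
    out["same_compartment"] = same_comp
    out.attrs.update(cls.attrs)
    out.attrs["deletion"] = str(deletion)
    return out


@dataclass
class StratifiedSummary:
    """Cross-tabulated site counts and the EZH2 association test.

    ``counts`` indexes (scope, ezh2_occupied, same_compartment) rows by
    status columns; the Fisher exact test (two-sided, point-probability
    method) contrasts significant-down against all other non-excluded
    sites across EZH2 occupancy, genome-wide and cis-only.
    """

    counts: pd.DataFrame
    fisher_odds_ratio: float
    fisher_p: float
    fisher_odds_ratio_cis: float
    fisher_p_cis: float


def _fisher_down_by_ezh2(df: pd.DataFrame) -> tuple[float, float]:
    down = (df["status"] == "down").to_numpy()
    ez = df["ezh2_occupied"].to_numpy(dtype=bool)
    table = [
        [int((down & ~ez).sum()), int((down & ez).sum())],
        [int((~down & ~ez).sum()), int((~down & ez).sum())],
    ]
    if down.sum() == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def stratified_summary(annotated: pd.DataFrame) -> StratifiedSummary:
    """Counts of up/down/ns sites by (EZH2 occupancy x compartment match).

    Excluded (deletion-overlapping) sites are dropped first.  Both a
    genome-wide and a cis-only cross-tabulation are reported, plus Fisher
    exact tests asking whether significant losses concentrate at sites
    lacking EZH2 occupancy.
    """
    needed = {"status", "excluded", "cis", "ezh2_occupied", "same_compartment"}
    missing = needed - set(annotated.columns)
    if missing:
        raise ValueError(f"annotate_sites must run first; missing {sorted(missing)}")
    usable = annotated[~annotated["excluded"]]
    blocks = []
    for scope, df in (("genome_wide", usable), ("cis", usable[usable["cis"]])):
        tab = (
            df.groupby(["ezh2_occupied", "same_compartment"], observed=False)["status"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["down", "ns", "up"], fill_value=0)
            .reset_index()
        )
        tab.insert(0, "scope", scope)
        blocks.append(tab)
    counts = pd.concat(blocks, ignore_index=True)
    odds, p = _fisher_down_by_ezh2(usable)
    odds_cis, p_cis = _fisher_down_by_ezh2(usable[usable["cis"]])
    return StratifiedSummary(
        counts=counts,
        fisher_odds_ratio=odds,
        fisher_p=p,
        fisher_odds_ratio_cis=odds_cis,
        fisher_p_cis=p_cis,
    )


def expression_scatter_flags(
    table: pd.DataFrame,
    deleted_genes: Sequence[str],
    partner_genes: Sequence[str],
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript higher/lower/ns classes plus membership flags.

    ``deleted_genes`` (genes inside the engineered deletion) and
    ``partner_genes`` (loop-partner genes of interest) are flagged
    regardless of significance so a scatterplot can highlight them.
    """
    if table["gene"].duplicated().any():
        raise ValueError("gene names must be unique per row")
    out = classify_differential_sites(table, fc_cut=fc_cut, p_cut=p_cut)
    out = out.rename(columns={"status": "expression_class"})
    out["expression_class"] = out["expression_class"].map(
        {"up": "higher", "down": "lower", "ns": "ns"}
    )
    deleted = set(deleted_genes)
    partners = set(partner_genes)
    out["is_deleted_gene"] = out["gene"].isin(deleted)
    out["is_partner_gene"] = out["gene"].isin(partners)
    return out
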