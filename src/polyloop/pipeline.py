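"""End-to-end driver: synthetic data -> loop statistics -> report bundle.

``run_pipeline`` executes every stage of the analysis on a synthetic
dataset emulating a two-mark HiChIP study (H3K27me3 vs H3K27ac loops),
writes per-stage tables under the output directory, and produces a
machine-readable ``summary.json`` plus a ``manifest.txt`` capturing the
seed and every parameter.  The same config and seed give byte-identical
summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io
from .core import GenomicInterval, IntervalSet
from .contacts import conserved_loops, match_loops, virtual_4c
from .diffsites import annotate_sites, classify_differential_sites, stratified_summary
from .enrichment import aggregate_profile, center_choice, overlap_distance_curve
from .loops import (
    anchor_peak_overlap_fraction,
    classify_nucleation,
    compare_distributions,
    summarize_loops,
)
from .orca import compare_genotypes, contact_frequency, pair_distances
from .synth import (
    LoopGeneratorSpec,
    SyntheticGenomeSpec,
    jittered_loop_set,
    make_contact_matrix,
    make_differential_table,
    make_ezh2_peaks,
    make_loops,
    make_orca_traces,
    make_signal_track,
    make_sites,
    make_tads_and_compartments,
    mouse_like_genome,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Every threshold is echoed into the run manifest; anything not set in a
    config file keeps the default shown here (logged at INFO when applied).
    """

    seed: int = 1
    outdir: str = "results/run"

    # loop generation (study conditions)
    n_short: int = 2000
    n_long: int = 2000
    frac_nucleation_both: float = 0.391
    frac_nucleation_one: float = 0.229

    # loop statistics
    percentile: float = 0.01
    min_distance: int = 1_000_000
    convention: str = "midpoint"

    # enrichment
    window_bp: int = 10_000
    bin_bp: int = 50
    span: float = 0.6
    n_boot: int = 200

    # contact analysis
    contact_chrom_size: int = 5_000_000
    contact_depth: float = 2_000_000.0
    decay_exponent: float = 1.0
    dot_enrichment: float = 8.0
    smooth_bins: int = 1
    slack_bp: int = 10_000
    concordance_fraction: float = 0.92
    concordance_extra: int = 1000
    conserved_fraction: float = 0.30

    # ORCA imaging
    n_cells_wt: int = 2190
    n_cells_mt: int = 520
    orca_contact_prob_wt: float = 0.40
    orca_contact_prob_mt: float = 0.05
    threshold_nm: float = 150.0
    step_sd_nm: float = 400.0
    missing_rate: float = 0.05

    # differential sites
    n_sites: int = 300
    effect_size: float = 2.0
    fc_cut: float = 1.0
    p_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        defaults = cls()
        for name in cls.__dataclass_fields__:
            if name not in raw:
                logger.info("config: using default %s=%r", name, getattr(defaults, name))
        return cfg


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage on synthetic data; return the summary dict.

    Writes, under ``config.outdir``: the generated datasets (BEDPE, BED,
    bedGraph, contact-matrix triplets, ORCA traces, differential table),
    per-stage result tables, ``summary.json`` and ``manifest.txt``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    if not (0 <= seed < 2**31 - 20):
        raise ValueError("seed must be a small nonnegative integer")
    summary: dict = {"seed": seed}

    # --- stage 1: synthetic genome, loops, TADs, compartments -------------
    logger.info("stage simulate: generating genome, loops, TADs, compartments")
    genome = mouse_like_genome(seed=seed)
    tads, comps = make_tads_and_compartments(genome, seed=seed + 1)
    loop_spec = LoopGeneratorSpec(
        n_short=config.n_short,
        n_long=config.n_long,
        frac_nucleation_both=config.frac_nucleation_both,
        frac_nucleation_one=config.frac_nucleation_one,
    )
    all_loops, truth = make_loops(loop_spec, genome, seed=seed + 2)
    me3 = [lp for lp in all_loops if lp.mark == "H3K27me3"]
    k27ac = [lp for lp in all_loops if lp.mark == "H3K27ac"]
    io.write_bedpe(me3, out / "loops_h3k27me3.bedpe")
    io.write_bedpe(k27ac, out / "loops_h3k27ac.bedpe")
    io.write_bed(tads, out / "tads.bed")
    io.write_bed(comps, out / "compartments.bed")
    io.write_bed(truth.nucleation_points, out / "nucleation_points.bed")
    truth.table.to_csv(out / "loop_ground_truth.tsv", sep="\t", index=False)

    # --- stage 2: loop architecture ---------------------------------------
    logger.info("stage loops: distance / TAD-crossing / nucleation statistics")
    sum_me3 = summarize_loops(me3, tads, config.percentile, config.convention)
    sum_ac = summarize_loops(k27ac, tads, config.percentile, config.convention)
    _, p_dist = compare_distributions(
        sum_me3.per_loop["distance"], sum_ac.per_loop["distance"]
    )
    _, p_tads = compare_distributions(
        sum_me3.per_loop["tads_crossed"], sum_ac.per_loop["tads_crossed"]
    )
    nuc = classify_nucleation(
        me3, truth.nucleation_points, config.min_distance, config.convention
    )
    sum_me3.per_loop.to_csv(out / "per_loop_h3k27me3.tsv", sep="\t", index=False)
    sum_ac.per_loop.to_csv(out / "per_loop_h3k27ac.tsv", sep="\t", index=False)
    summary["loops"] = {
        "n_h3k27me3": sum_me3.n_loops,
        "n_h3k27ac": sum_ac.n_loops,
        "median_distance_mb_h3k27me3": sum_me3.median_distance / 1e6,
        "median_distance_mb_h3k27ac": sum_ac.median_distance / 1e6,
        "top_percentile_median_distance_mb_h3k27me3":
            sum_me3.top_percentile_median_distance / 1e6,
        "top_percentile_median_distance_mb_h3k27ac":
            sum_ac.top_percentile_median_distance / 1e6,
        "median_tads_crossed_h3k27me3": sum_me3.median_tads_crossed,
        "median_tads_crossed_h3k27ac": sum_ac.median_tads_crossed,
        "top_percentile_median_tads_h3k27me3": sum_me3.top_percentile_median_tads,
        "top_percentile_median_tads_h3k27ac": sum_ac.top_percentile_median_tads,
        "wilcoxon_p_distance": p_dist,
        "wilcoxon_p_tads": p_tads,
        "nucleation_n_loops_over_min_distance": nuc.n_considered,
        "nucleation_frac_at_least_one": nuc.frac_at_least_one,
        "nucleation_frac_one_given_any": nuc.frac_one_given_any,
    }

    # --- stage 3: anchor enrichment ---------------------------------------
    logger.info("stage enrich: EZH2 peaks, signal profile, overlap curve")
    ezh2 = make_ezh2_peaks(all_loops, truth, seed=seed + 3)
    io.write_bed(ezh2, out / "ezh2_peaks.bed")
    track = make_signal_track(ezh2, genome, peak_height=5.0, background=0.1)
    io.write_bedgraph(track, out / "ezh2_signal.bedgraph")
    anchors = [anc for lp in me3 for anc in (lp.left, lp.right)]
    centers = center_choice(anchors, ezh2, mode="peak_in_anchor")
    profile = aggregate_profile(
        centers, track, config.window_bp, config.bin_bp,
        chrom_sizes=genome.chrom_sizes,
    )
    np.savetxt(
        out / "anchor_profile.tsv",
        np.column_stack([profile.bin_offsets, profile.values]),
        delimiter="\t", header="offset_bp\tsignal", comments="", fmt="%.6g",
    )
    curve = overlap_distance_curve(
        me3, ezh2, span=config.span, n_boot=config.n_boot, seed=seed + 4
    )
    if curve.fitted is not None:
        curve.fitted.to_csv(out / "overlap_distance_curve.tsv", sep="\t",
                            index=False, float_format="%.6g")
    n_bins = profile.values.size
    center_band = profile.values[n_bins // 2 - 2 : n_bins // 2 + 2].mean()
    edge_band = np.concatenate([profile.values[:10], profile.values[-10:]]).mean()
    summary["enrichment"] = {
        "n_profile_centers": profile.n_centers,
        "profile_center_signal": float(center_band),
        "profile_edge_signal": float(edge_band),
        "anchor_ezh2_overlap_fraction": anchor_peak_overlap_fraction(
            me3, ezh2, unit="per_anchor"
        ),
        "curve_fitted_rise": (
            float(curve.fitted["fraction"].iloc[-5:].mean()
                  - curve.fitted["fraction"].iloc[:5].mean())
            if curve.fitted is not None else float("nan")
        ),
    }

    # --- stage 4: contact analysis ----------------------------------------
    logger.info("stage contacts: virtual 4C, caller concordance, conservation")
    cgenome = SyntheticGenomeSpec(
        chrom_sizes={"chrV": config.contact_chrom_size},
        bin_size=10_000, seed=seed + 5,
    )
    bs = cgenome.bin_size
    # partner 20 bins from the viewpoint: with decay exponent 1 and an 8x
    # dot, the dot's expected value exceeds every bin outside a +/-5-bin
    # exclusion zone (8/21 > 1/7), so the planted contact is recoverable
    viewpoint = GenomicInterval("chrV", 100 * bs, 101 * bs)
    partner = GenomicInterval("chrV", 120 * bs, 121 * bs)
    from .core import Anchor, Loop

    planted = [
        Loop(
            Anchor(viewpoint, "left"),
            Anchor(partner, "right"),
            mark="H3K27me3",
        )
    ]
    cmatrix = make_contact_matrix(
        cgenome, planted, depth=config.contact_depth,
        decay_exponent=config.decay_exponent,
        dot_enrichment=config.dot_enrichment, seed=seed + 6,
    )
    io.write_contact_matrix(cmatrix, out / "contact_bins.bed",
                            out / "contact_triplets.tsv")
    profile4c = virtual_4c(cmatrix, viewpoint, smooth_bins=config.smooth_bins)
    np.savetxt(out / "virtual_4c.tsv",
               np.column_stack([profile4c.bin_starts, profile4c.values]),
               delimiter="\t", header="bin_start\tcpm", comments="", fmt="%.6g")
    exclusion = 5
    vbin = int(profile4c.viewpoint_bins[0])
    masked = profile4c.values.copy()
    masked[max(0, vbin - exclusion): vbin + exclusion + 1] = -np.inf
    argmax_bin = int(np.argmax(masked))
    partner_bin = partner.start // bs

    caller_b, _ = jittered_loop_set(
        me3, genome, shared_fraction=config.concordance_fraction,
        jitter_bp=config.slack_bp // 2, n_random=config.concordance_extra,
        seed=seed + 7,
    )
    concordance = match_loops(me3, caller_b, slack_bp=config.slack_bp)
    mapped, _ = jittered_loop_set(
        me3, genome, shared_fraction=config.conserved_fraction,
        jitter_bp=config.slack_bp // 2, seed=seed + 8,
    )
    conserved = conserved_loops(me3, mapped, slack_bp=config.slack_bp)
    summary["contacts"] = {
        "v4c_partner_bin": partner_bin,
        "v4c_argmax_bin_outside_viewpoint": argmax_bin,
        "v4c_partner_is_max": bool(argmax_bin == partner_bin),
        "v4c_partner_cpm": float(profile4c.values[partner_bin]),
        "caller_concordance_fraction": concordance.frac_a_shared,
        "conserved_fraction": conserved,
    }

    # --- stage 5: ORCA imaging --------------------------------------------
    logger.info("stage orca: pairwise distances and genotype comparison")
    barcodes = ["Hoxa", "Cntr", "Vax2"]
    wt = make_orca_traces(
        config.n_cells_wt, barcodes,
        {("Hoxa", "Vax2"): config.orca_contact_prob_wt},
        contact_radius=config.threshold_nm, step_sd=config.step_sd_nm,
        missing_rate=config.missing_rate, seed=seed + 9, genotype="WT",
    )
    mt = make_orca_traces(
        config.n_cells_mt, barcodes,
        {("Hoxa", "Vax2"): config.orca_contact_prob_mt},
        contact_radius=config.threshold_nm, step_sd=config.step_sd_nm,
        missing_rate=config.missing_rate, seed=seed + 10, genotype="MT",
    )
    traces = wt.concat(mt)
    io.write_orca_traces(traces, out / "orca_traces.tsv")
    wt_pair = pair_distances(wt, "Hoxa", "Vax2")
    mt_pair = pair_distances(mt, "Hoxa", "Vax2")
    med_wt, med_mt, p_orca = compare_genotypes(
        traces, ("Hoxa", "Vax2"), ("WT", "MT")
    )
    control = pair_distances(wt, "Hoxa", "Cntr")
    summary["orca"] = {
        "n_informative_wt": wt_pair.n_informative,
        "n_informative_mt": mt_pair.n_informative,
        "contact_frequency_wt": contact_frequency(wt_pair, config.threshold_nm),
        "contact_frequency_mt": contact_frequency(mt_pair, config.threshold_nm),
        "contact_frequency_control_pair": contact_frequency(
            control, config.threshold_nm
        ),
        "median_distance_nm_wt": med_wt,
        "median_distance_nm_mt": med_mt,
        "wilcoxon_p_wt_vs_mt": p_orca,
    }

    # --- stage 6: differential sites --------------------------------------
    logger.info("stage diff: classification and stratification")
    sites = make_sites(genome, config.n_sites, seed=seed + 11)
    rng = np.random.default_rng(seed + 12)
    ezh2_flags = rng.random(len(sites)) < 0.5
    ezh2_diff = IntervalSet(
        (iv for iv, f in zip(sites, ezh2_flags) if f), label="EZH2 at sites"
    )
    deletion = GenomicInterval("chr6", 52_000_000, 52_700_000)
    table, diff_truth = make_differential_table(
        sites, ezh2_diff, comps, deletion,
        effect_size=config.effect_size, seed=seed + 13,
    )
    io.write_differential_table(table, out / "differential_sites.tsv")
    diff_truth.to_csv(out / "differential_truth.tsv", sep="\t", index=False)
    cls = classify_differential_sites(table, config.fc_cut, config.p_cut)
    annotated = annotate_sites(cls, deletion, ezh2_diff, comps)
    strat = stratified_summary(annotated)
    strat.counts.to_csv(out / "stratified_counts.tsv", sep="\t", index=False)
    planted = diff_truth["planted"].to_numpy()
    down = (annotated["status"] == "down").to_numpy()
    occupied = annotated["ezh2_occupied"].to_numpy(dtype=bool)
    sensitivity = float(down[planted].mean()) if planted.any() else float("nan")
    fpr = float(down[occupied].mean()) if occupied.any() else float("nan")
    summary["differential"] = {
        "n_sites": int(len(table)),
        "n_planted": int(planted.sum()),
        "n_significant_down": int(down.sum()),
        "sensitivity": sensitivity,
        "false_positive_rate_ezh2_occupied": fpr,
        "fisher_p_down_by_ezh2": strat.fisher_p,
        "fisher_odds_ratio_down_by_ezh2": strat.fisher_odds_ratio,
    }

    # --- report ------------------------------------------------------------
    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    params = {f"config.{k}": v for k, v in asdict(config).items()}
    from . import __version__

    params["polyloop.version"] = __version__
    io.write_manifest(params, out / "manifest.txt")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
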