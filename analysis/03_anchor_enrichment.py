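"""EZH2 signal enrichment at Polycomb loop anchors and the distance trend.

Finding on the simulated dataset: signal aggregated over EZH2 peaks inside
H3K27me3 anchors shows a sharp central enrichment over background, and the
loess-smoothed fraction of loops with an EZH2-overlapping anchor rises
with loop distance.
"""

from pathlib import Path

import numpy as np

from polyloop import io
from polyloop.enrichment import aggregate_profile, center_choice, overlap_distance_curve

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    me3 = io.read_bedpe(DATA / "loops_h3k27me3.bedpe", mark="H3K27me3")
    ezh2 = io.read_bed(DATA / "ezh2_peaks.bed", label="EZH2")
    track = io.read_bedgraph(DATA / "ezh2_signal.bedgraph")

    anchors = [anc for lp in me3 for anc in (lp.left, lp.right)]
    centers = center_choice(anchors, ezh2, mode="peak_in_anchor")
    prof = aggregate_profile(centers, track, window_bp=10_000, bin_bp=50)
    np.savetxt(OUT / "anchor_profile.tsv",
               np.column_stack([prof.bin_offsets, prof.values]),
               delimiter="\t", header="offset_bp\tsignal", comments="",
               fmt="%.6g")

    curve = overlap_distance_curve(me3, ezh2, span=0.6, n_boot=200, seed=11)
    curve.fitted.to_csv(OUT / "overlap_distance_curve.tsv", sep="\t",
                        index=False, float_format="%.6g")

    mid = prof.values.size // 2
    print(f"aggregated {prof.n_centers} EZH2 peaks in anchors; "
          f"centre signal {prof.values[mid]:.4g} vs edge "
          f"{prof.values[:10].mean():.4g} (normalized depth/bp/centre)")
    f = curve.fitted
    print(f"overlap fraction rises from {f['fraction'].iloc[0]:.2f} at "
          f"10^{f['log10_distance'].iloc[0]:.1f} bp to "
          f"{f['fraction'].iloc[-1]:.2f} at 10^{f['log10_distance'].iloc[-1]:.1f} bp")


if __name__ == "__main__":
    main()
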