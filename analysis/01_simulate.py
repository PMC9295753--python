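"""Generate the synthetic study dataset every later analysis step consumes.

Emulates a two-mark HiChIP experiment in a mouse-scale genome: 2,000
H3K27ac enhancer loops and 2,000 H3K27me3 Polycomb loops (long-tailed
distances), a ~1-Mb TAD tiling grouped into A/B compartments, PRC2
nucleation points at Polycomb anchors, an EZH2 peak set, and an EZH2
signal track.  Writes plain-text files plus ground truth under
results/data/.
"""

from pathlib import Path

from polyloop import io
from polyloop.synth import (
    LoopGeneratorSpec,
    make_ezh2_peaks,
    make_loops,
    make_signal_track,
    make_tads_and_compartments,
    mouse_like_genome,
)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = mouse_like_genome(seed=SEED)
    tads, comps = make_tads_and_compartments(genome, seed=SEED + 1)
    loops, truth = make_loops(LoopGeneratorSpec(), genome, seed=SEED + 2)
    ezh2 = make_ezh2_peaks(loops, truth, seed=SEED + 3)
    track = make_signal_track(ezh2, genome, peak_height=5.0, background=0.1)

    me3 = [lp for lp in loops if lp.mark == "H3K27me3"]
    ac = [lp for lp in loops if lp.mark == "H3K27ac"]
    io.write_bedpe(me3, OUT / "loops_h3k27me3.bedpe")
    io.write_bedpe(ac, OUT / "loops_h3k27ac.bedpe")
    io.write_bed(tads, OUT / "tads.bed")
    io.write_bed(comps, OUT / "compartments.bed")
    io.write_bed(truth.nucleation_points, OUT / "nucleation_points.bed")
    io.write_bed(ezh2, OUT / "ezh2_peaks.bed")
    io.write_bedgraph(track, OUT / "ezh2_signal.bedgraph")
    truth.table.to_csv(OUT / "loop_ground_truth.tsv", sep="\t", index=False)
    io.write_manifest(
        {"seed": SEED, "n_short": 2000, "n_long": 2000,
         "genome": "mouse-like 19 autosomes"},
        OUT / "manifest.txt",
    )
    print(f"wrote {len(me3)} H3K27me3 and {len(ac)} H3K27ac loops, "
          f"{len(tads)} TADs, {len(ezh2)} EZH2 peaks to {OUT}")


if __name__ == "__main__":
    main()
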