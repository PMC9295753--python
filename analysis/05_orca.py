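"""ORCA 3D distance analysis of a long-range loop in WT and anchor-deleted cells.

Finding on the simulated dataset: with a 40% planted contact probability,
~40% of informative WT cells show the probe pair within 150 nm; deleting
the anchor (5% contact probability) significantly increases the pairwise
distance (Wilcoxon), while the control pair shows background contact only.
"""

from pathlib import Path

import numpy as np

from polyloop import io
from polyloop.orca import compare_genotypes, contact_frequency, pair_distances
from polyloop.synth import make_orca_traces

SEED = 7
DATA = Path(__file__).resolve().parents[1] / "results" / "data"

BARCODES = ["Hoxa", "Cntr", "Vax2"]


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    wt = make_orca_traces(2190, BARCODES, {("Hoxa", "Vax2"): 0.40},
                          contact_radius=150.0, step_sd=400.0,
                          missing_rate=0.05, seed=SEED, genotype="WT")
    mt = make_orca_traces(520, BARCODES, {("Hoxa", "Vax2"): 0.05},
                          contact_radius=150.0, step_sd=400.0,
                          missing_rate=0.05, seed=SEED + 1, genotype="MT")
    traces = wt.concat(mt)
    io.write_orca_traces(traces, DATA / "orca_traces.tsv")

    res_wt = pair_distances(wt, "Hoxa", "Vax2")
    res_ct = pair_distances(wt, "Hoxa", "Cntr")
    med_wt, med_mt, p = compare_genotypes(traces, ("Hoxa", "Vax2"),
                                          ("WT", "MT"))
    print(f"WT Hoxa-Vax2: {res_wt.n_informative} informative cells, "
          f"contact (<150 nm) in {100 * contact_frequency(res_wt):.1f}%")
    print(f"WT Hoxa-Cntr control: contact in "
          f"{100 * contact_frequency(res_ct):.1f}%")
    print(f"median distance WT {med_wt:.0f} nm vs anchor-deleted {med_mt:.0f} nm, "
          f"Wilcoxon p = {p:.3g}")


if __name__ == "__main__":
    main()
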