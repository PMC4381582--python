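#!/usr/bin/env python
"""Run the screen statistics chain and call synthetic-lethality hits.

Reads the well table written by 01_simulate_screen.py (re-simulating it if
absent), normalizes each plate to its negative controls, computes
median-centered robust z-scores per plate, pairs per-gene siRNA z-vectors
across the two cell lines and applies the concordance rule: a gene is a hit
when >= 2 siRNAs score z < -2 in the c-Myc-overexpressing line and the mean
z difference between lines is <= -1.

Writes hits and the hit z-score matrix under results/, the full z-score
table under scratch/, and reports recovery against the planted truth.
"""

from pathlib import Path

import pandas as pd

from sylscreen import ScreenSimConfig, read_screen_table, run_screen, simulate_screen, write_table

ROOT = Path(__file__).resolve().parents[1]
LINE_OVER, LINE_CTRL = "M2.1", "V11"


def main() -> None:
    wells_csv = ROOT / "scratch" / "screen_wells.csv"
    if wells_csv.exists():
        ds = read_screen_table(wells_csv)
    else:
        print("well table missing; re-simulating with seed 1")
        ds, _ = simulate_screen(ScreenSimConfig(seed=1))

    res = run_screen(ds, LINE_OVER, LINE_CTRL)

    results = ROOT / "results"
    zcols = ["cell_line", "gene", "sirna_id", "sf", "zscore", "plate_id"]
    write_table(res["zscores"][zcols], ROOT / "scratch" / "screen_zscores.csv")
    write_table(res["hits"], results / "screen_hits.csv")
    res["matrix"].to_csv(results / "screen_hit_matrix.csv")

    hits = res["hit_genes"]
    print(f"{len(hits)} hit gene(s): {', '.join(hits)}")
    truth_csv = results / "screen_truth.csv"
    if truth_csv.exists():
        truth = pd.read_csv(truth_csv)
        planted = set(truth.loc[truth["synthetic_lethal"], "gene"])
        tp = len(set(hits) & planted)
        print(f"recovery vs planted truth: {tp}/{len(planted)} recovered, "
              f"{len(set(hits) - planted)} false positive(s)")
    for c in res["calls"]:
        if c.hit:
            zs = ", ".join(f"{z:.1f}" for z in sorted(c.z_by_sirna_overexpr))
            print(f"  {c.gene}: z_overexpr = [{zs}], selectivity = {c.selectivity:.1f}")


if __name__ == "__main__":
    main()
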