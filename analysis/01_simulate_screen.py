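#!/usr/bin/env python
"""Generate the default synthetic kinome screen.

Emulates the study conditions: 719 genes x 3 siRNAs plated in triplicate in
two paired DAOY clones (M2.1 c-Myc-overexpressing, V11 empty vector), 80
sample + 16 control wells per 96-well plate, a 5-gene planted
synthetic-lethal set (surviving fraction 0.4 in M2.1, 1.0 in V11), 2%
off-target siRNAs, 5% well noise and 5% plate effects.

Writes the full well table and per-well truth under scratch/ (large) and
the gene-level truth labels under results/.
"""

from pathlib import Path

import pandas as pd

from sylscreen import ScreenSimConfig, simulate_screen, validate_controls, write_table

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = ScreenSimConfig(seed=SEED)
    ds, truth = simulate_screen(cfg)

    scratch = ROOT / "scratch"
    results = ROOT / "results"
    write_table(ds, scratch / "screen_wells.csv")
    write_table(truth.true_sf, scratch / "screen_true_sf.csv")
    labels = pd.DataFrame(
        {"gene": list(truth.labels), "synthetic_lethal": list(truth.labels.values())}
    )
    write_table(labels, results / "screen_truth.csv")

    qc = validate_controls(ds)
    print(f"simulated {len(ds.wells)} wells on {ds.n_plates} plates "
          f"({cfg.n_genes} genes x {cfg.sirnas_per_gene} siRNAs x "
          f"{cfg.n_replicate_wells} replicate wells x 2 cell lines, seed {SEED})")
    print(f"planted synthetic-lethal genes: {', '.join(truth.planted_genes)}")
    print(f"off-target siRNAs: {len(truth.offtarget_sirnas)}")
    print(f"QC: {len(qc)} plates, {int(qc['fatal'].sum())} fatal")
    print(f"wells -> {scratch / 'screen_wells.csv'}")


if __name__ == "__main__":
    main()
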