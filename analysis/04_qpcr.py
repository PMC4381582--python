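#!/usr/bin/env python
"""ddCt fold changes for a simulated siRNA knockdown experiment.

Emulates the validation qPCR: a reference (non-targeting siRNA) sample and
two knockdown samples per target gene, 18S + beta-actin housekeeping,
triplicate technical replicates, 0.15-cycle Ct noise. A planted 4-fold
knockdown should come back as fold change ~0.25.
"""

from pathlib import Path

import pandas as pd

from sylscreen import fold_changes, log2_normalize_to_reference, simulate_qpcr, write_table

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
TARGETS = {"AKAP12": 0.25, "CSNK1A1": 0.30, "EPHA7": 0.25, "PCTK1": 0.20}


def main() -> None:
    rows = []
    for sample, factor in (("siCtrl", 1.0), ("siRNA_1", 1.0), ("siRNA_2", 1.0)):
        for gene in ("18S", "ACTB"):
            rows.append({"sample": sample, "gene": gene, "fold": 1.0})
    for gene, kd in TARGETS.items():
        rows.append({"sample": "siCtrl", "gene": gene, "fold": 1.0})
        rows.append({"sample": "siRNA_1", "gene": gene, "fold": kd})
        rows.append({"sample": "siRNA_2", "gene": gene, "fold": min(1.0, kd * 1.5)})
    design = pd.DataFrame(rows)

    records = simulate_qpcr(design, ["18S", "ACTB"], ct_noise_sd=0.15, seed=SEED)
    folds = fold_changes(records, ["18S", "ACTB"], "siCtrl")
    folds = log2_normalize_to_reference(folds, "siCtrl")
    write_table(folds, ROOT / "results" / "qpcr_folds.csv")

    print("knockdown fold changes vs siCtrl (18S+ACTB housekeeping):")
    for gene in TARGETS:
        sub = folds[folds["gene"] == gene].set_index("sample")
        print(f"  {gene}: siRNA_1 = {sub.loc['siRNA_1', 'fold_change']:.2f} "
              f"(planted {TARGETS[gene]:.2f}), "
              f"siRNA_2 = {sub.loc['siRNA_2', 'fold_change']:.2f}")


if __name__ == "__main__":
    main()
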