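"""Relative qPCR quantification by the comparative-Ct (ddCt) method.

Technical replicates are averaged per (sample, gene); each target gene is
normalized to the arithmetic mean Ct of the housekeeping genes (equivalent
to the geometric mean of their expression), then to a reference sample:

    dCt  = Ct(target) - mean(Ct(housekeeping))
    ddCt = dCt(sample) - dCt(reference sample)
    fold = efficiency ** (-ddCt)          (efficiency 2 = perfect doubling)

A uniform Ct shift of a whole sample (pipetting offset) cancels in dCt, so
fold changes are invariant to it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sylscreen.errors import IntegrityError


def fold_changes(
    records: pd.DataFrame,
    housekeeping: list[str],
    reference_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-(sample, gene) fold change relative to ``reference_sample``.

    ``records`` needs columns ``sample, gene, ct`` (``replicate`` optional;
    replicates are averaged first). Housekeeping genes are excluded from the
    output. The reference sample's own fold changes are exactly 1.

    Raises
    ------
    ValueError
        if the reference sample is absent.
    IntegrityError
        if any sample lacks a housekeeping measurement.
    """
    req = {"sample", "gene", "ct"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if reference_sample not in set(records["sample"]):
        raise ValueError(f"unknown reference sample {reference_sample!r}")
    if not housekeeping:
        raise ValueError("at least one housekeeping gene is required")

    mean_ct = records.groupby(["sample", "gene"], sort=True)["ct"].mean().unstack("gene")
    for hk in housekeeping:
        if hk not in mean_ct.columns or mean_ct[hk].isna().any():
            missing = (
                mean_ct.index[mean_ct[hk].isna()].tolist()
                if hk in mean_ct.columns
                else mean_ct.index.tolist()
            )
            raise IntegrityError(
                f"housekeeping gene {hk!r} not measured in sample(s) {missing}"
            )

    hk_mean = mean_ct[list(housekeeping)].mean(axis=1)
    targets = [g for g in mean_ct.columns if g not in set(housekeeping)]
    dct = mean_ct[targets].sub(hk_mean, axis=0)
    ddct = dct.sub(dct.loc[reference_sample], axis=1)
    fold = np.power(float(efficiency), -ddct)

    out = fold.stack().rename("fold_change").reset_index()
    out = out.merge(ddct.stack().rename("ddct").reset_index(), on=["sample", "gene"])
    return out[["sample", "gene", "ddct", "fold_change"]].sort_values(
        ["gene", "sample"], kind="mergesort", ignore_index=True
    )


def log2_normalize_to_reference(
    folds: pd.DataFrame, reference_sample: str
) -> pd.DataFrame:
    """log2 of fold changes, anchoring the reference sample at exactly 0.

    Raises
    ------
    ValueError
        on non-positive fold changes (log undefined).
    """
    if (folds["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive for log2 normalization")
    out = folds.copy()
    out["log2_fold"] = np.log2(out["fold_change"].to_numpy(dtype=float))
    out.loc[out["sample"] == reference_sample, "log2_fold"] = 0.0
    return out
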