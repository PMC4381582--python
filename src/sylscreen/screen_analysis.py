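"""Statistical chain of the paired-line viability screen.

Four stages, each a pure function over long-format tables:

1. ``surviving_fractions`` — each well's reading divided by the median
   negative-control (non-targeting siRNA) reading on the same plate.
2. ``median_centered_zscores`` — robust standardization of surviving
   fractions, (sf - stratum median) / scale, with the scale estimated from
   sample wells only (1.4826*MAD by default, SD optional).
3. ``aggregate_genes`` — per-gene paired z-vectors across the
   overexpressing and control cell lines.
4. ``call_hits`` — the synthetic-lethality decision: a gene is a hit when
   at least ``min_concordant`` of its siRNAs score below ``threshold`` in
   the overexpressing line AND the mean z difference between lines is at
   most ``selectivity_margin``. Requiring concordant independent siRNAs
   guards against single-duplex off-target artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sylscreen.errors import InsufficientDataError, NormalizationError
from sylscreen.plate_io import ScreenDataset

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826  # makes MAD a consistent sigma estimator under normality


def surviving_fractions(ds: ScreenDataset) -> pd.DataFrame:
    """Normalize every well to the per-plate median of negative controls.

    Returns a long table ``cell_line, plate_id, gene, sirna_id, role, sf``
    covering sample *and* control wells (neg controls get sf with median 1
    by construction).

    Raises
    ------
    NormalizationError
        if any plate lacks negative-control wells, or their median reading
        is zero (degenerate plate).
    """
    wells = ds.wells.reset_index(drop=True)
    out = wells[["cell_line", "plate_id", "gene", "sirna_id", "role"]].copy()
    sf = np.empty(len(wells), dtype=float)
    for (line, plate), grp in wells.groupby(["cell_line", "plate_id"], sort=False):
        neg = grp.loc[grp["role"] == "neg_control", "reading"]
        if neg.empty:
            raise NormalizationError(
                f"plate {plate!r} (cell line {line!r}) has no neg_control wells"
            )
        center = float(neg.median())
        if center <= 0:
            raise NormalizationError(
                f"plate {plate!r} (cell line {line!r}) has a degenerate "
                f"neg_control median of {center}"
            )
        sf[grp.index] = grp["reading"].to_numpy() / center
    out["sf"] = sf
    return out


def _scale_estimate(values: np.ndarray, scale: str) -> float:
    if scale == "mad":
        med = np.median(values)
        return MAD_CONSISTENCY * float(np.median(np.abs(values - med)))
    if scale == "sd":
        return float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    raise ValueError(f"unknown scale estimator {scale!r}")


def median_centered_zscores(
    sf: pd.DataFrame,
    stratify: str = "per_plate",
    scale: str = "mad",
) -> pd.DataFrame:
    """Median-centered z-scores of surviving fractions.

    z = (sf - median(sample sf in stratum)) / scale_estimate. Center and
    scale are estimated from *sample* wells only; control wells are still
    scored against them. Strata are plates (default, guarding against plate
    effects) or whole cell lines.

    A stratum whose MAD is zero falls back to the SD with a logged warning;
    if both are zero every z in the stratum is set to 0.

    Raises
    ------
    InsufficientDataError
        if a stratum holds fewer than 4 sample wells.
    """
    if stratify == "per_plate":
        keys = ["cell_line", "plate_id"]
    elif stratify == "per_cell_line":
        keys = ["cell_line"]
    else:
        raise ValueError(f"unknown stratification {stratify!r}")

    sf = sf.reset_index(drop=True)
    out = sf.copy()
    z = np.empty(len(sf), dtype=float)
    for key, grp in sf.groupby(keys, sort=False):
        samp = grp.loc[grp["role"] == "sample", "sf"].to_numpy()
        if samp.size < 4:
            raise InsufficientDataError(
                f"stratum {key} has only {samp.size} sample wells (need >= 4)"
            )
        center = float(np.median(samp))
        spread = _scale_estimate(samp, scale)
        if spread == 0.0 and scale == "mad":
            logger.warning("stratum %s: zero MAD, falling back to sd", key)
            spread = _scale_estimate(samp, "sd")
        if spread == 0.0:
            logger.warning("stratum %s: zero scale, all z set to 0", key)
            z[grp.index] = 0.0
        else:
            z[grp.index] = (grp["sf"].to_numpy() - center) / spread
    out["zscore"] = z
    return out[["cell_line", "gene", "sirna_id", "plate_id", "sf", "zscore", "role"]]


@dataclass
class GenePairedZ:
    """Ordered siRNA z-score vectors for one gene in both cell lines."""

    gene: str
    sirna_ids: list[str]
    z_overexpr: list[float]
    z_control: list[float]
    line_overexpr: str
    line_control: str


def aggregate_genes(
    z: pd.DataFrame,
    line_overexpr: str,
    line_control: str,
) -> tuple[list[GenePairedZ], pd.DataFrame]:
    """Pair each gene's siRNA z-scores across the two cell lines.

    Only sample wells contribute. siRNAs measured more than once per line
    (replicate wells) are averaged. Returns the paired records plus a
    missing-data report listing every (gene, sirna_id) absent from either
    line; genes with no complete siRNA pair are reported, never silently
    dropped, and never eligible as hits.

    Raises
    ------
    ValueError
        if a requested cell line is absent from the table.
    """
    lines = set(z["cell_line"].unique())
    for ln in (line_overexpr, line_control):
        if ln not in lines and len(z):
            raise ValueError(f"cell line {ln!r} not present in z-score table")

    samples = z[z["role"] == "sample"] if "role" in z.columns else z
    mean_z = (
        samples.groupby(["cell_line", "gene", "sirna_id"], sort=True)["zscore"]
        .mean()
        .unstack("cell_line")
        if len(samples)
        else pd.DataFrame()
    )

    records: list[GenePairedZ] = []
    missing_rows: list[dict] = []
    if mean_z.empty:
        return records, pd.DataFrame(columns=["gene", "sirna_id", "missing_in"])

    for gene, grp in mean_z.groupby(level="gene", sort=True):
        sirnas, z_over, z_ctrl = [], [], []
        for (_, sirna), row in grp.iterrows():
            over = row.get(line_overexpr, np.nan)
            ctrl = row.get(line_control, np.nan)
            if np.isnan(over) or np.isnan(ctrl):
                missing_in = line_overexpr if np.isnan(over) else line_control
                missing_rows.append(
                    {"gene": gene, "sirna_id": sirna, "missing_in": missing_in}
                )
                continue
            sirnas.append(sirna)
            z_over.append(float(over))
            z_ctrl.append(float(ctrl))
        if sirnas:
            records.append(
                GenePairedZ(gene, sirnas, z_over, z_ctrl, line_overexpr, line_control)
            )
    report = pd.DataFrame(missing_rows, columns=["gene", "sirna_id", "missing_in"])
    return records, report


@dataclass
class GeneHitCall:
    """Hit decision for one gene with its full evidence."""

    gene: str
    sirna_ids: list[str]
    z_by_sirna_overexpr: list[float]
    z_by_sirna_control: list[float]
    n_below_threshold: int
    selectivity: float
    hit: bool
    line_overexpr: str = ""
    line_control: str = ""
    mean_z_overexpr: float = field(default=np.nan)


def call_hits(
    genes: list[GenePairedZ],
    threshold: float = -2.0,
    min_concordant: int = 2,
    selectivity_margin: float = -1.0,
) -> list[GeneHitCall]:
    """Synthetic-lethality hit calling over paired per-gene z-vectors.

    A gene is a hit iff strictly fewer-than-threshold z-scores occur for at
    least ``min_concordant`` distinct siRNAs in the overexpressing line
    (z < threshold, strict) AND its selectivity — mean z in the
    overexpressing line minus mean z in the control line — is at most
    ``selectivity_margin``, i.e. viability drops specifically in the
    overexpressing background.

    Every gene is returned with its decision and evidence, sorted by
    ascending mean overexpressing-line z (strongest first).
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative")
    if min_concordant < 1:
        raise ValueError("min_concordant must be >= 1")

    calls: list[GeneHitCall] = []
    for g in genes:
        z_over = np.asarray(g.z_overexpr, dtype=float)
        z_ctrl = np.asarray(g.z_control, dtype=float)
        n_below = int(np.sum(z_over < threshold))
        selectivity = float(z_over.mean() - z_ctrl.mean())
        hit = (n_below >= min_concordant) and (selectivity <= selectivity_margin)
        calls.append(
            GeneHitCall(
                gene=g.gene,
                sirna_ids=list(g.sirna_ids),
                z_by_sirna_overexpr=[float(v) for v in z_over],
                z_by_sirna_control=[float(v) for v in z_ctrl],
                n_below_threshold=n_below,
                selectivity=selectivity,
                hit=hit,
                line_overexpr=g.line_overexpr,
                line_control=g.line_control,
                mean_z_overexpr=float(z_over.mean()),
            )
        )
    calls.sort(key=lambda c: (c.mean_z_overexpr, c.gene))
    return calls


def hits_table(calls: list[GeneHitCall]) -> pd.DataFrame:
    """Flat hit-call table in the exchange schema
    ``gene,n_sirnas_below,hit,min_z_line_a,min_z_line_b,selectivity``
    (line a = overexpressing, line b = control)."""
    rows = [
        {
            "gene": c.gene,
            "n_sirnas_below": c.n_below_threshold,
            "hit": c.hit,
            "min_z_line_a": min(c.z_by_sirna_overexpr) if c.z_by_sirna_overexpr else np.nan,
            "min_z_line_b": min(c.z_by_sirna_control) if c.z_by_sirna_control else np.nan,
            "selectivity": c.selectivity,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "n_sirnas_below", "hit", "min_z_line_a", "min_z_line_b", "selectivity"],
    )


def run_screen(
    ds: ScreenDataset,
    line_overexpr: str,
    line_control: str,
    stratify: str = "per_plate",
    scale: str = "mad",
    threshold: float = -2.0,
    min_concordant: int = 2,
    selectivity_margin: float = -1.0,
) -> dict:
    """Full screen chain: normalization -> z-scores -> pairing -> hit calls.

    Returns a dict with the intermediate tables (``sf``, ``zscores``,
    ``missing``), the per-gene ``calls``, the flat ``hits`` table, the list
    of ``hit_genes`` and the hit ``matrix``.
    """
    sf = surviving_fractions(ds)
    z = median_centered_zscores(sf, stratify=stratify, scale=scale)
    paired, missing = aggregate_genes(z, line_overexpr, line_control)
    calls = call_hits(
        paired,
        threshold=threshold,
        min_concordant=min_concordant,
        selectivity_margin=selectivity_margin,
    )
    return {
        "sf": sf,
        "zscores": z,
        "missing": missing,
        "calls": calls,
        "hits": hits_table(calls),
        "hit_genes": [c.gene for c in calls if c.hit],
        "matrix": hit_matrix(calls),
    }


def hit_matrix(calls: list[GeneHitCall]) -> pd.DataFrame:
    """Gene x (cell_line, siRNA slot) z-score matrix restricted to hits.

    Rows are hit genes in ascending mean overexpressing-line z; columns are
    ``<line>:sirna<k>`` for each siRNA slot in each line, ready for
    heat-map rendering. No hits yields a 0-row frame with the header.
    """
    hits = [c for c in calls if c.hit]
    hits.sort(key=lambda c: (c.mean_z_overexpr, c.gene))
    n_slots = max((len(c.sirna_ids) for c in hits), default=3)
    lines = (
        (hits[0].line_overexpr, hits[0].line_control) if hits else ("overexpr", "control")
    )
    columns = [f"{line}:sirna{k + 1}" for line in lines for k in range(n_slots)]
    rows = {}
    for c in hits:
        vals = []
        for zvec in (c.z_by_sirna_overexpr, c.z_by_sirna_control):
            vals.extend(list(zvec) + [np.nan] * (n_slots - len(zvec)))
        rows[c.gene] = vals
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    mat.index.name = "gene"
    return mat
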