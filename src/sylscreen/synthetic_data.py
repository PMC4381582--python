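"""Seeded generators for every pipeline stage.

The screen generator emulates a kinome-scale library (719 genes x 3 siRNAs)
screened in a paired pair of cell lines — one c-Myc-overexpressing, one
empty-vector control — on 96-well plates carrying non-targeting negative
controls plus positive and cell-death controls. A small planted gene set is
synthetic-lethal (low surviving fraction in the overexpressing line only);
a fraction of library siRNAs additionally carry an off-target toxicity of
random severity. Off-target toxicity is a property of the siRNA sequence,
so a rogue duplex depresses viability in *both* lines: the concordance rule
(>= 2 independent siRNAs) rejects it at the gene level and the selectivity
margin rejects line-unspecific kills. Well readings are
``plate_effect * true_sf * (1 + N(0, well_noise_sd))`` floored at zero.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sylscreen.errors import ConfigError
from sylscreen.plate_io import ROW_LETTERS, ScreenDataset, _validate_wells

PLATE_ROWS = len(ROW_LETTERS)  # 8
PLATE_COLS = 12
PLATE_WELLS = PLATE_ROWS * PLATE_COLS  # 96


@dataclass
class ScreenSimConfig:
    """Generative model of the paired-line kinome viability screen."""

    n_genes: int = 719
    sirnas_per_gene: int = 3
    n_replicate_wells: int = 3  # cells are plated in triplicate per siRNA
    line_overexpr: str = "M2.1"
    line_control: str = "V11"
    plate_sample_capacity: int = 80
    n_neg_control: int = 8
    n_pos_control: int = 4
    n_death_control: int = 4
    planted_genes: tuple = ()  # empty = pick n_planted at random
    n_planted: int = 5
    planted_sf_overexpr: float = 0.4
    planted_sf_control: float = 1.0
    offtarget_rate: float = 0.02
    offtarget_sf_range: tuple = (0.3, 1.0)
    well_noise_sd: float = 0.05
    plate_effect_sd: float = 0.05
    pos_control_sf: float = 0.3
    death_control_sf: float = 0.05
    baseline_reading: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < max(self.n_planted, len(self.planted_genes)):
            raise ConfigError("planted gene set larger than the library")
        for name, val in (
            ("planted_sf_overexpr", self.planted_sf_overexpr),
            ("planted_sf_control", self.planted_sf_control),
            ("offtarget_rate", self.offtarget_rate),
            ("pos_control_sf", self.pos_control_sf),
            ("death_control_sf", self.death_control_sf),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {val}")
        if self.well_noise_sd < 0 or self.plate_effect_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.n_replicate_wells < 1:
            raise ConfigError("n_replicate_wells must be >= 1")
        n_ctrl = self.n_neg_control + self.n_pos_control + self.n_death_control
        if self.plate_sample_capacity + n_ctrl > PLATE_WELLS:
            raise ConfigError("plate layout exceeds 96 wells")


@dataclass
class ScreenTruth:
    """Ground truth of one simulated screen for recovery scoring."""

    labels: dict  # gene -> bool (synthetic-lethal)
    true_sf: pd.DataFrame  # per-well latent surviving fraction
    planted_genes: tuple = ()
    offtarget_sirnas: tuple = ()

    @property
    def sl_genes(self) -> set:
        return {g for g, lab in self.labels.items() if lab}


def _library(cfg: ScreenSimConfig) -> pd.DataFrame:
    genes = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    rows = [
        {"gene": g, "sirna_id": f"{g}_si{j}"}
        for g in genes
        for j in range(1, cfg.sirnas_per_gene + 1)
    ]
    return pd.DataFrame(rows)


def _well_positions(n: int):
    """First ``n`` row-major positions of a 96-well plate."""
    return [(ROW_LETTERS[k // PLATE_COLS], k % PLATE_COLS + 1) for k in range(n)]


def simulate_screen(cfg: ScreenSimConfig) -> tuple[ScreenDataset, ScreenTruth]:
    """Generate one paired-line screen and its ground truth.

    Library siRNAs fill plates sequentially (sample wells first, then the
    control block); each plate is replicated ``n_replicate_wells`` times
    (cells plated in triplicate by default) and the same layout is screened
    once per cell line on its own physical plates, mirroring a paired-clone
    design. Deterministic for a given config (bit-identical reruns).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib = _library(cfg)
    genes = lib["gene"].unique()

    if cfg.planted_genes:
        planted = tuple(cfg.planted_genes)
        unknown = set(planted) - set(genes)
        if unknown:
            raise ConfigError(f"planted gene(s) not in library: {sorted(unknown)}")
    else:
        planted = tuple(sorted(rng.choice(genes, size=cfg.n_planted, replace=False)))
    planted_set = set(planted)

    # siRNA-intrinsic off-target toxicity, shared by both lines
    is_rogue = rng.random(len(lib)) < cfg.offtarget_rate
    severity = rng.uniform(*cfg.offtarget_sf_range, size=len(lib))
    offtarget_factor = np.where(is_rogue, severity, 1.0)

    sf_over = np.where(lib["gene"].isin(planted_set), cfg.planted_sf_overexpr, 1.0)
    sf_ctrl = np.where(lib["gene"].isin(planted_set), cfg.planted_sf_control, 1.0)
    true_sf_by_line = {
        cfg.line_overexpr: sf_over * offtarget_factor,
        cfg.line_control: sf_ctrl * offtarget_factor,
    }

    n_plates = int(np.ceil(len(lib) / cfg.plate_sample_capacity))
    control_roles = (
        ["neg_control"] * cfg.n_neg_control
        + ["pos_control"] * cfg.n_pos_control
        + ["death_control"] * cfg.n_death_control
    )
    control_sf = {
        "neg_control": 1.0,
        "pos_control": cfg.pos_control_sf,
        "death_control": cfg.death_control_sf,
    }

    well_rows: list[dict] = []
    truth_rows: list[dict] = []
    for line in (cfg.line_overexpr, cfg.line_control):
        tsf = true_sf_by_line[line]
        for p, rep in (
            (p, rep) for p in range(n_plates) for rep in range(1, cfg.n_replicate_wells + 1)
        ):
            plate_id = f"{line}-P{p + 1:02d}r{rep}"
            plate_effect = float(np.exp(rng.normal(0.0, cfg.plate_effect_sd)))
            lo = p * cfg.plate_sample_capacity
            hi = min(lo + cfg.plate_sample_capacity, len(lib))
            chunk = lib.iloc[lo:hi]
            positions = _well_positions(len(chunk) + len(control_roles))
            entries = [
                (chunk.iloc[k]["gene"], chunk.iloc[k]["sirna_id"], "sample", tsf[lo + k])
                for k in range(len(chunk))
            ] + [("", "", role, control_sf[role]) for role in control_roles]
            noise = rng.normal(0.0, cfg.well_noise_sd, size=len(entries))
            for (gene, sirna, role, true_sf), (row, col), eps in zip(entries, positions, noise):
                reading = max(0.0, cfg.baseline_reading * plate_effect * true_sf * (1.0 + eps))
                well_rows.append(
                    {
                        "plate_id": plate_id,
                        "row": row,
                        "col": col,
                        "cell_line": line,
                        "sirna_id": sirna,
                        "gene": gene,
                        "role": role,
                        "reading": reading,
                    }
                )
                truth_rows.append(
                    {
                        "plate_id": plate_id,
                        "row": row,
                        "col": col,
                        "cell_line": line,
                        "gene": gene,
                        "sirna_id": sirna,
                        "role": role,
                        "true_sf": float(true_sf),
                    }
                )

    ds = ScreenDataset(wells=_validate_wells(pd.DataFrame(well_rows)))
    truth = ScreenTruth(
        labels={g: g in planted_set for g in genes},
        true_sf=pd.DataFrame(truth_rows),
        planted_genes=planted,
        offtarget_sirnas=tuple(lib.loc[is_rogue, "sirna_id"]),
    )
    return ds, truth


def simulate_dose_response(
    true_fit: dict,
    doses,
    noise_sd: float = 3.0,
    n_series: int = 1,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Noisy 4PL titration series from known parameters.

    ``true_fit`` holds ``bottom, top, hill, ic50`` (molar). Each series is a
    DataFrame ``concentration, response`` with Gaussian noise of ``noise_sd``
    percentage points on the 4PL mean. Deterministic per seed.
    """
    from sylscreen.dose_response import four_pl

    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ConfigError("dose list must be non-empty")
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive (molar)")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")

    mean = four_pl(
        doses,
        true_fit["bottom"],
        true_fit["top"],
        true_fit["hill"],
        np.log10(true_fit["ic50"]),
    )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_series):
        resp = mean + rng.normal(0.0, noise_sd, size=doses.size)
        out.append(pd.DataFrame({"concentration": doses, "response": resp}))
    return out


def simulate_qpcr(
    design: pd.DataFrame,
    housekeeping: list[str],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    base_ct: float = 20.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ct records from a (sample, gene, fold) expression design.

    ``fold`` is expression relative to one unit of baseline; Ct is generated
    as ``base_ct - log2(fold) + noise`` with ``n_replicates`` technical
    replicates per (sample, gene). Housekeeping genes must be present in the
    design with fold 1 (no effect) for every sample.
    """
    req = {"sample", "gene", "fold"}
    if not req.issubset(design.columns):
        raise ConfigError(f"design must have columns {sorted(req)}")
    hk = design[design["gene"].isin(housekeeping)]
    if set(hk["gene"]) != set(housekeeping):
        raise ConfigError("every housekeeping gene must appear in the design")
    if not np.allclose(hk["fold"], 1.0):
        raise ConfigError("housekeeping genes must have fold 1 (zero effect)")
    if (design["fold"] <= 0).any():
        raise ConfigError("fold values must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for rec in design.itertuples(index=False):
        base = getattr(rec, "base_ct", None)
        base = base_ct if base is None or (isinstance(base, float) and np.isnan(base)) else base
        clean_ct = float(base) - float(np.log2(rec.fold))
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": rec.sample,
                    "gene": rec.gene,
                    "ct": clean_ct + float(rng.normal(0.0, ct_noise_sd)),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_cam(
    n_per_group: int,
    growth_rates: dict,
    cell_line: str = "M2.1",
    pre_diameter_mm: float = 3.0,
    diameter_sd_log: float = 0.15,
    noise_sd_log: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """CAM tumor diameter table from per-group growth factors.

    ``growth_rates`` maps group name (e.g. vehicle/treated) to the
    multiplicative diameter factor between pre- and post-treatment imaging;
    a factor below 1 produces predominantly shrinking tumors. Pre-treatment
    diameters are lognormal around ``pre_diameter_mm``.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    if any(f <= 0 for f in growth_rates.values()):
        raise ConfigError("growth factors must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for group in growth_rates:  # insertion order: deterministic
        factor = growth_rates[group]
        for _ in range(n_per_group):
            k += 1
            d_pre = pre_diameter_mm * np.exp(rng.normal(0.0, diameter_sd_log, size=2))
            d_post = d_pre * factor * np.exp(rng.normal(0.0, noise_sd_log, size=2))
            rows.append(
                {
                    "embryo_id": f"E{k:03d}",
                    "group": group,
                    "cell_line": cell_line,
                    "d1_pre": float(d_pre[0]),
                    "d2_pre": float(d_pre[1]),
                    "d1_post": float(d_post[0]),
                    "d2_post": float(d_post[1]),
                }
            )
    return pd.DataFrame(rows)
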