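import numpy as np
import pandas as pd
import pytest

from sylscreen import ScreenSimConfig, run_screen, simulate_screen


def make_plate_csv(
    plate_id="P01",
    cell_line="M2.1",
    n_genes=20,
    sirnas_per_gene=4,
    n_neg=8,
    n_pos=4,
    n_death=4,
    seed=0,
):
    """Small single-plate screen CSV (text) with 80 sample + 16 control wells."""
    rng = np.random.default_rng(seed)
    rows = ["plate_id,row,col,cell_line,sirna_id,gene,role,reading"]
    letters = "ABCDEFGH"
    k = 0

    def pos(k):
        return letters[k // 12], k % 12 + 1

    for g in range(1, n_genes + 1):
        for s in range(1, sirnas_per_gene + 1):
            r, c = pos(k)
            k += 1
            reading = rng.normal(1.0, 0.05)
            rows.append(f"{plate_id},{r},{c},{cell_line},G{g:03d}_si{s},G{g:03d},sample,{reading}")
    for role, n in (("neg_control", n_neg), ("pos_control", n_pos), ("death_control", n_death)):
        base = {"neg_control": 1.0, "pos_control": 0.3, "death_control": 0.05}[role]
        for _ in range(n):
            r, c = pos(k)
            k += 1
            reading = max(0.0, rng.normal(base, 0.02))
            rows.append(f"{plate_id},{r},{c},{cell_line},,,{role},{reading}")
    return "\n".join(rows) + "\n"


@pytest.fixture
def plate_csv():
    return make_plate_csv()


@pytest.fixture(scope="session")
def default_screen():
    """Default synthetic screen (seed 1) and its truth, shared across tests."""
    cfg = ScreenSimConfig(seed=1)
    ds, truth = simulate_screen(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_screen_result(default_screen):
    cfg, ds, truth = default_screen
    return run_screen(ds, cfg.line_overexpr, cfg.line_control)


@pytest.fixture
def qpcr_design():
    return pd.DataFrame(
        [
            {"sample": "reference", "gene": "18S", "fold": 1.0},
            {"sample": "reference", "gene": "ACTB", "fold": 1.0},
            {"sample": "reference", "gene": "PCTK1", "fold": 1.0},
            {"sample": "knockdown", "gene": "18S", "fold": 1.0},
            {"sample": "knockdown", "gene": "ACTB", "fold": 1.0},
            {"sample": "knockdown", "gene": "PCTK1", "fold": 0.25},
        ]
    )
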