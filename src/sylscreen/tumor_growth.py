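"""CAM xenograft tumor-volume estimation and pre/post growth analysis.

Tumors growing on the chick chorio-allantoic membrane are measured by two
perpendicular external diameters d1, d2 (mm). Volume assumes a sphere with
the geometric-mean radius,

    V = (4/3) * pi * r**3,   r = 0.5 * sqrt(d1 * d2)

(``radius_rule="geomean"``; ``"single_diameter"`` uses r = d1/2 instead).
Growth is the volume change between pre- and post-treatment measurements;
a tumor regresses iff delta_v < 0 (strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RADIUS_RULES = ("geomean", "single_diameter")


def tumor_volume(d1, d2, radius_rule: str = "geomean"):
    """Estimated tumor volume (mm^3) from two perpendicular diameters (mm).

    Symmetric in (d1, d2) under the default geometric-mean rule and strictly
    increasing in each diameter.

    Raises
    ------
    ValueError
        on non-positive diameters or an unknown radius rule.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("diameters must be positive")
    if radius_rule == "geomean":
        r = 0.5 * np.sqrt(d1 * d2)
    elif radius_rule == "single_diameter":
        r = 0.5 * d1
    else:
        raise ValueError(f"unknown radius rule {radius_rule!r}; use one of {RADIUS_RULES}")
    v = (4.0 / 3.0) * np.pi * r**3
    return float(v) if np.ndim(v) == 0 else v


def growth_analysis(
    records: pd.DataFrame, radius_rule: str = "geomean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-embryo volumes/growth plus per-group summaries.

    ``records`` needs columns ``embryo_id, group, cell_line, d1_pre, d2_pre,
    d1_post, d2_post`` (diameters in mm). Returns ``(per_embryo, summary)``:
    the embryo table gains ``v_pre, v_post, delta_v, regressing`` and the
    summary holds per (group, cell_line) the embryo count, mean/median
    delta_v and the number of regressing tumors (delta_v < 0, strict).
    Empty groups appear with n = 0 and NaN statistics.
    """
    req = {"embryo_id", "group", "cell_line", "d1_pre", "d2_pre", "d1_post", "d2_post"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")

    per = records.copy().reset_index(drop=True)
    per["v_pre"] = tumor_volume(per["d1_pre"], per["d2_pre"], radius_rule)
    per["v_post"] = tumor_volume(per["d1_post"], per["d2_post"], radius_rule)
    per["delta_v"] = per["v_post"] - per["v_pre"]
    per["regressing"] = per["delta_v"] < 0

    rows = []
    for (group, line), grp in per.groupby(["group", "cell_line"], sort=True, dropna=False):
        n = len(grp)
        rows.append(
            {
                "group": group,
                "cell_line": line,
                "n": n,
                "mean_delta_v": float(grp["delta_v"].mean()) if n else np.nan,
                "median_delta_v": float(grp["delta_v"].median()) if n else np.nan,
                "n_regressing": int(grp["regressing"].sum()),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["group", "cell_line", "n", "mean_delta_v", "median_delta_v", "n_regressing"]
    )
    return per, summary
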