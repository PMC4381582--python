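import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sylscreen import (
    GenePairedZ,
    aggregate_genes,
    call_hits,
    hit_matrix,
    hits_table,
    median_centered_zscores,
    read_screen_table,
    surviving_fractions,
)
from sylscreen.errors import InsufficientDataError, NormalizationError
from sylscreen.plate_io import ScreenDataset

from conftest import make_plate_csv


def wells_frame(rows):
    return ScreenDataset(
        wells=pd.DataFrame(
            rows,
            columns=["plate_id", "row", "col", "cell_line", "sirna_id", "gene", "role", "reading"],
        )
    )


class TestSurvivingFractions:
    def test_normalizes_to_neg_control_median(self):
        ds = wells_frame(
            [
                ("P1", "A", 1, "M2.1", "g1_s1", "g1", "sample", 0.5),
                ("P1", "A", 2, "M2.1", "", "", "neg_control", 0.8),
                ("P1", "A", 3, "M2.1", "", "", "neg_control", 1.0),
                ("P1", "A", 4, "M2.1", "", "", "neg_control", 1.2),
                ("P1", "A", 5, "M2.1", "g2_s1", "g2", "sample", 1.0),
                ("P1", "A", 6, "M2.1", "g3_s1", "g3", "sample", 0.0),
            ]
        )
        sf = surviving_fractions(ds).set_index("sirna_id")["sf"]
        assert sf["g1_s1"] == pytest.approx(0.5)  # median of {0.8,1.0,1.2} is 1.0
        assert sf["g2_s1"] == pytest.approx(1.0)  # reading equal to the median
        assert sf["g3_s1"] == 0.0
        # neg-control wells normalize to median 1 by construction
        neg = surviving_fractions(ds)
        assert neg.loc[neg.role == "neg_control", "sf"].median() == pytest.approx(1.0)

    def test_plate_without_neg_controls_raises(self):
        ds = wells_frame([("P9", "A", 1, "V11", "g1_s1", "g1", "sample", 0.5)])
        with pytest.raises(NormalizationError, match="P9"):
            surviving_fractions(ds)

    def test_all_zero_neg_controls_is_degenerate(self):
        ds = wells_frame(
            [
                ("P1", "A", 1, "V11", "g1_s1", "g1", "sample", 0.5),
                ("P1", "A", 2, "V11", "", "", "neg_control", 0.0),
                ("P1", "A", 3, "V11", "", "", "neg_control", 0.0),
            ]
        )
        with pytest.raises(NormalizationError, match="degenerate"):
            surviving_fractions(ds)


class TestMedianCenteredZScores:
    def _sf_frame(self, values, role="sample"):
        return pd.DataFrame(
            {
                "cell_line": "M2.1",
                "plate_id": "P1",
                "gene": [f"g{i}" for i in range(len(values))],
                "sirna_id": [f"g{i}_s1" for i in range(len(values))],
                "role": role,
                "sf": values,
            }
        )

    def test_sd_scale_hand_example(self):
        sf = self._sf_frame([0.5, 1.0, 1.0, 1.0, 1.0, 1.5])
        z = median_centered_zscores(sf, scale="sd")
        sd = np.std([0.5, 1.0, 1.0, 1.0, 1.0, 1.5], ddof=1)
        assert z["zscore"].iloc[0] == pytest.approx((0.5 - 1.0) / sd)
        assert z["zscore"].iloc[0] == pytest.approx(-1.5811, abs=1e-4)

    def test_mad_scale_matches_definition(self):
        vals = [0.4, 0.9, 1.0, 1.1, 1.2, 1.6]
        z = median_centered_zscores(self._sf_frame(vals), scale="mad")
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(np.array(vals) - med))
        assert z["zscore"].iloc[0] == pytest.approx((0.4 - med) / mad)

    def test_degenerate_stratum_all_identical_gives_zero(self):
        z = median_centered_zscores(self._sf_frame([1.0] * 6))
        assert (z["zscore"] == 0).all()

    def test_zero_mad_falls_back_to_sd(self):
        # >50% identical values: MAD = 0 but SD > 0
        vals = [1.0, 1.0, 1.0, 1.0, 1.0, 1.6]
        z = median_centered_zscores(self._sf_frame(vals), scale="mad")
        sd = np.std(vals, ddof=1)
        assert z["zscore"].iloc[-1] == pytest.approx(0.6 / sd)

    def test_sample_median_is_zero_within_tolerance(self, default_screen_result):
        z = default_screen_result["zscores"]
        samp = z[z.role == "sample"]
        per_stratum = samp.groupby(["cell_line", "plate_id"])["zscore"].median()
        assert per_stratum.abs().max() < 1e-9

    def test_plate_rescaling_leaves_z_unchanged(self, plate_csv):
        ds = read_screen_table(io.StringIO(plate_csv))
        doubled = ds.wells.copy()
        doubled["reading"] *= 2.0
        z1 = median_centered_zscores(surviving_fractions(ds))
        z2 = median_centered_zscores(surviving_fractions(ScreenDataset(wells=doubled)))
        np.testing.assert_allclose(z1["zscore"], z2["zscore"], rtol=1e-12)

    def test_small_stratum_rejected(self):
        with pytest.raises(InsufficientDataError):
            median_centered_zscores(self._sf_frame([1.0, 1.1, 0.9]))

    def test_controls_are_scored_but_not_in_center(self):
        sf = pd.concat(
            [self._sf_frame([0.9, 1.0, 1.0, 1.1]), self._sf_frame([0.1], role="death_control")],
            ignore_index=True,
        )
        z = median_centered_zscores(sf, scale="sd")
        samp = z[z.role == "sample"]["zscore"]
        assert samp.median() == pytest.approx(0.0, abs=1e-12)
        assert z[z.role == "death_control"]["zscore"].iloc[0] < -5


class TestAggregateGenes:
    def _z_frame(self, entries):
        return pd.DataFrame(
            entries, columns=["cell_line", "gene", "sirna_id", "plate_id", "sf", "zscore", "role"]
        )

    def test_pairs_both_lines(self):
        z = self._z_frame(
            [
                ("M2.1", "g1", "s1", "P1", 0.4, -3.0, "sample"),
                ("M2.1", "g1", "s2", "P1", 0.5, -2.5, "sample"),
                ("V11", "g1", "s1", "P1", 1.0, 0.1, "sample"),
                ("V11", "g1", "s2", "P1", 1.0, -0.1, "sample"),
            ]
        )
        paired, missing = aggregate_genes(z, "M2.1", "V11")
        assert len(paired) == 1 and missing.empty
        assert paired[0].z_overexpr == [-3.0, -2.5]
        assert paired[0].z_control == [0.1, -0.1]

    def test_replicate_wells_are_averaged(self):
        z = self._z_frame(
            [
                ("M2.1", "g1", "s1", "P1r1", 0.4, -3.0, "sample"),
                ("M2.1", "g1", "s1", "P1r2", 0.5, -1.0, "sample"),
                ("V11", "g1", "s1", "P1r1", 1.0, 0.0, "sample"),
            ]
        )
        paired, _ = aggregate_genes(z, "M2.1", "V11")
        assert paired[0].z_overexpr == [-2.0]

    def test_sirna_missing_in_one_line_reported_not_dropped_silently(self):
        z = self._z_frame(
            [
                ("M2.1", "g1", "s1", "P1", 0.4, -3.0, "sample"),
                ("M2.1", "g1", "s2", "P1", 0.5, -2.5, "sample"),
                ("V11", "g1", "s1", "P1", 1.0, 0.1, "sample"),
            ]
        )
        paired, missing = aggregate_genes(z, "M2.1", "V11")
        assert paired[0].sirna_ids == ["s1"]
        assert missing.to_dict("records") == [
            {"gene": "g1", "sirna_id": "s2", "missing_in": "V11"}
        ]

    def test_unknown_cell_line_is_error(self):
        z = self._z_frame([("M2.1", "g1", "s1", "P1", 0.4, -3.0, "sample")])
        with pytest.raises(ValueError, match="NOPE"):
            aggregate_genes(z, "NOPE", "M2.1")

    def test_empty_input_gives_empty_output(self):
        paired, missing = aggregate_genes(self._z_frame([]), "M2.1", "V11")
        assert paired == [] and missing.empty


def brute_force_hits(genes, threshold=-2.0, min_concordant=2, selectivity_margin=-1.0):
    """Independent re-check: plain loops, no vectorization shared with call_hits."""
    out = {}
    for g in genes:
        n_below = 0
        for z in g.z_overexpr:
            if z < threshold:
                n_below += 1
        mean_over = sum(g.z_overexpr) / len(g.z_overexpr)
        mean_ctrl = sum(g.z_control) / len(g.z_control)
        sel = mean_over - mean_ctrl
        out[g.gene] = n_below >= min_concordant and sel <= selectivity_margin
    return out


def paired(gene, z_over, z_ctrl):
    return GenePairedZ(gene, [f"s{i}" for i in range(len(z_over))],
                       list(z_over), list(z_ctrl), "M2.1", "V11")


class TestCallHits:
    def test_concordant_selective_gene_is_hit(self):
        calls = call_hits([paired("g1", [-2.5, -2.1, -0.3], [-0.1, 0.2, 0.0])])
        (c,) = calls
        assert c.hit and c.n_below_threshold == 2
        assert c.selectivity == pytest.approx(-5 / 3)  # -1.6333 - 0.0333

    def test_single_sirna_below_threshold_is_not_hit(self):
        (c,) = call_hits([paired("g1", [-2.5, -1.9, -1.9], [0.0, 0.0, 0.0])])
        assert not c.hit and c.n_below_threshold == 1

    def test_all_zero_is_not_hit(self):
        (c,) = call_hits([paired("g1", [0.0, 0.0, 0.0], [0.0, 0.0, 0.0])])
        assert not c.hit

    def test_unselective_kill_is_not_hit(self):
        # lethal in both lines: concordant but not c-Myc-selective
        (c,) = call_hits([paired("g1", [-4.0, -4.0, -4.0], [-3.8, -4.1, -3.9])])
        assert c.n_below_threshold == 3 and not c.hit

    def test_boundary_is_strict(self):
        (c,) = call_hits([paired("g1", [-2.0, -2.0, -2.0], [0.0, 0.0, 0.0])])
        assert c.n_below_threshold == 0 and not c.hit

    def test_sorted_by_ascending_mean_overexpressing_z(self):
        calls = call_hits(
            [paired("weak", [-1, -1, -1], [0, 0, 0]), paired("strong", [-9, -9, -9], [0, 0, 0])]
        )
        assert [c.gene for c in calls] == ["strong", "weak"]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            call_hits([], threshold=1.0)
        with pytest.raises(ValueError):
            call_hits([], min_concordant=0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.lists(st.floats(-6, 2, allow_nan=False), min_size=3, max_size=3),
                st.lists(st.floats(-6, 2, allow_nan=False), min_size=3, max_size=3),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_agrees_with_brute_force_oracle(self, gene_data):
        genes = [paired(f"g{i}", zo, zc) for i, (zo, zc) in enumerate(gene_data)]
        calls = {c.gene: c.hit for c in call_hits(genes)}
        assert calls == brute_force_hits(genes)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(
                st.lists(st.floats(-6, 2, allow_nan=False), min_size=3, max_size=3),
                st.lists(st.floats(-6, 2, allow_nan=False), min_size=3, max_size=3),
            ),
            min_size=1,
            max_size=12,
        ),
        st.floats(-4, -2),
        st.integers(2, 3),
    )
    def test_hit_set_shrinks_with_stricter_parameters(self, gene_data, threshold, min_conc):
        genes = [paired(f"g{i}", zo, zc) for i, (zo, zc) in enumerate(gene_data)]
        base = {c.gene for c in call_hits(genes, threshold=-2.0, min_concordant=2) if c.hit}
        stricter_t = {c.gene for c in call_hits(genes, threshold=threshold) if c.hit}
        stricter_k = {c.gene for c in call_hits(genes, min_concordant=min_conc) if c.hit}
        assert stricter_t <= base
        assert stricter_k <= base


class TestHitMatrix:
    def test_matrix_rows_are_hits_and_values_match_z(self):
        genes = [
            paired("g1", [-3.0, -2.5, -2.2], [0.1, 0.0, -0.2]),
            paired("g2", [0.0, 0.1, 0.2], [0.0, 0.1, 0.2]),
        ]
        calls = call_hits(genes)
        mat = hit_matrix(calls)
        assert list(mat.index) == ["g1"]
        assert mat.loc["g1", "M2.1:sirna1"] == -3.0
        assert mat.loc["g1", "V11:sirna3"] == -0.2
        assert mat.shape == (1, 6)

    def test_no_hits_yields_empty_matrix_with_header(self):
        calls = call_hits([paired("g1", [0, 0, 0], [0, 0, 0])])
        mat = hit_matrix(calls)
        assert len(mat) == 0 and len(mat.columns) == 6

    def test_hits_table_schema(self):
        calls = call_hits([paired("g1", [-3.0, -2.5, -2.2], [0.1, 0.0, -0.2])])
        tab = hits_table(calls)
        assert list(tab.columns) == [
            "gene", "n_sirnas_below", "hit", "min_z_line_a", "min_z_line_b", "selectivity",
        ]
        assert tab.loc[0, "min_z_line_a"] == -3.0
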