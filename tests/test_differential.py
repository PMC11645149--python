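import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cocultnet import differential, synthetic
from cocultnet.io import ExpressionMatrix


def _mat(values: dict, scale="counts", conditions=None):
    df = pd.DataFrame(values)
    conditions = conditions or {s: "c" for s in df.columns}
    ann = pd.DataFrame(
        {"condition": [conditions[s] for s in df.columns], "cell_line": "x", "batch": 1},
        index=df.columns,
    )
    return ExpressionMatrix(df, scale, ann)


class TestNormalizeLog2Cpm:
    def test_single_gene_full_library(self):
        mat = _mat({"S1": [1e6]})
        out = differential.normalize_log2cpm(mat)
        assert out.values.iloc[0, 0] == pytest.approx(math.log2(1_000_001), rel=1e-9)

    def test_all_zero_gene_maps_to_zero(self):
        mat = _mat({"S1": [0, 10], "S2": [0, 20]})
        out = differential.normalize_log2cpm(mat)
        assert (out.values.loc[out.values.index[0]] == 0).all()

    def test_scale_invariance_to_library_depth(self):
        m1 = differential.normalize_log2cpm(_mat({"S1": [10, 90]}))
        m2 = differential.normalize_log2cpm(_mat({"S1": [20, 180]}))
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_zero_library_names_sample(self):
        with pytest.raises(ValueError, match="S2"):
            differential.normalize_log2cpm(_mat({"S1": [5], "S2": [0]}))

    def test_median_of_ratios_removes_composition_shift(self):
        # sample B doubles a single dominant gene; size factors should not
        # shift the unchanged genes' values
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=50).astype(float)
        values = {"A": base.copy(), "B": base.copy()}
        values["B"][0] = base[0] * 200
        mat = _mat(values)
        libs = differential.effective_library_sizes(mat)
        out = differential.normalize_log2cpm(mat, library_sizes=libs)
        diff = (out.values["B"] - out.values["A"]).iloc[1:]
        assert diff.abs().max() < 0.02


class TestDeTest:
    def test_zero_variance_separation_is_degenerate_with_floor_p(self):
        mat = _mat({"S1": [1.0], "S2": [1.0], "S3": [3.0], "S4": [3.0]}, scale="log2cpm")
        res = differential.de_test(mat, ["S1", "S2"], ["S3", "S4"])
        row = res.table.iloc[0]
        assert row["log2_fc"] == 2.0
        assert row["degenerate"]
        assert 0 < row["p_value"] <= np.nextafter(0, 1)

    def test_identical_constant_groups_give_null_result(self):
        mat = _mat({"S1": [2.0], "S2": [2.0], "S3": [2.0], "S4": [2.0]}, scale="log2cpm")
        res = differential.de_test(mat, ["S1", "S2"], ["S3", "S4"])
        assert res.table.iloc[0]["log2_fc"] == 0.0
        assert res.table.iloc[0]["p_value"] == 1.0

    def test_matches_hand_coded_welch_formula(self):
        a = np.array([2.0, 2.2, 1.8])
        b = np.array([4.1, 3.9, 4.0])
        mat = _mat(
            {f"A{i}": [a[i]] for i in range(3)} | {f"B{i}": [b[i]] for i in range(3)},
            scale="log2cpm",
        )
        res = differential.de_test(mat, [f"A{i}" for i in range(3)], [f"B{i}" for i in range(3)])
        # independent Welch oracle from the textbook formulas
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t), df)
        assert res.table.iloc[0]["log2_fc"] == pytest.approx(2.0, abs=0.01)
        assert res.table.iloc[0]["p_value"] == pytest.approx(p_oracle, rel=1e-10)

    def test_swapping_groups_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 1, size=(30, 6)), index=[f"G{i}" for i in range(30)],
                          columns=[f"S{i}" for i in range(6)])
        mat = _mat({c: df[c].tolist() for c in df.columns}, scale="log2cpm")
        mat.values.index = df.index
        ga, gb = ["S0", "S1", "S2"], ["S3", "S4", "S5"]
        r1 = differential.de_test(mat, ga, gb)
        r2 = differential.de_test(mat, gb, ga)
        np.testing.assert_allclose(r1.table["log2_fc"], -r2.table["log2_fc"])
        np.testing.assert_allclose(r1.table["p_value"], r2.table["p_value"], rtol=1e-12)

    def test_overlapping_or_unknown_groups_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="overlap"):
            differential.de_test(tiny_matrix, ["S1", "S2"], ["S2", "S3"])
        with pytest.raises(ValueError, match="unknown"):
            differential.de_test(tiny_matrix, ["S1", "S2"], ["S3", "SX"])

    def test_single_sample_groups_flagged_p_one(self):
        mat = _mat({"S1": [1.0], "S2": [5.0]}, scale="log2cpm")
        res = differential.de_test(mat, ["S1"], ["S2"])
        assert res.table.iloc[0]["log2_fc"] == 4.0
        assert res.table.iloc[0]["p_value"] == 1.0

    def test_moderated_engine_agrees_on_direction_and_gains_power(self):
        rng = np.random.default_rng(2)
        n = 400
        base = rng.normal(8, 1, size=n)
        vals = {}
        for j in range(3):
            vals[f"A{j}"] = base + rng.normal(0, 0.4, n)
        shift = np.zeros(n)
        shift[:40] = 2.5
        for j in range(3):
            vals[f"B{j}"] = base + shift + rng.normal(0, 0.4, n)
        df = pd.DataFrame(vals, index=[f"G{i}" for i in range(n)])
        mat = _mat({c: df[c].tolist() for c in df.columns}, scale="log2cpm")
        mat.values.index = df.index
        ga, gb = [f"A{j}" for j in range(3)], [f"B{j}" for j in range(3)]
        welch = differential.de_test(mat, ga, gb, engine="welch")
        mod = differential.de_test(mat, ga, gb, engine="moderated")
        np.testing.assert_allclose(welch.table["log2_fc"], mod.table["log2_fc"])
        true_idx = [f"G{i}" for i in range(40)]
        assert mod.table.loc[true_idx, "p_value"].median() < welch.table.loc[true_idx, "p_value"].median()
        # null genes stay calibrated
        null_p = mod.table.iloc[40:]["p_value"]
        assert (null_p < 0.05).mean() < 0.08

    def test_null_pvalues_uniform_on_generator_null(self):
        """Under equal group means the Welch p-values are uniform within
        Kolmogorov-Smirnov D < 0.05 at 2000 genes."""
        truth = synthetic.default_truth(n_transfer=0, n_intrinsic=0, n_cm=0)
        expr = synthetic.simulate_coculture(truth, seed=13)
        log2 = differential.normalize_log2cpm(expr)
        res = differential.de_test(
            log2,
            expr.samples_where(condition="recipient_mono"),
            expr.samples_where(condition="recipient_cm"),
        )
        from scipy.stats import kstest

        d = kstest(res.table["p_value"], "uniform").statistic
        assert d < 0.05


from _oracles import bh_stepup as _bh_oracle


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([1, 1, 1], [1, 1, 1]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
        ],
    )
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(differential.bh_adjust(p), expected)

    def test_matches_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 51))
            np.testing.assert_allclose(differential.bh_adjust(p), _bh_oracle(p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            differential.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_output_in_unit_interval_and_order_preserving(self, p):
        q = differential.bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        # genes with smaller p never get larger adjusted p
        idx = np.argsort(p, kind="stable")
        assert (np.diff(q[idx]) >= -1e-12).all()


class TestFilterDeg:
    @pytest.fixture
    def result(self):
        table = pd.DataFrame(
            {
                "log2_fc": [2.5, 1.0, -3.0],
                "p_value": [0.001, 0.0001, 0.01],
                "adj_p": [0.01, 0.001, 0.04],
                "mean_a": [0, 0, 0],
                "mean_b": [0, 0, 0],
                "degenerate": False,
            },
            index=["G1", "G2", "G3"],
        )
        return differential.DEResult(table, ("a",), ("b",))

    @pytest.mark.parametrize(
        "direction,expected",
        [("up", {"G1"}), ("down", {"G3"}), ("both", {"G1", "G3"})],
    )
    def test_directional_thresholds(self, result, direction, expected):
        assert differential.filter_deg(result, 2, 0.05, direction).genes == frozenset(expected)

    def test_zero_adj_p_ceiling_empties_result(self, result):
        assert differential.filter_deg(result, 2, 0.0, "both").genes == frozenset()
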