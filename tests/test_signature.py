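import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cocultnet import signature, synthetic
from cocultnet.io import ExpressionMatrix, GeneSet
from cocultnet.stats import hypergeom_upper_tail, roc_auc
from cocultnet.triage import TriagePartition


def _mat(values: dict, index, conditions=None):
    df = pd.DataFrame(values, index=index, dtype=float)
    conditions = conditions or {s: "c" for s in df.columns}
    ann = pd.DataFrame(
        {"condition": [conditions[s] for s in df.columns], "cell_line": "x", "batch": 1},
        index=df.columns,
    )
    return ExpressionMatrix(df, "log2cpm", ann)


class TestCompositeScore:
    def test_hand_computed_zscore_mean(self):
        mat = _mat({"S1": [1, 4], "S2": [2, 4], "S3": [3, 4]}, index=["G1", "G2"])
        scores = signature.composite_score(mat, GeneSet("sig", frozenset({"G1", "G2"})))
        np.testing.assert_allclose(scores.scores().to_numpy(), [-0.5, 0.0, 0.5])

    def test_single_gene_signature_equals_its_zscore(self):
        mat = _mat({"S1": [1.0], "S2": [3.0]}, index=["G1"])
        scores = signature.composite_score(mat, GeneSet("sig", frozenset({"G1"})))
        z = (np.array([1.0, 3.0]) - 2.0) / np.std([1.0, 3.0], ddof=1)
        np.testing.assert_allclose(scores.scores().to_numpy(), z)

    def test_per_gene_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.normal(5, 2, size=(6, 5))
        m1 = _mat({f"S{j}": base[:, j] for j in range(5)}, index=[f"G{i}" for i in range(6)])
        scaled = base * rng.uniform(0.5, 3, size=(6, 1)) + rng.normal(0, 4, size=(6, 1))
        m2 = _mat({f"S{j}": scaled[:, j] for j in range(5)}, index=[f"G{i}" for i in range(6)])
        sig = GeneSet("sig", frozenset(f"G{i}" for i in range(6)))
        np.testing.assert_allclose(
            signature.composite_score(m1, sig).scores(),
            signature.composite_score(m2, sig).scores(),
            atol=1e-10,
        )

    def test_absent_signature_is_error_missing_genes_skipped(self):
        mat = _mat({"S1": [1.0], "S2": [2.0]}, index=["G1"])
        with pytest.raises(ValueError):
            signature.composite_score(mat, GeneSet("sig", frozenset({"NOPE"})))
        ok = signature.composite_score(mat, GeneSet("sig", frozenset({"G1", "NOPE"})))
        assert len(ok.table) == 2


class TestHierarchicalCluster:
    def test_duplicate_profiles_cocluster_at_zero_distance(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(0, 1, 10)
        mat = _mat(
            {"S1": profile, "S2": profile, "S3": -profile},
            index=[f"G{i}" for i in range(10)],
        )
        out = signature.hierarchical_cluster(
            mat, GeneSet("sig", frozenset(f"G{i}" for i in range(10)))
        )
        labels = out["labels"]
        assert labels["S1"] == labels["S2"] != labels["S3"]
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-8)

    def test_membership_stable_under_sample_permutation(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(8, 6))
        vals[:, 3:] += 3
        names = [f"S{j}" for j in range(6)]
        m1 = _mat({names[j]: vals[:, j] for j in range(6)}, index=[f"G{i}" for i in range(8)])
        perm = [4, 2, 0, 5, 1, 3]
        m2 = _mat({names[j]: vals[:, j] for j in perm}, index=[f"G{i}" for i in range(8)])
        sig = GeneSet("sig", frozenset(f"G{i}" for i in range(8)))
        out1 = signature.hierarchical_cluster(m1, sig)["labels"]
        out2 = signature.hierarchical_cluster(m2, sig)["labels"]
        part1 = {frozenset(s for s in names if out1[s] == k) for k in (1, 2)}
        part2 = {frozenset(s for s in names if out2[s] == k) for k in (1, 2)}
        assert part1 == part2

    def test_contact_samples_cluster_with_donor_monocultures(self, default_truth):
        """The synthetic study reproduces the observed dendrogram pattern:
        contact-culture recipients group with donor monocultures, while
        conditioned-media recipients group with recipient monocultures."""
        from cocultnet import differential

        sig = GeneSet("sig", frozenset(sorted(default_truth.transfer_genes.genes)[:39]))
        hits = 0
        for s in range(20):
            expr = synthetic.simulate_coculture(default_truth, seed=600 + s)
            log2 = differential.normalize_log2cpm(
                expr, library_sizes=differential.effective_library_sizes(expr)
            )
            labels = signature.hierarchical_cluster(log2, sig)["labels"]
            groups = {
                c: {labels[x] for x in expr.samples_where(condition=c)}
                for c in synthetic.CONDITIONS
            }
            if (
                all(len(v) == 1 for v in groups.values())
                and groups["donor_mono"] == groups["recipient_cc"]
                and groups["recipient_mono"] == groups["recipient_cm"]
                and groups["donor_mono"] != groups["recipient_mono"]
            ):
                hits += 1
        assert hits >= 18

    def test_fewer_than_two_samples_rejected(self):
        mat = _mat({"S1": [1.0, 2.0]}, index=["G1", "G2"])
        with pytest.raises(ValueError):
            signature.hierarchical_cluster(mat, GeneSet("s", frozenset({"G1"})))


class TestAnovaTukey:
    def _scores(self, groups: dict):
        rows = []
        for g, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"{g}{i}", v, g))
        table = pd.DataFrame(
            {"score": [r[1] for r in rows], "group": [r[2] for r in rows]},
            index=[r[0] for r in rows],
        )
        return signature.SignatureScoreSet("sig", table)

    def test_identical_groups_give_null_statistics(self):
        out = signature.anova_tukey(self._scores({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}))
        assert out["F"] == 0.0 and out["p"] == 1.0
        assert all(p == 1.0 for p in out["pairwise"].values())

    def test_perfect_separation_reports_floor_p(self):
        out = signature.anova_tukey(self._scores({"a": [0, 0, 0], "b": [10, 10, 10], "c": [0, 0, 0]}))
        assert np.isinf(out["F"])
        assert out["pairwise"][("a", "b")] < 1e-300
        assert out["pairwise"][("a", "c")] == 1.0

    def test_matches_direct_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        groups = {k: rng.normal(i, 1, 5) for i, k in enumerate("abc")}
        out = signature.anova_tukey(self._scores(groups))
        # independent one-way ANOVA decomposition
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 12)
        from scipy.stats import f as fdist, studentized_range

        p_oracle = fdist.sf(f_oracle, 2, 12)
        assert out["F"] == pytest.approx(f_oracle, rel=1e-8)
        assert out["p"] == pytest.approx(p_oracle, rel=1e-8)
        # Tukey oracle: studentized range on the (a, b) contrast
        ms_w = ssw / 12
        q = abs(groups["a"].mean() - groups["b"].mean()) / math.sqrt(ms_w / 5)
        p_tukey = studentized_range.sf(q, 3, 12)
        assert out["pairwise"][("a", "b")] == pytest.approx(p_tukey, rel=1e-6)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            signature.anova_tukey(self._scores({"a": [1.0], "b": [1, 2]}))


from _oracles import auc_pair_counting as _auc_oracle


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            ([3, 5], [1, 4], 0.75),
            ([10, 11], [1, 2], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.5),
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected)

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            pos = rng.integers(0, 8, size=rng.integers(1, 8)).astype(float)
            neg = rng.integers(0, 8, size=rng.integers(1, 8)).astype(float)
            assert roc_auc(pos, neg) == pytest.approx(_auc_oracle(pos, neg), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=10),
        st.lists(st.floats(-5, 5), min_size=1, max_size=10),
    )
    def test_complement_symmetry(self, pos, neg):
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestRefineByAuc:
    def _dataset(self, aucs: dict, seed):
        """Build a 4v4 dataset whose per-gene separation is either clean
        (auc 1.0 target) or absent."""
        rng = np.random.default_rng(seed)
        genes = sorted(aucs)
        pos, neg = [f"P{j}" for j in range(4)], [f"N{j}" for j in range(4)]
        vals = {}
        for s in pos + neg:
            vals[s] = []
        for g in genes:
            shift = 5.0 if aucs[g] else 0.0
            for s in pos:
                vals[s].append(rng.normal(shift, 1))
            for s in neg:
                vals[s].append(rng.normal(0, 1))
        mat = _mat(vals, index=genes)
        return mat, pos, neg

    def test_intersection_over_datasets(self):
        cand = GeneSet("c", frozenset({"G1", "G2", "G3"}))
        d1 = self._dataset({"G1": True, "G2": True, "G3": True}, 1)
        d2 = self._dataset({"G1": True, "G2": False, "G3": True}, 2)
        refined, table = signature.refine_by_auc(cand, [d1, d2], 0.85)
        assert "G1" in refined.genes and "G2" not in refined.genes
        assert set(table["dataset"]) == {"dataset_1", "dataset_2"}

    def test_threshold_monotonicity(self):
        cand = GeneSet("c", frozenset({"G1", "G2"}))
        d = self._dataset({"G1": True, "G2": False}, 3)
        lo, _ = signature.refine_by_auc(cand, [d], 0.6)
        hi, _ = signature.refine_by_auc(cand, [d], 0.99)
        assert hi.genes <= lo.genes

    def test_recovery_on_synthetic_validation_datasets(self, default_truth):
        """150 planted-true + 50 null candidates, two simulated datasets,
        threshold 0.85: >=90% of true and <=10% of null survive."""
        truth = default_truth
        planted = truth.transfer_genes.genes | truth.intrinsic_genes.genes | truth.cm_genes.genes
        nulls = [g for g in synthetic.gene_universe(2000) if g not in planted][:50]
        cand = GeneSet("cand", truth.transfer_genes.genes | frozenset(nulls))
        datasets = [
            synthetic.simulate_validation_dataset(truth, seed=301 + i) for i in range(2)
        ]
        refined, _ = signature.refine_by_auc(cand, datasets, 0.85)
        true_kept = len(refined.genes & truth.transfer_genes.genes) / 150
        null_kept = len(refined.genes & set(nulls)) / 50
        assert true_kept >= 0.9
        assert null_kept <= 0.1


class TestRecapitulation:
    def _partition(self, borrowed, intrinsic):
        return TriagePartition(
            GeneSet("cat", frozenset(borrowed)),
            GeneSet("borrowed", frozenset(borrowed)),
            GeneSet("intrinsic", frozenset(intrinsic)),
            GeneSet("cm", frozenset()),
        )

    def test_perfect_separator_counted_overlapping_not(self):
        mat = _mat(
            {"P1": [5, 1], "P2": [6, 3], "C1": [0, 2], "C2": [1, 2.5]},
            index=["G1", "G2"],
        )
        part = self._partition(["G1", "G2"], ["GX"])
        out = signature.recapitulation_fraction(mat, ["P1", "P2"], ["C1", "C2"], part)
        assert out["recap_borrowed"].genes == frozenset({"G1"})
        assert out["fraction_borrowed"] == 0.5

    def test_bin_absent_from_matrix_gives_zero_fraction(self):
        mat = _mat({"P1": [1.0], "P2": [2.0], "C1": [0.0], "C2": [1.0]}, index=["G1"])
        part = self._partition(["GA", "GB"], ["GC"])
        out = signature.recapitulation_fraction(mat, ["P1", "P2"], ["C1", "C2"], part)
        assert out["fraction_borrowed"] == 0.0

    def test_planted_fraction_recovered_over_seeds(self, default_truth):
        """A perturbation planted in 20% of the borrowed bin is recovered
        within +-5 percentage points (mean over 20 seeds)."""
        borrowed = GeneSet("borrowed", default_truth.transfer_genes.genes)
        intrinsic = GeneSet("intrinsic", default_truth.intrinsic_genes.genes)
        part = TriagePartition(
            GeneSet("cat", borrowed.genes), borrowed, intrinsic, GeneSet("cm", frozenset())
        )
        fracs = []
        for s in range(20):
            mat, _planted = synthetic.simulate_perturbation(
                borrowed, 0.2, other_genes=intrinsic, seed=700 + s
            )
            out = signature.recapitulation_fraction(
                mat,
                mat.samples_where(condition="perturbed"),
                mat.samples_where(condition="control"),
                part,
                auc_threshold=1.0,
            )
            fracs.append(out["fraction_borrowed"])
        assert abs(float(np.mean(fracs)) - 0.2) <= 0.05


class TestOra:
    def test_query_equal_to_set_in_small_universe(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(10)))
        query = GeneSet("q", frozenset(f"G{i}" for i in range(5)))
        coll = [GeneSet("hit", query.genes), GeneSet("miss", frozenset({"ZZ1", "ZZ2"}))]
        out = signature.ora_enrichment(query, coll, universe)
        hit = out.set_index("set").loc["hit"]
        assert hit["p"] == pytest.approx(1 / 252, rel=1e-12)
        miss = out.set_index("set").loc["miss"]
        assert miss["overlap_k"] == 0 and miss["p"] == 1.0

    def test_duplicate_collections_are_idempotent(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(10)))
        query = GeneSet("q", frozenset({"G1", "G2"}))
        coll = [GeneSet("s", frozenset({"G1", "G3"}))] * 2
        out = signature.ora_enrichment(query, coll, universe)
        assert out["p"].nunique() == 1

    def test_shares_hypergeometric_core_with_network_test(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(30)))
        query = GeneSet("q", frozenset(f"G{i}" for i in range(8)))
        coll = [GeneSet("s", frozenset(f"G{i}" for i in range(4, 16)))]
        out = signature.ora_enrichment(query, coll, universe)
        expected = hypergeom_upper_tail(30, 12, 8, 4)
        assert out.loc[0, "p"] == expected

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            signature.ora_enrichment(
                GeneSet("q", frozenset({"A"})), [], GeneSet("u", frozenset())
            )
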