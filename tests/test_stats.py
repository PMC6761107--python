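import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isotarget.io import AnnotationSet, GeneModel, GeneSetCollection, ValidationError
from isotarget.stats import (
    hypergeometric_enrichment,
    mann_whitney_u,
    neighbor_perturbation_ratio,
    overlap_percentage,
    permutation_overlap_test,
    roc_sit_evaluation,
    sensitivity_association,
)


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_oracle_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n, m = rng.integers(1, 9, size=2)
            pool = rng.choice(1000, size=n + m, replace=False).astype(float)
            x, y = pool[:n], pool[n:]
            ours = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.method == "exact"
            assert ours.u == pytest.approx(float(ref.statistic))
            assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_large_sample_uses_normal(self):
        rng = np.random.default_rng(1)
        res = mann_whitney_u(rng.normal(size=30), rng.normal(1.5, 1, size=30))
        assert res.method == "normal"
        assert res.p_value < 0.01

    def test_u_range_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, m = rng.integers(1, 12, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            res = mann_whitney_u(x, y)
            assert 0 <= res.u <= n * m
            assert 0 < res.p_value <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestRoc:
    def test_hand_enumerated_curve(self):
        # 4 ranked isoforms, positive ranked second
        res = roc_sit_evaluation([(["i1", "i2", "i3", "i4"], {"i2"})])
        pts = list(zip(res.frame["FPR"].round(6), res.frame["TPR"].round(6)))
        assert pts == [
            (round(1 / 3, 6), 0.0),
            (round(1 / 3, 6), 1.0),
            (round(2 / 3, 6), 1.0),
            (1.0, 1.0),
        ]
        assert res.auc == pytest.approx(2 / 3)

    def test_perfect_ranking_auc_one(self):
        res = roc_sit_evaluation(
            [(["p", "a", "b", "c"], {"p"}), (["q", "x", "y"], {"q"})]
        )
        assert res.auc == pytest.approx(1.0)

    def test_tpr_fpr_monotone(self):
        rng = np.random.default_rng(0)
        ranking = [f"n{i}" for i in rng.permutation(50)]
        res = roc_sit_evaluation([(ranking, {"n3", "n17", "n40"})])
        assert (np.diff(res.frame["TPR"]) >= -1e-12).all()
        assert (np.diff(res.frame["FPR"]) >= -1e-12).all()

    def test_auc_invariant_to_monotone_score_transform(self):
        # AUC depends only on the order, which is what the API consumes
        ranking = [f"n{i}" for i in range(20)]
        a = roc_sit_evaluation([(ranking, {"n2", "n9"})])
        b = roc_sit_evaluation([(list(ranking), {"n2", "n9"})])
        assert a.auc == b.auc

    def test_missing_positive_counts_as_fn(self):
        # positive absent from the ranking: TPR can never reach 1
        res = roc_sit_evaluation([(["a", "b", "c"], {"a", "zz"})])
        assert res.frame["TPR"].max() == pytest.approx(0.5)

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            roc_sit_evaluation([(["a", "b"], {"zz"})])

    def test_null_shuffle_auc_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(20):
            ranking = [f"n{i}" for i in rng.permutation(200)]
            pos = set(rng.choice([f"n{i}" for i in range(200)], 20, replace=False))
            aucs.append(roc_sit_evaluation([(ranking, pos)]).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestOverlapPercentage:
    @pytest.mark.parametrize(
        "observed,total,expected",
        [(97, 118, 82.2), (75, 118, 63.5), (44, 58, 75.8), (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_truncation_convention(self, observed, total, expected):
        assert overlap_percentage(observed, total) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            overlap_percentage(1, 0)
        with pytest.raises(ValidationError):
            overlap_percentage(5, 4)


class TestPermutationOverlap:
    model = GeneModel.from_records(
        [("g1", "a1"), ("g1", "a2"), ("g2", "b1"), ("g2", "b2"), ("g3", "c1"), ("g3", "c2")]
    )
    reference = AnnotationSet("principal", {"g1": "a1", "g2": "b1", "g3": "c1"})

    def test_exact_binomial_oracle(self):
        # 3 genes x 2 isoforms, all predictions match: P(null >= 3) = 1/8
        predicted = {"g1": "a1", "g2": "b1", "g3": "c1"}
        res = permutation_overlap_test(predicted, self.reference, self.model,
                                       n_perm=4000, seed=0)
        assert res.observed == 3
        assert res.null_mean == pytest.approx(1.5, abs=0.1)
        assert res.p_value == pytest.approx(1 / 8, abs=0.02)

    def test_p_value_floor(self):
        predicted = {"g1": "a1", "g2": "b1", "g3": "c1"}
        res = permutation_overlap_test(predicted, self.reference, self.model,
                                       n_perm=100, seed=1)
        assert res.p_value >= 1 / 101

    def test_reference_isoform_outside_model_excluded(self):
        ref = AnnotationSet("principal", {"g1": "a1", "g2": "zz"})
        res = permutation_overlap_test(
            {"g1": "a1", "g2": "b1"}, ref, self.model, n_perm=50, seed=0
        )
        assert res.n_genes == 1

    def test_seed_reproducible(self):
        predicted = {"g1": "a2", "g2": "b1", "g3": "c2"}
        r1 = permutation_overlap_test(predicted, self.reference, self.model, 500, seed=7)
        r2 = permutation_overlap_test(predicted, self.reference, self.model, 500, seed=7)
        assert (r1.p_value, r1.null_mean, r1.null_sd) == (r2.p_value, r2.null_mean, r2.null_sd)

    def test_no_common_genes_rejected(self):
        with pytest.raises(ValidationError):
            permutation_overlap_test({"gX": "y"}, self.reference, self.model, 10, 0)

    def test_null_mean_matches_analytic(self):
        # E[matches] = sum 1/k_g over common MIT genes
        model = GeneModel.from_records(
            [("g1", "a1"), ("g1", "a2"), ("g1", "a3"), ("g2", "b1"), ("g2", "b2")]
        )
        ref = AnnotationSet("x", {"g1": "a1", "g2": "b1"})
        res = permutation_overlap_test({"g1": "a1", "g2": "b2"}, ref, model,
                                       n_perm=8000, seed=3)
        assert res.null_mean == pytest.approx(1 / 3 + 1 / 2, abs=0.05)


class TestSensitivity:
    def _sens(self, cells, values, col="aac"):
        return pd.DataFrame({"cell_line": cells, "drug": "dx", col: values})

    def test_proportional_expression_r_one(self):
        cells = [f"c{i}" for i in range(5)]
        aac = [0.1, 0.2, 0.3, 0.4, 0.5]
        expr = pd.DataFrame([np.array(aac) * 2 + 1], index=["i1"], columns=cells)
        out = sensitivity_association(expr, self._sens(cells, aac), "dx", ["i1"])
        assert out["i1"] == pytest.approx(1.0)

    def test_auc_column_converted(self):
        cells = [f"c{i}" for i in range(4)]
        auc = [0.9, 0.7, 0.5, 0.3]  # AAC = 1-AUC increasing
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["i1"], columns=cells)
        out = sensitivity_association(expr, self._sens(cells, auc, col="auc"), "dx", ["i1"])
        assert out["i1"] == pytest.approx(1.0)

    def test_constant_expression_missing(self):
        cells = [f"c{i}" for i in range(4)]
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["i1"], columns=cells)
        out = sensitivity_association(expr, self._sens(cells, [0.1, 0.2, 0.3, 0.4]), "dx", ["i1"])
        assert math.isnan(out["i1"])

    def test_too_few_shared_lines(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["i1"], columns=["c1", "c2"])
        with pytest.raises(ValidationError, match="shared"):
            sensitivity_association(expr, self._sens(["c1", "c2"], [0.1, 0.2]), "dx", ["i1"])


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection.from_dict({"T": universe[:5]}, universe)
        res = hypergeometric_enrichment(universe[:5], coll)
        assert res.loc[0, "overlap"] == 5
        assert res.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert res.loc[0, "fdr"] == res.loc[0, "p_value"]  # single term: FDR == p
        assert bool(res.loc[0, "significant"])

    def test_expected_overlap_not_significant(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        term = list(rng.choice(universe, 50, replace=False))
        query = list(rng.choice(universe, 40, replace=False))
        coll = GeneSetCollection.from_dict({"T": term}, universe)
        res = hypergeometric_enrichment(query, coll)
        assert not bool(res.loc[0, "significant"]) or res.loc[0, "p_value"] > 0.01

    def test_bh_never_decreases_p(self):
        universe = [f"g{i}" for i in range(100)]
        rng = np.random.default_rng(1)
        sets = {f"T{k}": list(rng.choice(universe, 20, replace=False)) for k in range(8)}
        coll = GeneSetCollection.from_dict(sets, universe)
        res = hypergeometric_enrichment(list(rng.choice(universe, 30, replace=False)), coll)
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()

    def test_query_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection.from_dict({"T": universe[:4]}, universe)
        res = hypergeometric_enrichment(universe[:4] + ["alien"], coll)
        assert res.loc[0, "overlap"] == 4

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection.from_dict({}, [])
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(["g1"], coll)


class TestNeighborRatio:
    def _fixture(self):
        # isoform x's neighbors map to genes n1,n2; perturbed genes p1..p6;
        # one term holding all eight -> ratio 2/8
        model_records = [("gx", "x")]
        net = nx.Graph()
        for k in (1, 2):
            iso = f"i{k}"
            net.add_edge("x", iso, weight=0.9)
            model_records.append((f"n{k}", iso))
        perturbed = [f"p{k}" for k in range(1, 7)]
        for g in perturbed:
            model_records.append((g, g + "_t"))
        model = GeneModel.from_records(model_records)
        members = ["n1", "n2"] + perturbed
        universe = members + [f"bg{i}" for i in range(200)]
        coll = GeneSetCollection.from_dict({"T": members}, universe)
        return net, model, coll, perturbed

    def test_disjoint_sets_ratio(self):
        net, model, coll, perturbed = self._fixture()
        ratios = neighbor_perturbation_ratio(net, "x", perturbed, coll, model)
        assert ratios["T"] == pytest.approx(2 / 8)

    def test_alternative_denominator(self):
        net, model, coll, perturbed = self._fixture()
        ratios = neighbor_perturbation_ratio(
            net, "x", perturbed, coll, model, denominator="perturbed"
        )
        assert ratios["T"] == pytest.approx(2 / 6)

    def test_identical_sets_ratio_one(self):
        model = GeneModel.from_records([("gx", "x"), ("n1", "i1"), ("n2", "i2")])
        net = nx.Graph([("x", "i1"), ("x", "i2")])
        universe = ["n1", "n2"] + [f"bg{i}" for i in range(100)]
        coll = GeneSetCollection.from_dict({"T": ["n1", "n2"]}, universe)
        ratios = neighbor_perturbation_ratio(net, "x", ["n1", "n2"], coll, model)
        assert ratios["T"] == pytest.approx(1.0)

    def test_no_common_terms_empty(self):
        net, model, coll, perturbed = self._fixture()
        # perturbed genes outside every term -> no common significant terms
        ratios = neighbor_perturbation_ratio(net, "x", ["bg0", "bg1"], coll, model)
        assert len(ratios) == 0

    def test_isolated_isoform_empty(self):
        net, model, coll, perturbed = self._fixture()
        net.add_node("lonely")
        ratios = neighbor_perturbation_ratio(net, "lonely", perturbed, coll, model)
        assert len(ratios) == 0
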