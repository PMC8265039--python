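"""Feature aggregation, logistic fitting, stepwise AIC selection, AUC and
the resampling loop."""

import numpy as np
import pandas as pd
import pytest

from icbnet import response
from icbnet.io import BulkCohort, ExpressionMatrix
from icbnet.networks import AnnotationSets, RegulationNetwork
from icbnet import networks as networks_mod


def brute_force_auc(scores, labels01):
    wins = ties = 0
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFeatureTable:
    def test_per_sample_means(self, toy_matrix, toy_annotation):
        reg = RegulationNetwork(
            edge_clusters={("GA", "t", "GB"): {1}},
            node_clusters={"GA": {1}, "GB": {1}},
            roles={"GA": (False, True, False), "GB": (False, False, True)},
        )
        table = response.build_feature_table(toy_matrix, toy_annotation, reg)
        assert table.genes == ["GA", "GB"]
        i = table.sample_ids.index("s1")
        expected = toy_matrix.cell_columns(["c0", "c1"]).mean(axis=1)[0]
        assert table.values[i, 0] == pytest.approx(expected)

    def test_panel_matches_network_roles(self, feature_table, regulation_network):
        panel = set(feature_table.genes)
        assert panel == (
            regulation_network.genes_with_role("ligand")
            | regulation_network.genes_with_role("receptor")
        )

    def test_network_without_roles_is_error(self, toy_matrix, toy_annotation):
        reg = RegulationNetwork(
            edge_clusters={}, node_clusters={"GA": {1}}, roles={}
        )
        with pytest.raises(ValueError, match="ligand"):
            response.build_feature_table(toy_matrix, toy_annotation, reg)


class TestSplitHalf:
    def test_48_samples_split_24_24(self):
        samples = [f"s{i}" for i in range(48)]
        labels = ["R"] * 20 + ["NR"] * 28
        train, test = response.split_half(samples, labels, seed=0)
        assert len(train) == 24 and len(test) == 24
        assert set(train) | set(test) == set(samples)
        assert not set(train) & set(test)

    def test_seed_determinism(self):
        samples = [f"s{i}" for i in range(10)]
        labels = ["R"] * 5 + ["NR"] * 5
        assert response.split_half(samples, labels, 3) == response.split_half(
            samples, labels, 3
        )

    def test_rare_class_constraint(self):
        samples = ["a", "b", "c", "d"]
        labels = ["R", "R", "R", "NR"]
        for seed in range(20):
            train, test = response.split_half(samples, labels, seed)
            got = [l for s, l in zip(samples, labels) if s in train]
            # the single NR is in one half; each half still has an R
            assert "R" in got
            assert "R" in [l for s, l in zip(samples, labels) if s in test]


class TestFitLogistic:
    def test_symmetric_data_zero_intercept(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        fit = response.fit_logistic(X, y)
        assert abs(fit.intercept) < 1e-6

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 3))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 2]
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = response.fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [fit.intercept, *fit.coefficients], ref.params, atol=1e-6
        )
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_parameter_recovery_within_3_se(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        true = np.array([0.3, 1.0, -0.7])
        X = rng.normal(size=(500, 2))
        eta = true[0] + X @ true[1:]
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = response.fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        est = np.array([fit.intercept, *fit.coefficients])
        assert np.all(np.abs(est - true) < 3 * ref.bse)

    def test_null_coefficients_centred_at_zero(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 1))
        coefs = []
        for _ in range(200):
            y = rng.permutation([0] * 20 + [1] * 20).astype(float)
            coefs.append(response.fit_logistic(X, y).coefficients[0])
        coefs = np.array(coefs)
        assert abs(coefs.mean()) < 3 * coefs.std() / np.sqrt(len(coefs))

    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = response.fit_logistic(X, y, genes=["const", "sig"])
        assert fit.dropped == ["const"]
        assert fit.genes == ["sig"]

    def test_separation_triggers_ridge_fallback(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0], [-3.0], [3.0]])
        y = np.array([0, 0, 1, 1, 0, 1])
        fit = response.fit_logistic(X, y)
        assert fit.ridged
        assert np.isfinite(fit.coefficients).all()


class TestStepwise:
    def test_single_signal_feature_selected(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        sel, fit = response.stepwise_select(x[:, None], y, ["sig"])
        assert sel == ["sig"]

    def test_signal_beats_noise_in_most_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            signal = rng.normal(0, 1, n) + 3.0 * y
            noise = rng.normal(size=(n, 5))
            X = np.column_stack([signal, noise])
            genes = ["sig"] + [f"n{i}" for i in range(5)]
            sel, _ = response.stepwise_select(X, y, genes)
            hits += "sig" in sel
        assert hits >= 95

    def test_all_noise_selects_little(self):
        sizes = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 100
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            X = rng.normal(size=(n, 6))
            sel, _ = response.stepwise_select(X, y, [f"n{i}" for i in range(6)])
            sizes.append(len(sel))
        assert np.median(sizes) <= 2

    def test_deterministic_given_order(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        genes = list("abcd")
        assert (
            response.stepwise_select(X, y, genes)[0]
            == response.stepwise_select(X, y, genes)[0]
        )


class TestAuc:
    def test_perfect_and_tied(self):
        assert response.auc([1, 2, 3, 4], ["NR", "NR", "R", "R"]) == 1.0
        assert response.auc([1, 1, 1, 1], ["NR", "NR", "R", "R"]) == 0.5

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            scores = np.round(rng.normal(size=20), 1)  # induces ties
            y = rng.integers(0, 2, 20)
            if y.sum() in (0, 20):
                continue
            assert response.auc(scores, y) == pytest.approx(
                brute_force_auc(scores, y), abs=1e-12
            )

    def test_one_class_is_error(self):
        with pytest.raises(ValueError):
            response.auc([1, 2], ["R", "R"])

    def test_roc_points_integrate_to_auc(self):
        rng = np.random.default_rng(17)
        scores = np.round(rng.normal(size=30), 1)
        y = np.array([1] * 12 + [0] * 18)
        roc = response.roc_points(scores, y)
        trapezoid = np.trapezoid(roc["tpr"], roc["fpr"])
        assert trapezoid == pytest.approx(response.auc(scores, y), abs=1e-12)
        assert roc.iloc[0]["tpr"] == 0.0 and roc.iloc[-1]["tpr"] == 1.0


class TestSelectionLoop:
    def test_single_iteration(self, feature_table):
        runs, summary = response.run_selection_loop(feature_table, n_iter=1)
        assert len(runs) == 1
        assert summary["n_iter"] == 1

    def test_reproducible_from_base_seed(self, feature_table):
        r1, _ = response.run_selection_loop(feature_table, n_iter=10, base_seed=5)
        r2, _ = response.run_selection_loop(feature_table, n_iter=10, base_seed=5)
        assert r1 == r2

    def test_no_leakage_between_halves(self, feature_table):
        runs, _ = response.run_selection_loop(feature_table, n_iter=20, base_seed=1)
        for r in runs:
            assert not set(r.train_samples) & set(r.test_samples)
            assert set(r.train_samples) | set(r.test_samples) == set(
                feature_table.sample_ids
            )

    def test_null_cohort_auc_near_half(self):
        # enough samples that no noise feature separates the labels globally
        rng = np.random.default_rng(16)
        null = response.PatientFeatureTable(
            sample_ids=[f"s{i}" for i in range(40)],
            genes=[f"g{i}" for i in range(10)],
            values=rng.normal(size=(40, 10)),
            response=["R"] * 20 + ["NR"] * 20,
        )
        _, summary = response.run_selection_loop(null, n_iter=200, base_seed=2)
        assert 0.35 <= summary["median_test_auc"] <= 0.65


class TestRankGeneSets:
    def _runs(self):
        def run(i, genes, auc_):
            return response.SelectionRun(
                iteration=i, seed=i, train_samples=[], test_samples=[],
                selected_genes=genes, coefficients={}, intercept=0.0,
                ridged=False, train_auc=1.0, test_auc=auc_,
            )
        return [run(0, ["A", "B"], 0.8), run(1, ["B", "A"], 0.6),
                run(2, ["C"], 0.7)]

    def test_unordered_deduplication(self):
        df = response.rank_gene_sets(self._runs())
        assert len(df) == 2
        ab = df[df["genes"] == "A,B"].iloc[0]
        assert ab["count"] == 2
        assert ab["best_test_auc"] == pytest.approx(0.8)

    def test_max_sets_one(self):
        assert len(response.rank_gene_sets(self._runs(), max_sets=1)) == 1

    def test_order_invariance(self):
        fwd = response.rank_gene_sets(self._runs())
        rev = response.rank_gene_sets(list(reversed(self._runs())))
        pd.testing.assert_frame_equal(fwd, rev)


class TestExternalValidation:
    def test_empty_gene_set_is_error(self, feature_table, bulk_cohort):
        with pytest.raises(ValueError, match="empty"):
            response.validate_external([], feature_table, bulk_cohort)

    def test_missing_gene_reported(self, feature_table, bulk_cohort):
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            response.validate_external(
                ["NOT_A_GENE"], feature_table, bulk_cohort
            )

    def test_zero_variance_bulk_feature_is_error(self, feature_table):
        gene = feature_table.genes[0]
        bulk = BulkCohort(
            sample_ids=["b1", "b2", "b3", "b4"],
            gene_ids=[gene],
            values=np.ones((4, 1)),
            response=["R", "R", "NR", "NR"],
        )
        with pytest.raises(ValueError, match=gene):
            response.validate_external([gene], feature_table, bulk)

    def test_single_gene_auc_is_delegation(self, bulk_cohort):
        gene = bulk_cohort.gene_ids[5]
        expected = response.auc(
            bulk_cohort.gene_column(gene), bulk_cohort.response
        )
        assert response.single_gene_auc(gene, bulk_cohort) == expected

    def test_planted_signal_validates(self, synth, feature_table, bulk_cohort):
        _, _, truth = synth
        model = response.validate_external(
            truth.predictive_lr_genes, feature_table, bulk_cohort
        )
        assert model.validation_auc > 0.7
        assert model.discovery_auc > 0.7

    def test_label_permuted_bulk_auc_near_half(self, synth, feature_table, bulk_cohort):
        _, _, truth = synth
        inside = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            perm = list(rng.permutation(bulk_cohort.response))
            shuffled = BulkCohort(
                sample_ids=bulk_cohort.sample_ids,
                gene_ids=bulk_cohort.gene_ids,
                values=bulk_cohort.values,
                response=perm,
            )
            model = response.validate_external(
                truth.predictive_lr_genes, feature_table, shuffled
            )
            inside += 0.3 <= model.validation_auc <= 0.7
        assert inside >= 44
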