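"""Edge conditions, per-cluster construction, merging and role annotation."""

import numpy as np
import pandas as pd
import pytest

from icbnet import networks
from icbnet.io import AnnotationSets, ExpressionMatrix, PathwayInteractionSet


def rank_then_pearson(x, y):
    """Independent Spearman oracle: hand-rolled average ranks, then the
    explicit Pearson formula, then the t-approximation p."""
    from scipy.stats import t as tdist

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    rho = num / den
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * ((n - 2) / (1 - rho**2)) ** 0.5
    return rho, 2.0 * tdist.sf(abs(tstat), df=n - 2)


class TestExpressedGenes:
    def _matrix(self, detected):
        vals = np.zeros((1, 100))
        vals[0, :detected] = 1.0
        return ExpressionMatrix(["GA"], [f"c{i}" for i in range(100)], vals)

    def test_two_percent_included(self):
        m = self._matrix(2)
        assert networks.expressed_genes(m, m.cell_ids, 0.01) == {"GA"}

    def test_exactly_one_percent_excluded(self):
        m = self._matrix(1)
        assert networks.expressed_genes(m, m.cell_ids, 0.01) == set()

    def test_zero_threshold_keeps_any_detection(self):
        m = self._matrix(1)
        assert networks.expressed_genes(m, m.cell_ids, 0.0) == {"GA"}

    def test_empty_cell_list_is_error(self, toy_matrix):
        with pytest.raises(ValueError, match="empty"):
            networks.expressed_genes(toy_matrix, [], 0.01)


class TestSpearmanEdgeTest:
    def test_perfect_monotone(self, toy_matrix):
        cells = toy_matrix.cell_ids
        rho, _ = networks.spearman_edge_test(toy_matrix, cells, "GA", "GA")
        assert rho == pytest.approx(1.0)
        rho, _ = networks.spearman_edge_test(toy_matrix, cells, "GA", "GB")
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_contract(self, toy_matrix):
        rho, p = networks.spearman_edge_test(
            toy_matrix, toy_matrix.cell_ids, "GA", "GD"
        )
        assert np.isnan(rho) and p == 1.0

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 6, 30).astype(float)  # heavy ties
        y = rng.integers(0, 6, 30).astype(float)
        m = ExpressionMatrix(["GA", "GB"], [f"c{i}" for i in range(30)],
                             np.vstack([x, y]))
        rho, p = networks.spearman_edge_test(m, m.cell_ids, "GA", "GB")
        rho_o, p_o = rank_then_pearson(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_vectorized_pairs_match_scalar_path(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(3.0, size=(6, 50)).astype(float)
        m = ExpressionMatrix([f"G{i}" for i in range(6)],
                             [f"c{i}" for i in range(50)], X)
        ia, ib = np.array([0, 1, 2, 4]), np.array([3, 2, 5, 5])
        rho_v, p_v = networks._spearman_pairs(X, ia, ib)
        for k, (i, j) in enumerate(zip(ia, ib)):
            rho_s, p_s = networks.spearman_edge_test(
                m, m.cell_ids, f"G{i}", f"G{j}"
            )
            assert rho_v[k] == pytest.approx(rho_s, abs=1e-12)
            assert p_v[k] == pytest.approx(p_s, abs=1e-12)


class TestBuildClusterNetwork:
    def _toy(self):
        """5 catalogue edges: 2 fail prevalence, 1 fails correlation."""
        rng = np.random.default_rng(0)
        n = 50
        x = rng.normal(size=n)
        vals = np.vstack(
            [
                np.abs(x) + 1,                       # GA
                np.abs(x) + 1 + rng.normal(0, .1, n), # GB ~ GA
                np.abs(x) + 1 + rng.normal(0, .1, n), # GC ~ GA
                np.abs(rng.normal(size=n)) + 1,       # GD independent of GA
                np.zeros(n),                          # GE undetected
            ]
        )
        m = ExpressionMatrix(
            ["GA", "GB", "GC", "GD", "GE"], [f"c{i}" for i in range(n)], vals
        )
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "cluster": 1,
                "sample_id": "s1",
                "phase": "pre",
                "response": "R",
            }
        )
        cat = PathwayInteractionSet(
            [
                ("GA", "controls-expression-of", "GB"),
                ("GA", "controls-expression-of", "GC"),
                ("GA", "controls-expression-of", "GD"),  # fails correlation
                ("GA", "controls-expression-of", "GE"),  # fails prevalence
                ("GE", "controls-expression-of", "GB"),  # fails prevalence
            ]
        )
        return m, ann, cat

    def test_toy_counting_case(self):
        m, ann, cat = self._toy()
        net = networks.build_cluster_network(m, ann, 1, cat)
        assert set(net.edges) == {
            ("GA", "controls-expression-of", "GB"),
            ("GA", "controls-expression-of", "GC"),
        }

    def test_zero_alpha_gives_empty_network(self):
        m, ann, cat = self._toy()
        net = networks.build_cluster_network(m, ann, 1, cat, alpha=0.0)
        assert net.edges == {}

    def test_tiny_cluster_is_error(self):
        m, ann, cat = self._toy()
        ann = ann.iloc[:3]
        m = m.submatrix(ann["cell_id"].tolist())
        with pytest.raises(ValueError, match=">= 4"):
            networks.build_cluster_network(m, ann, 1, cat)

    def test_planted_modules_recovered(self, synth, catalog, cluster_networks):
        _, _, truth = synth
        recovered = total = 0
        for net in cluster_networks:
            planted = truth.planted_edges_per_cluster[net.cluster]
            got = {(min(s, t), max(s, t)) for s, _, t in net.edges}
            total += len(planted)
            recovered += sum(1 for p in planted if p in got)
        assert recovered / total >= 0.90

    def test_every_edge_exists_in_catalogue(self, cluster_networks, catalog):
        allowed = {networks.canonical_edge(*r) for r in catalog}
        for net in cluster_networks:
            assert set(net.edges) <= allowed

    def test_monotone_in_alpha_and_prevalence(self, synth, catalog):
        matrix, annotation, _ = synth
        prev = None
        for alpha in (0.01, 0.05, 0.2):
            net = networks.build_cluster_network(
                matrix, annotation, 1, catalog, alpha=alpha
            )
            if prev is not None:
                assert prev <= set(net.edges)
            prev = set(net.edges)
        loose = networks.build_cluster_network(
            matrix, annotation, 1, catalog, min_fraction=0.0
        )
        strict = networks.build_cluster_network(
            matrix, annotation, 1, catalog, min_fraction=0.05
        )
        assert set(strict.edges) <= set(loose.edges)

    def test_exhaustive_reference_equivalence(self):
        """On a small instance the fast path must equal a brute-force loop
        over all catalogue triples using the rank-then-Pearson oracle."""
        from icbnet import simulate

        cat = simulate.generate_pathway_catalog(50, 4, seed=21)
        m, ann, _ = simulate.generate_cells(
            cat,
            simulate.TruthSpec(
                modules_per_cluster=1, module_size=3, n_deg_per_phase=2,
                n_predictive=1, n_decoys=3,
            ),
            n_cells=150, n_clusters=1, n_samples=4, seed=22,
        )
        net = networks.build_cluster_network(m, ann, 1, cat)

        cells = ann["cell_id"].tolist()
        expressed = networks.expressed_genes(m, cells, 0.01)
        expected = {}
        seen = set()
        for s, t, o in cat:
            if s not in expressed or o not in expressed:
                continue
            e = networks.canonical_edge(s, t, o)
            if e in seen:
                continue
            seen.add(e)
            x = m.gene_row(e[0])
            y = m.gene_row(e[2])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = rank_then_pearson(x, y)
            if p < 0.05:
                expected[e] = (rho, p)
        assert set(net.edges) == set(expected)
        for e, (rho, p) in expected.items():
            assert net.edges[e][0] == pytest.approx(rho, abs=1e-10)
            assert net.edges[e][1] == pytest.approx(p, abs=1e-10)


class TestMergeAndRoles:
    def _nets(self):
        n1 = networks.ClusterNetwork(
            1,
            {
                ("GA", "t", "GB"): (0.5, 0.01),
                ("GB", "t", "GC"): (0.4, 0.02),
            },
        )
        n2 = networks.ClusterNetwork(
            2,
            {
                ("GA", "t", "GB"): (0.6, 0.01),
                ("GD", "t", "GE"): (0.7, 0.001),
            },
        )
        return n1, n2

    def test_disjoint_networks_union(self):
        n1, n2 = self._nets()
        n2b = networks.ClusterNetwork(
            2, {("GX", "t", "GY"): (0.5, 0.01), ("GY", "t", "GZ"): (0.5, 0.01)}
        )
        merged = networks.merge_networks([n1, n2b])
        assert merged.n_edges == 4
        assert all(len(ms) == 1 for ms in merged.edge_clusters.values())

    def test_shared_edge_membership(self):
        merged = networks.merge_networks(list(self._nets()))
        assert merged.edge_clusters[("GA", "t", "GB")] == {1, 2}
        assert merged.node_clusters["GA"] == {1, 2}

    def test_roles_can_overlap(self):
        merged = networks.merge_networks(list(self._nets()))
        sets_ = AnnotationSets(tfs={"GA"}, lr_pairs={("GB", "GA")})
        networks.annotate_roles(merged, sets_)
        assert merged.roles["GA"] == (True, False, True)
        counts = merged.role_counts()
        assert counts == {"tfs": 1, "ligands": 1, "receptors": 1}

    def test_empty_annotation_sets_flag_nothing(self):
        merged = networks.merge_networks(list(self._nets()))
        networks.annotate_roles(
            merged, AnnotationSets(tfs=set(), lr_pairs=set())
        )
        assert all(f == (False, False, False) for f in merged.roles.values())
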