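"""Shared fixtures: one default synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icbnet import networks, response, simulate
from icbnet.io import ExpressionMatrix


@pytest.fixture(scope="session")
def catalog():
    return simulate.generate_pathway_catalog(seed=1)


@pytest.fixture(scope="session")
def annotation_sets(catalog):
    return simulate.generate_annotation_sets(catalog, seed=2)


@pytest.fixture(scope="session")
def synth(catalog, annotation_sets):
    """Default-size synthetic draw: (matrix, annotation, truth)."""
    return simulate.generate_cells(
        catalog, simulate.TruthSpec(), seed=3, annotation_sets=annotation_sets
    )


@pytest.fixture(scope="session")
def cluster_networks(synth, catalog):
    matrix, annotation, _ = synth
    return networks.build_all_cluster_networks(matrix, annotation, catalog)


@pytest.fixture(scope="session")
def regulation_network(cluster_networks, annotation_sets):
    return networks.annotate_roles(
        networks.merge_networks(cluster_networks), annotation_sets
    )


@pytest.fixture(scope="session")
def feature_table(synth, regulation_network):
    matrix, annotation, _ = synth
    return response.build_feature_table(matrix, annotation, regulation_network)


@pytest.fixture(scope="session")
def bulk_cohort(synth):
    _, _, truth = synth
    return simulate.generate_bulk_cohort(truth, seed=11)


@pytest.fixture
def toy_matrix():
    """4 genes x 6 cells, hand-checkable values (log1p scale)."""
    values = np.log1p(
        np.array(
            [
                [1, 2, 3, 4, 5, 6],
                [6, 5, 4, 3, 2, 1],
                [0, 0, 0, 0, 0, 1],
                [2, 2, 2, 2, 2, 2],
            ],
            dtype=float,
        )
    )
    return ExpressionMatrix(
        ["GA", "GB", "GC", "GD"], [f"c{i}" for i in range(6)], values
    )


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "cluster": [1, 1, 1, 1, 2, 2],
            "sample_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "phase": ["pre", "pre", "pre", "pre", "on", "on"],
            "response": ["R", "R", "NR", "NR", "R", "R"],
        }
    )


def small_truth_spec(**overrides):
    """Tiny planted structure for fast per-seed regeneration in MC tests."""
    base = dict(
        modules_per_cluster=1,
        module_size=3,
        module_rho=0.6,
        n_deg_per_phase=0,
        deg_effect=2.5,
        n_predictive=0,
        n_decoys=2,
    )
    base.update(overrides)
    return simulate.TruthSpec(**base)
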