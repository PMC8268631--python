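"""Shared fixtures.

The default synthetic cohort (5,000 genes x 120 samples, 6 subtypes, 6
planted modules of 40 genes, half methylation-coupled, moderate noise)
and its trained 30x30 expression map are expensive, so they are built
once per session and shared.  The ten-seed bundle used by the recovery
and network-specificity checks trains both layers per seed and is also
session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cartograph import (CohortConfig, SomParams, center_genes,
                        detect_group_spots, drop_sex_chromosomes,
                        generate_cohort, promoter_beta, train_som)

BASE_SEED = 20_240_601


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return CohortConfig(seed=BASE_SEED)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """(expr, cpgs, ann, pheno, truth) for the default study conditions."""
    return generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def meth_matrix(cohort):
    expr, cpgs, ann, pheno, truth = cohort
    agg = promoter_beta(cpgs, ann)
    return drop_sex_chromosomes(agg.matrix, ann)


@pytest.fixture(scope="session")
def expr_matrix(cohort):
    expr, cpgs, ann, pheno, truth = cohort
    return drop_sex_chromosomes(expr, ann)


@pytest.fixture(scope="session")
def som_expr(expr_matrix):
    """30x30 expression map trained on the centered default cohort."""
    return train_som(center_genes(expr_matrix),
                     SomParams(grid_k=30, epochs=40, seed=BASE_SEED))


@pytest.fixture(scope="session")
def som_meth(meth_matrix):
    return train_som(center_genes(meth_matrix),
                     SomParams(grid_k=30, epochs=40, seed=BASE_SEED))


def _layer_spots(matrix, groups, seed, grid_k, q):
    model = train_som(center_genes(matrix),
                      SomParams(grid_k=grid_k, epochs=40, seed=seed))
    return model, detect_group_spots(model, groups, q=q)


@pytest.fixture(scope="session")
def multiseed_runs():
    """Ten independent cohorts with trained E- and M-maps and their spots.

    The expression layer uses the conventional 50x50 grid, methylation
    30x30.  Each entry: dict with truth, groups, e_model, e_spots,
    m_model, m_spots, universe (shared gene count).
    """
    runs = []
    for i in range(10):
        cfg = CohortConfig(seed=BASE_SEED + 1000 + i)
        expr, cpgs, ann, pheno, truth = generate_cohort(cfg)
        expr = drop_sex_chromosomes(expr, ann)
        meth = drop_sex_chromosomes(promoter_beta(cpgs, ann).matrix, ann)
        groups = dict(zip(pheno["sample_id"], pheno["subtype"]))
        # quantiles leave a foreground budget above the expected module
        # area: 50 units for ~42 elevated (E), 27 for ~21 (M)
        e_model, e_spots = _layer_spots(expr, groups, cfg.seed, 50, 0.98)
        m_model, m_spots = _layer_spots(meth, groups, cfg.seed, 30, 0.97)
        runs.append({
            "truth": truth, "groups": groups,
            "e_model": e_model, "e_spots": e_spots,
            "m_model": m_model, "m_spots": m_spots,
            "universe": len(e_model.gene_ids.intersection(m_model.gene_ids)),
        })
    return runs


@pytest.fixture
def tiny_matrix():
    """4 genes x 3 samples toy with exact values for hand oracles."""
    from cartograph import OmicsMatrix
    df = pd.DataFrame([[1.0, 4.0, 2.0],
                       [2.0, 6.0, 2.0],
                       [3.0, 8.0, 2.0],
                       [0.0, 2.0, 2.0]],
                      index=["g1", "g2", "g3", "g4"],
                      columns=["s1", "s2", "s3"])
    return OmicsMatrix(df)
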