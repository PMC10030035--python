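"""Shared fixtures: small cohorts and two session-scoped pipeline runs.

The null run (no planted pleiotropy, no structure confound, pure-noise
traits) and the recovery run (5% of genic intervals carry a causal site
shared by five traits, h2 = 0.6) are the two study conditions the
calibration and recovery checks are defined on; they are computed once per
session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pleioscan import RunConfig, SimConfig, run_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small structured cohort for unit-level checks."""
    cfg = SimConfig(
        n_samples=250, n_chrom=3, sites_per_chrom=400, ld_block_len=10,
        within_block_r=0.6, n_subpops=3, fst_like_divergence=0.15,
        genes_per_chrom=10, gene_len_bp=5000, chrom_len_bp=500_000,
        traits_per_category={"nam_field": 8, "gap_field": 8,
                             "mass_feature": 8, "expression": 10},
        pleiotropy_rate=0.2, traits_per_pleiotropic_site=4, h2=0.7,
        n_hidden_factors=3, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Pipeline under the global null: no planted sharing, no structure
    confound, traits are pure noise (300 samples, 5,000 sites, 60 traits,
    10 permutations per field/mass category, 5 for expression)."""
    cfg = RunConfig(
        sim=SimConfig(
            n_samples=300, n_chrom=5, sites_per_chrom=1000, ld_block_len=20,
            within_block_r=0.6, n_subpops=1, fst_like_divergence=0.0,
            genes_per_chrom=40, gene_len_bp=5000, chrom_len_bp=1_000_000,
            traits_per_category={"nam_field": 15, "gap_field": 15,
                                 "mass_feature": 15, "expression": 15},
            pleiotropy_rate=0.0, causal_sites_per_trait=0,
            structure_confound_sd=0.0, h2=0.5, n_hidden_factors=2, seed=101),
        n_perm={"nam_field": 10, "gap_field": 10, "mass_feature": 10,
                "expression": 5},
        models=("model1", "model2"),
        window_genes=20, shift_genes=10, seed=101,
    )
    out = tmp_path_factory.mktemp("null_run")
    return run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Pipeline with planted pleiotropy: 5% of genic intervals carry a
    causal site shared across 5 same-category traits at h2 = 0.6."""
    cfg = RunConfig(
        sim=SimConfig(
            n_samples=400, n_chrom=5, sites_per_chrom=1500, ld_block_len=20,
            within_block_r=0.6, n_subpops=3, fst_like_divergence=0.1,
            genes_per_chrom=40, gene_len_bp=5000, chrom_len_bp=1_000_000,
            traits_per_category={"nam_field": 25, "gap_field": 25,
                                 "mass_feature": 25, "expression": 30},
            pleiotropy_rate=0.05, traits_per_pleiotropic_site=5, h2=0.6,
            n_hidden_factors=3, structure_confound_sd=0.0, seed=202),
        n_perm={"nam_field": 10, "gap_field": 10, "mass_feature": 10,
                "expression": 5},
        models=("model1", "model2"),
        window_genes=20, shift_genes=10, seed=202,
    )
    out = tmp_path_factory.mktemp("recovery_run")
    return run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def pooled_scores(recovery_run):
    """Score tables of the recovery run concatenated across categories."""
    return pd.concat(recovery_run.scores.values(), keys=recovery_run.scores.keys())
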