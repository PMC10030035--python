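"""Structure covariates and the residual-permutation null."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import (SimConfig, compute_global_pcs, compute_window_pcs,
                       estimate_hidden_factors, n_components_for_variance,
                       permute_phenotypes, simulate_genotypes)
from pleioscan.containers import CovariateMatrix, GenotypeMatrix, TraitMatrix
from pleioscan.simdata import simulate_gene_annotation


def _toy_G(X, chrom="chr1"):
    n, m = X.shape
    sites = pd.DataFrame({
        "site_id": [f"s{j}" for j in range(m)], "chrom": chrom,
        "pos": np.arange(1, m + 1) * 100, "ref": "A", "alt": "T"})
    return GenotypeMatrix(X, sites, [f"i{k}" for k in range(n)])


@pytest.fixture(scope="module")
def structured():
    cfg = SimConfig(n_samples=300, n_chrom=2, sites_per_chrom=300,
                    n_subpops=2, fst_like_divergence=0.25,
                    genes_per_chrom=5, seed=4)
    return simulate_genotypes(cfg)


class TestGlobalPCs:

    def test_self_projection_equals_own_scores(self, structured):
        G, _ = structured
        C = compute_global_pcs(G, G, k=3)
        Xc = G.dosages - G.dosages.mean(0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        own = np.abs(U[:, :3] * S[:3])
        np.testing.assert_allclose(np.abs(C.values.to_numpy()), own, atol=1e-8)

    def test_pc1_sign_separates_two_subpops(self, structured):
        G, truth = structured
        C = compute_global_pcs(G, G, k=1)
        pc1 = C.values["globalPC1"].to_numpy()
        labels = truth.structure_labels.to_numpy()
        side = pc1 > np.median(pc1)
        frac = max((side == (labels == 0)).mean(), (side == (labels == 1)).mean())
        assert frac > 0.95

    def test_duplicated_samples_leave_axes_unchanged(self, structured):
        G, _ = structured
        G2 = GenotypeMatrix(np.vstack([G.dosages, G.dosages]), G.sites,
                            G.samples + [s + "b" for s in G.samples])
        C1 = compute_global_pcs(G, G, k=2)
        C2 = compute_global_pcs(G2, G, k=2)  # target = original samples
        r = np.corrcoef(C1.values.to_numpy().T, C2.values.to_numpy().T)
        assert np.abs(np.diag(r[:2, 2:])).min() > 1 - 1e-8

    def test_too_few_shared_sites_fails(self):
        G = _toy_G(np.random.default_rng(0).integers(0, 3, (20, 2)).astype(float))
        with pytest.raises(ValueError):
            compute_global_pcs(G, G, k=5)


class TestWindowPCs:
    @pytest.mark.parametrize("shares,target,expected", [
        ((0.5, 0.3, 0.2), 0.15, 1),
        ((0.10, 0.10, 0.10, 0.10, 0.10, 0.5), 0.15, 2),
        ((1.0,), 0.15, 1),
    ])
    def test_cumulative_variance_rule(self, shares, target, expected):
        assert n_components_for_variance(np.array(shares), target) == expected

    def test_main_and_mid_window_counts(self):
        # 720 genes on one chromosome, window 360, shift 180:
        # main tiling -> 2 windows; mid tiling -> 3 (two edge half-windows)
        cfg = SimConfig(n_samples=60, n_chrom=1, sites_per_chrom=1440,
                        ld_block_len=10, genes_per_chrom=720, gene_len_bp=100,
                        chrom_len_bp=1_000_000, n_subpops=2,
                        fst_like_divergence=0.1, seed=8)
        G, _ = simulate_genotypes(cfg)
        genes = simulate_gene_annotation(cfg)
        main, mid = compute_window_pcs(G, genes, window_genes=360,
                                       shift_genes=180, var_target=0.15)
        n_main = {lbl.split("_PC")[0] for lbl in main.labels}
        n_mid = {lbl.split("_PC")[0] for lbl in mid.labels}
        assert len(n_main) == 2
        assert len(n_mid) == 3

    def test_sparse_window_contributes_nothing(self):
        rng = np.random.default_rng(3)
        G = _toy_G(rng.integers(0, 3, (40, 1)).astype(float))
        genes = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": "chr1",
                              "start": [0, 50_000], "end": [10, 50_010],
                              "strand": "+"})
        main, mid = compute_window_pcs(G, genes, window_genes=1, shift_genes=1)
        # each 1-gene window holds at most the single SNP -> no covariates
        assert main.values.shape[1] == 0


class TestHiddenFactors:
    def test_planted_factors_recovered(self):
        rng = np.random.default_rng(12)
        n, t, k = 300, 40, 3
        F = rng.normal(size=(n, k))
        lam = rng.normal(size=(k, t))
        Y = F @ lam + 0.3 * rng.normal(size=(n, t))
        T = TraitMatrix(pd.DataFrame(Y, index=[f"i{j}" for j in range(n)],
                                     columns=[f"t{j}" for j in range(t)]),
                        pd.Series("expression", index=[f"t{j}" for j in range(t)]))
        C = estimate_hidden_factors(T, k)
        # canonical correlation between planted and estimated factor spaces
        Qf, _ = np.linalg.qr(F - F.mean(0))
        Qe, _ = np.linalg.qr(C.values.to_numpy())
        svals = np.linalg.svd(Qf.T @ Qe, compute_uv=False)
        assert svals.min() > 0.9

    def test_zero_factors_is_empty(self):
        T = TraitMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                                     index=list("abcdefghij"), columns=list("wxyz")),
                        pd.Series("expression", index=list("wxyz")))
        C = estimate_hidden_factors(T, 0)
        assert C.values.shape == (10, 0)
        with pytest.raises(ValueError):
            estimate_hidden_factors(T, 10)

    def test_row_equivariance(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, 8))
        idx = [f"i{j}" for j in range(30)]
        cats = pd.Series("expression", index=[f"t{j}" for j in range(8)])
        T = TraitMatrix(pd.DataFrame(Y, index=idx, columns=cats.index), cats)
        perm = rng.permutation(30)
        Tp = TraitMatrix(pd.DataFrame(Y[perm], index=[idx[i] for i in perm],
                                      columns=cats.index), cats)
        C = estimate_hidden_factors(T, 2).values.to_numpy()
        Cp = estimate_hidden_factors(Tp, 2).values.to_numpy()
        np.testing.assert_allclose(C[perm], Cp, atol=1e-10)


class TestPermutation:
    def _traits(self, Y, samples=None):
        samples = samples or [f"i{j}" for j in range(len(Y))]
        cols = [f"t{j}" for j in range(Y.shape[1])]
        return TraitMatrix(pd.DataFrame(Y, index=samples, columns=cols),
                           pd.Series("nam_field", index=cols))

    def test_intercept_only_reverses_exactly(self):
        # y=(1,2,3), fitted=(2,2,2), residuals (-1,0,1); any shuffle of the
        # residuals is a shuffle of y itself
        T = self._traits(np.array([[1.0], [2.0], [3.0]]))
        C = CovariateMatrix.empty(T.samples)
        found = set()
        for seed in range(30):
            P = permute_phenotypes(T, C, 1, seed=seed)
            found.add(tuple(P.replicates[0].values["t0"]))
        assert found <= {p for p in
                         {(1, 2, 3), (1, 3, 2), (2, 1, 3), (2, 3, 1),
                          (3, 1, 2), (3, 2, 1)}}
        assert (3.0, 2.0, 1.0) in found  # the fully reversed shuffle occurs

    def test_intercept_only_preserves_multiset_mean_variance(self):
        rng = np.random.default_rng(7)
        T = self._traits(rng.normal(size=(50, 6)))
        C = CovariateMatrix.empty(T.samples)
        P = permute_phenotypes(T, C, 3, seed=1)
        for rep in P:
            for t in T.traits:
                assert sorted(rep.values[t]) == pytest.approx(sorted(T.values[t]))
                assert rep.values[t].mean() == pytest.approx(T.values[t].mean())
                assert rep.values[t].var() == pytest.approx(T.values[t].var())

    def test_fitted_component_identical_by_construction(self):
        rng = np.random.default_rng(8)
        n = 80
        X = rng.normal(size=(n, 3))
        Y = X @ rng.normal(size=(3, 5)) + rng.normal(size=(n, 5))
        T = self._traits(Y)
        C = CovariateMatrix(pd.DataFrame(X, index=T.samples,
                                         columns=["c1", "c2", "c3"]),
                            pd.Series("global", index=["c1", "c2", "c3"]))
        D = np.column_stack([np.ones(n), X])
        Q, _ = np.linalg.qr(D)
        fitted = Q @ (Q.T @ Y)
        resid = Y - fitted
        P = permute_phenotypes(T, C, 2, seed=3)
        for rep in P:
            shuffled = rep.values.to_numpy() - fitted
            # permuted trait decomposes as original fit + permuted residuals
            for j in range(5):
                assert sorted(shuffled[:, j]) == pytest.approx(sorted(resid[:, j]))
            # mean is preserved exactly (residuals sum to zero with intercept)
            np.testing.assert_allclose(rep.values.mean(0), Y.mean(0), atol=1e-10)

    def test_rank_deficient_design_fails(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        T = self._traits(rng.normal(size=(20, 2)))
        C = CovariateMatrix(pd.DataFrame({"c1": x, "c2": 2 * x}, index=T.samples),
                            pd.Series("global", index=["c1", "c2"]))
        with pytest.raises(ValueError):
            permute_phenotypes(T, C, 1, seed=0)

    def test_covariates_only_reduce_residual_variance(self):
        rng = np.random.default_rng(10)
        n = 100
        Y = rng.normal(size=(n, 4))
        X = rng.normal(size=(n, 3))
        D0 = np.ones((n, 1))
        D1 = np.column_stack([np.ones(n), X])
        for D_small, D_big in [(D0, D1)]:
            Qs, _ = np.linalg.qr(D_small)
            Qb, _ = np.linalg.qr(D_big)
            r_small = Y - Qs @ (Qs.T @ Y)
            r_big = Y - Qb @ (Qb.T @ Y)
            assert (r_big.var(0) <= r_small.var(0) + 1e-12).all()
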