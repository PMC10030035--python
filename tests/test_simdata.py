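"""Generator contracts: LD control, structure, planted causal architecture,
annotation coupling, determinism."""

import numpy as np
import pandas as pd
import pytest
from numpy.linalg import lstsq
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from pleioscan import SimConfig, simulate_cohort, simulate_genotypes
from pleioscan.intervals import build_intervals
from pleioscan.simdata import simulate_annotations, simulate_gene_annotation, simulate_traits


def _mean_pairwise_r2(X):
    C = np.corrcoef(X.T)
    iu = np.triu_indices(X.shape[1], 1)
    return np.nanmean(C[iu] ** 2)


class TestGenotypes:
    def test_dosage_range_and_determinism(self):
        cfg = SimConfig(n_samples=100, n_chrom=2, sites_per_chrom=100, seed=5,
                        genes_per_chrom=5)
        G1, _ = simulate_genotypes(cfg)
        G2, _ = simulate_genotypes(cfg)
        assert G1.dosages.min() >= 0 and G1.dosages.max() <= 2
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        assert G1.sites.equals(G2.sites)

    def test_no_ld_limit_matches_sampling_noise(self):
        # with one subpopulation and r=0, inter-site r2 is pure sampling
        # noise: E[r2] = 1/(n-1)
        cfg = SimConfig(n_samples=300, n_chrom=1, sites_per_chrom=300,
                        ld_block_len=10, within_block_r=0.0, n_subpops=1,
                        fst_like_divergence=0.0, genes_per_chrom=5, seed=7)
        G, _ = simulate_genotypes(cfg)
        r2 = _mean_pairwise_r2(G.dosages)
        expected = 1.0 / (cfg.n_samples - 1)
        assert abs(r2 - expected) < 3 * expected

    def test_perfect_ld_limit(self):
        cfg = SimConfig(n_samples=120, n_chrom=1, sites_per_chrom=40,
                        ld_block_len=10, within_block_r=1.0, n_subpops=1,
                        fst_like_divergence=0.0, genes_per_chrom=3, seed=7)
        G, truth = simulate_genotypes(cfg)
        blocks = truth.block_of_site.to_numpy()
        for b in np.unique(blocks):
            X = G.dosages[:, blocks == b]
            assert (X == X[:, [0]]).all()  # identical within block

    def test_block_r2_tracks_within_block_r(self):
        cfg = SimConfig(n_samples=2000, n_chrom=1, sites_per_chrom=50,
                        ld_block_len=5, within_block_r=0.8, n_subpops=1,
                        fst_like_divergence=0.0, genes_per_chrom=3, seed=13)
        G, truth = simulate_genotypes(cfg)
        blocks = truth.block_of_site.to_numpy()
        r2s = [
            _mean_pairwise_r2(G.dosages[:, blocks == b]) for b in np.unique(blocks)
        ]
        assert abs(np.mean(r2s) - 0.64) < 0.05

    def test_structure_separates_on_top_pc(self):
        cfg = SimConfig(n_samples=500, n_chrom=2, sites_per_chrom=500,
                        n_subpops=3, fst_like_divergence=0.2,
                        genes_per_chrom=5, seed=1)
        G, truth = simulate_genotypes(cfg)
        pcs = PCA(n_components=2).fit_transform(G.dosages - G.dosages.mean(0))
        sil = silhouette_score(pcs, truth.structure_labels.to_numpy())
        assert sil > 0.5

    @pytest.mark.parametrize("bad", [
        dict(n_samples=2), dict(within_block_r=1.5), dict(within_block_r=-0.1),
        dict(pleiotropy_rate=1.2), dict(h2=0.0), dict(h2=1.0),
        dict(traits_per_pleiotropic_site=1), dict(ld_block_len=10**9),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestGeneAnnotation:
    def test_partition_counts_without_overlap(self):
        cfg = SimConfig(n_samples=10, n_chrom=2, sites_per_chrom=10, ld_block_len=5,
                        genes_per_chrom=2, gene_len_bp=1000,
                        chrom_len_bp=100_000, seed=3)
        genes = simulate_gene_annotation(cfg)
        I = build_intervals(genes, cfg.chrom_lens)
        for chrom in cfg.chroms:
            sub = I.df[I.df["chrom"] == chrom]
            assert (sub["itype"] == "genic").sum() == 2
            assert (sub["itype"] == "intergenic").sum() == 3

    def test_forced_overlap_merges(self):
        cfg = SimConfig(n_samples=10, n_chrom=1, sites_per_chrom=10, ld_block_len=5,
                        genes_per_chrom=4, gene_len_bp=1000,
                        chrom_len_bp=100_000, seed=3)
        genes = simulate_gene_annotation(cfg, overlap=True)
        I = build_intervals(genes, cfg.chrom_lens)
        # overlapping pairs merge: 4 genes -> 2 genic intervals of 2 genes each
        genic = I.genic()
        assert len(genic) == 2
        assert all(len(g.split(",")) == 2 for g in genic["genes"])

    def test_gff3_round_trip(self, tmp_path):
        from pleioscan.io import read_gff3, write_gff3
        cfg = SimConfig(n_samples=10, n_chrom=2, sites_per_chrom=10, ld_block_len=5,
                        genes_per_chrom=100, gene_len_bp=500,
                        chrom_len_bp=1_000_000, seed=7)
        genes = simulate_gene_annotation(cfg)
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gff3(path)
        merged = genes.merge(back, on="gene_id", suffixes=("", "_rt"))
        assert (merged["start"] == merged["start_rt"]).all()
        assert (merged["end"] == merged["end_rt"]).all()


@pytest.fixture(scope="module")
def small():
    cfg = SimConfig(n_samples=500, n_chrom=2, sites_per_chrom=500,
                    n_subpops=1, fst_like_divergence=0.0,
                    genes_per_chrom=20,
                    traits_per_category={"nam_field": 13, "gap_field": 13,
                                         "mass_feature": 12, "expression": 12},
                    pleiotropy_rate=0.1, h2=0.5, seed=3)
    return cfg, simulate_cohort(cfg)


class TestTraits:

    def test_near_zero_h2_kills_genetic_signal(self):
        cfg = SimConfig(n_samples=300, n_chrom=1, sites_per_chrom=200,
                        n_subpops=1, fst_like_divergence=0.0, genes_per_chrom=5,
                        traits_per_category={"nam_field": 10, "gap_field": 1,
                                             "mass_feature": 1, "expression": 1},
                        pleiotropy_rate=0.0, h2=1e-6, seed=9)
        cohort = simulate_cohort(cfg)
        idx = cohort.genotypes.site_indexer()
        cors = []
        for site, effs in cohort.truth.causal_map.items():
            g = cohort.genotypes.dosages[:, idx[site]]
            for trait, _ in effs:
                y = cohort.traits.values[trait].to_numpy()
                cors.append(abs(np.corrcoef(g, y)[0, 1]))
        assert np.mean(cors) < 0.1

    def test_zero_pleiotropy_rate_plants_nothing(self):
        cfg = SimConfig(n_samples=50, n_chrom=1, sites_per_chrom=100,
                        genes_per_chrom=10, pleiotropy_rate=0.0, seed=2)
        cohort = simulate_cohort(cfg)
        assert cohort.truth.pleiotropic_intervals == set()
        assert cohort.truth.shared_sites == {}

    def test_ols_recovers_causal_effect_signs(self, small):
        # regress each trait on its own causal sites; planted signs should
        # be recovered for effects clearly above the noise floor
        cfg, cohort = small
        idx = cohort.genotypes.site_indexer()
        per_trait = {}
        for site, effs in cohort.truth.causal_map.items():
            for trait, beta in effs:
                per_trait.setdefault(trait, []).append((idx[site], beta))
        agree = total = 0
        for trait, entries in per_trait.items():
            cols = [j for j, _ in entries]
            X = cohort.genotypes.dosages[:, cols]
            X = np.column_stack([np.ones(len(X)), X])
            y = cohort.traits.values[trait].to_numpy()
            coef = lstsq(X, y, rcond=None)[0][1:]
            for (j, beta), chat in zip(entries, coef):
                if abs(beta) > 0.5:  # clearly above the noise floor
                    total += 1
                    agree += int(np.sign(chat) == np.sign(beta))
        assert total > 20
        assert agree / total >= 0.9

    def test_planted_intervals_contain_shared_sites(self, small):
        _, cohort = small
        for site, iid in cohort.truth.shared_sites.items():
            traits = {t for t, _ in cohort.truth.causal_map[site]}
            assert len(traits) >= 2
            assert iid in cohort.truth.pleiotropic_intervals

    def test_hidden_factor_loadings_only_on_expression(self, small):
        _, cohort = small
        lam = cohort.truth.hidden_factor_loadings
        cats = cohort.traits.categories
        nonexpr = lam.loc[[t for t in lam.index if cats[t] != "expression"]]
        assert (nonexpr == 0).all().all()


class TestAnnotations:
    def _cohort(self, coupling):
        cfg = SimConfig(n_samples=200, n_chrom=2, sites_per_chrom=300,
                        genes_per_chrom=25, pleiotropy_rate=0.2,
                        annotation_coupling=coupling, seed=21)
        return simulate_cohort(cfg)

    def test_decoupled_tracks_are_independent_of_truth(self):
        cohort = self._cohort(0.0)
        deg = cohort.truth.interval_degree(cohort.intervals, cohort.genotypes)
        genic = cohort.intervals.genic()["interval_id"]
        gene_iid = cohort.intervals.locate(
            cohort.genes["chrom"].to_numpy(), cohort.genes["start"].to_numpy())
        expr = cohort.annotations.expression.set_index("gene_id")["max_rna"]
        per_int = pd.Series(expr.to_numpy(), index=gene_iid).groupby(level=0).mean()
        from scipy.stats import spearmanr
        rho = spearmanr(deg.loc[per_int.index], per_int)[0]
        assert abs(rho) < 0.25

    def test_full_expression_coupling_separates_groups(self):
        cohort = self._cohort({"expression": 1.0})
        gene_iid = cohort.intervals.locate(
            cohort.genes["chrom"].to_numpy(), cohort.genes["start"].to_numpy())
        expr = cohort.annotations.expression.set_index("gene_id")["max_rna"]
        per_int = pd.Series(expr.to_numpy(), index=gene_iid).groupby(level=0).mean()
        pleio = per_int.index.isin(cohort.truth.pleiotropic_intervals)
        assert pleio.any() and (~pleio).any()
        assert per_int[pleio].min() > per_int[~pleio].max()

    def test_bed_round_trip(self, tmp_path):
        from pleioscan.io import read_bed, write_bed
        cohort = self._cohort(0.0)
        path = tmp_path / "peaks.bed"
        write_bed(cohort.annotations.peaks, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end"]],
            cohort.annotations.peaks[["chrom", "start", "end"]])

    def test_byte_identical_outputs_for_fixed_seed(self):
        a = self._cohort(0.5)
        b = self._cohort(0.5)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.traits.values, b.traits.values)
        pd.testing.assert_frame_equal(a.annotations.go_map, b.annotations.go_map)
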