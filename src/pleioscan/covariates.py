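"""Structure covariates and covariate-preserving phenotype permutations.

Three covariate families control confounding in the association scans:

* global PCs — principal components of a (reference) genotype panel, with
  target samples projected onto the reference axes;
* gene-window PCs — per-window PCs capturing local family structure in a
  structured multi-family panel; windows of ``window_genes`` genes, with a
  half-window-shifted "mid" set to absorb edge effects, keeping per window
  the smallest number of PCs explaining ``var_target`` of that window's
  total genotypic variance;
* hidden factors — truncated-SVD factors of the standardized trait matrix,
  standing in for latent expression heterogeneity (PEER-factor role).

The permutation scheme fits each trait on the covariates, shuffles the
residuals, and adds the fitted values back, so the null preserves exactly
the structure the mapping model controls for (the genotypes are never
permuted, preserving LD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import CovariateMatrix, GenotypeMatrix, TraitMatrix

__all__ = [
    "compute_global_pcs",
    "compute_window_pcs",
    "n_components_for_variance",
    "estimate_hidden_factors",
    "permute_phenotypes",
    "PermutedTraitSet",
]

log = logging.getLogger(__name__)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each component positive."""
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    return V * flip


def compute_global_pcs(
    reference_G: GenotypeMatrix, target_G: GenotypeMatrix, k: int = 3
) -> CovariateMatrix:
    """Top-k PCs fit on the reference panel, target samples projected on.

    Only sites shared between the two panels are used; constant reference
    sites are dropped with a warning.
    """
    shared = reference_G.sites.merge(target_G.sites, on="site_id")["site_id"]
    if len(shared) == 0:
        raise ValueError("panels share no sites")
    ridx = reference_G.site_indexer().loc[shared].to_numpy()
    tidx = target_G.site_indexer().loc[shared].to_numpy()
    Xr = reference_G.dosages[:, ridx]
    Xt = target_G.dosages[:, tidx]
    keep = Xr.std(axis=0) > 0
    if not keep.all():
        log.warning("dropping %d constant shared sites before PCA", (~keep).sum())
    Xr, Xt = Xr[:, keep], Xt[:, keep]
    if Xr.shape[1] < k:
        raise ValueError(f"only {Xr.shape[1]} usable shared sites for k={k} PCs")
    mean = Xr.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xr - mean, full_matrices=False)
    V = _fix_signs(Vt[:k].T)
    scores = (Xt - mean) @ V
    labels = [f"globalPC{i + 1}" for i in range(k)]
    return CovariateMatrix(
        values=pd.DataFrame(scores, index=target_G.samples, columns=labels),
        provenance=pd.Series("global", index=labels),
    )


def n_components_for_variance(eigen_shares: np.ndarray, var_target: float) -> int:
    """Smallest component count whose cumulative variance share >= target."""
    shares = np.asarray(eigen_shares, dtype=float)
    cum = np.cumsum(shares)
    hit = np.flatnonzero(cum >= var_target - 1e-12)
    return int(hit[0]) + 1 if len(hit) else len(shares)


def _gene_windows(starts: np.ndarray, ends: np.ndarray, window: int, offset: int):
    """Window index ranges over genes sorted by start, first window truncated
    to ``offset`` genes (offset=window gives the main tiling)."""
    n = len(starts)
    bounds = [0]
    nxt = offset if offset > 0 else window
    while bounds[-1] < n:
        bounds.append(min(nxt, n))
        nxt += window
    spans = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        spans.append((int(starts[a:b].min()), int(ends[a:b].max())))
    return spans


def compute_window_pcs(
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    window_genes: int = 360,
    shift_genes: int = 180,
    var_target: float = 0.15,
) -> tuple[CovariateMatrix, CovariateMatrix]:
    """Main and mid (half-window-shifted) gene-window PCs.

    Windows are built per chromosome over genes ordered by start; a SNP
    belongs to the window whose genomic span (first gene start to last gene
    end, half-open) contains it, and SNPs outside all spans attach to the
    nearest window.  Windows with fewer than two SNPs contribute no
    covariates.
    """
    out = {}
    for tag, offset in (("main", window_genes), ("mid", shift_genes)):
        cols, labels = [], []
        for chrom in pd.unique(genes["chrom"]):
            gsub = genes[genes["chrom"] == chrom].sort_values("start")
            if gsub.empty:
                continue
            spans = _gene_windows(gsub["start"].to_numpy(), gsub["end"].to_numpy(),
                                  window_genes, offset)
            smask = G.sites["chrom"].to_numpy() == chrom
            pos0 = G.sites["pos"].to_numpy()[smask] - 1
            cols_idx = np.flatnonzero(smask)
            # nearest-window assignment: distance zero inside a span
            dists = np.stack([
                np.maximum(s - pos0, 0) + np.maximum(pos0 - (e - 1), 0)
                for s, e in spans
            ])
            win_of_snp = dists.argmin(axis=0)
            for w in range(len(spans)):
                idx = cols_idx[win_of_snp == w]
                if len(idx) < 2:
                    log.info("window %s/%s#%d has <2 SNPs, skipped", chrom, tag, w)
                    continue
                X = G.dosages[:, idx]
                X = X[:, X.std(axis=0) > 0]
                if X.shape[1] < 2:
                    continue
                Xc = X - X.mean(axis=0)
                U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
                ev = S**2
                shares = ev / ev.sum()
                npc = n_components_for_variance(shares, var_target)
                V = _fix_signs(Vt[:npc].T)
                scores = Xc @ V
                for j in range(npc):
                    cols.append(scores[:, j])
                    labels.append(f"{tag}W_{chrom}_{w}_PC{j + 1}")
        values = (pd.DataFrame(np.column_stack(cols), index=G.samples, columns=labels)
                  if cols else pd.DataFrame(index=G.samples))
        prov = pd.Series(f"{tag}_window", index=labels)
        out[tag] = CovariateMatrix(values=values, provenance=prov)
    return out["main"], out["mid"]


def estimate_hidden_factors(T: TraitMatrix, k: int) -> CovariateMatrix:
    """Top-k truncated-SVD factor scores of the column-standardized traits."""
    n = len(T.samples)
    if k >= n:
        raise ValueError(f"k={k} must be < sample count {n}")
    if k == 0:
        return CovariateMatrix.empty(T.samples)
    X = T.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(S))
    # scores with the same sign convention as PCs (largest |loading| positive)
    flip = np.sign(Vt.T[np.argmax(np.abs(Vt.T), axis=0), np.arange(Vt.shape[0])])
    flip[flip == 0] = 1.0
    scores = U[:, :k] * S[:k] * flip[:k]
    labels = [f"factor{i + 1}" for i in range(k)]
    return CovariateMatrix(
        values=pd.DataFrame(scores, index=T.samples, columns=labels),
        provenance=pd.Series("hidden_factor", index=labels),
    )


@dataclass
class PermutedTraitSet:
    """Residual-permuted replicates of one trait matrix."""

    replicates: list[TraitMatrix]
    seed: int

    def __iter__(self):
        return iter(self.replicates)

    def __len__(self):
        return len(self.replicates)


def _design(C: CovariateMatrix, samples: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(samples)), C.values.loc[samples].to_numpy()]) \
        if C.values.shape[1] else np.ones((len(samples), 1))
    return X


def permute_phenotypes(
    T: TraitMatrix, C: CovariateMatrix, n_perm: int, seed: int
) -> PermutedTraitSet:
    """Fit trait ~ covariates, shuffle residuals, add fitted values back.

    Shuffles are independent per trait and per replicate; each permuted
    trait keeps the observed multiset of values and, by construction, the
    exact covariate-fitted component of the original.
    """
    X = _design(C, T.samples)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    Q, _ = np.linalg.qr(X)
    Y = T.values.to_numpy(dtype=float)
    fitted = Q @ (Q.T @ Y)
    resid = Y - fitted
    rng = substream(seed, "permutations")
    reps = []
    n = Y.shape[0]
    for r in range(n_perm):
        P = np.empty_like(resid)
        for j in range(Y.shape[1]):
            P[:, j] = resid[rng.permutation(n), j]
        reps.append(TraitMatrix(
            values=pd.DataFrame(fitted + P, index=T.values.index, columns=T.values.columns),
            categories=T.categories, trait_types=T.trait_types))
    return PermutedTraitSet(replicates=reps, seed=seed)
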