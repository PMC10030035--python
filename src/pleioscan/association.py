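"""Fast covariate-adjusted single-marker association across many traits.

The scan follows the fixed-effects "fast association" contract: traits and
genotypes are residualized against the covariate design once, then every
trait x site marginal regression statistic comes from a single cross-product
of the residualized matrices — no per-pair model refits.  For residualized
trait y* and genotype g* the t statistic is

    t = r * sqrt(df / (1 - r^2)),   r = <g*, y*> / (||g*|| ||y*||),

with df = n - rank(C) - 1 (the covariate projection removes rank(C) degrees
of freedom, the marker one more), and two-sided p from the t distribution.
This is numerically identical to fitting y ~ intercept + covariates + g per
pair.  Only hits below the significance threshold (default p < 1e-5) are
retained, for observed data and every permutation replicate alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CovariateMatrix, GenotypeMatrix, TraitMatrix

__all__ = ["HitStore", "maf_filter", "fast_association", "union_min_p"]

log = logging.getLogger(__name__)

HIT_COLUMNS = ["trait", "site_id", "chrom", "pos", "effect", "p_value", "model_tag"]


@dataclass
class HitStore:
    """Significant trait-site associations for one (category, replicate).

    ``df`` is sorted by (chrom, pos) — the single-sorted-stream contract the
    interval counter relies on — and holds at most one row per (trait, site)
    pair after model union.
    """

    df: pd.DataFrame
    category: str = "default"
    replicate: str = "observed"
    site_map: pd.DataFrame | None = None  # site_id -> chrom, pos of the scanned panel

    def __post_init__(self) -> None:
        if list(self.df.columns) != HIT_COLUMNS:
            self.df = self.df.reindex(columns=HIT_COLUMNS)
        self.df = self.df.sort_values(["chrom", "pos", "trait"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def maf_filter(G: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Drop sites with minor-allele frequency below ``min_maf``.

    "Minimum allele frequency" names the smallest allowed value, so a site
    at exactly the threshold is retained.
    """
    keep = G.maf() >= min_maf - 1e-12
    if not keep.any():
        log.warning("MAF filter removed every site")
    return G.take_sites(np.flatnonzero(keep))


def _residualize(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return X - Q @ (Q.T @ X)


def fast_association(
    T: TraitMatrix,
    G: GenotypeMatrix,
    C: CovariateMatrix | None = None,
    p_threshold: float = 1e-5,
    model_tag: str = "global",
    category: str = "default",
    replicate: str = "observed",
    chunk_sites: int = 4000,
) -> HitStore:
    """All-traits-at-once marginal association scan; emits hits p < threshold."""
    n = G.n_samples
    if C is not None and C.values.shape[1]:
        if list(C.values.index) != list(T.samples):
            raise ValueError("covariate/trait sample order mismatch")
        X = np.column_stack([np.ones(n), C.values.to_numpy(dtype=float)])
    else:
        X = np.ones((n, 1))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    Q = U[:, S > S[0] * 1e-10]  # orthonormal basis of the column space
    rank = Q.shape[1]
    df = n - rank - 1
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={rank})")

    Y = _residualize(T.values.to_numpy(dtype=float), Q)
    ynorm = np.linalg.norm(Y, axis=0)
    y_ok = ynorm > 0
    traits = np.asarray(T.traits)

    frames = []
    for lo in range(0, G.n_sites, chunk_sites):
        hi = min(lo + chunk_sites, G.n_sites)
        Gm = _residualize(G.dosages[:, lo:hi], Q)
        gss = np.einsum("ij,ij->j", Gm, Gm)
        g_ok = gss > 1e-10 * n
        if not g_ok.all():
            log.info("%d sites constant after residualization, skipped",
                     (~g_ok).sum())
        cross = Gm.T @ Y  # (sites, traits)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cross / (np.sqrt(gss)[:, None] * ynorm[None, :])
        r = np.clip(r, -1.0, 1.0)
        valid = g_ok[:, None] & y_ok[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        hit = valid & (p < p_threshold)
        si, ti = np.nonzero(hit)
        if len(si):
            sites = G.sites.iloc[lo + si]
            frames.append(pd.DataFrame({
                "trait": traits[ti],
                "site_id": sites["site_id"].to_numpy(),
                "chrom": sites["chrom"].to_numpy(),
                "pos": sites["pos"].to_numpy(),
                "effect": cross[si, ti] / gss[si],
                "p_value": p[si, ti],
                "model_tag": model_tag,
            }))
    hits = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=HIT_COLUMNS))
    return HitStore(df=hits, category=category, replicate=replicate,
                    site_map=G.sites[["site_id", "chrom", "pos"]])


def union_min_p(A: HitStore, B: HitStore) -> HitStore:
    """Union of two models' hits; on a (trait, site) collision keep the
    smaller p-value and its model tag."""
    if A.site_map is not None and B.site_map is not None:
        merged = A.site_map.merge(B.site_map, on="site_id", suffixes=("_a", "_b"))
        if ((merged["chrom_a"] != merged["chrom_b"]) |
                (merged["pos_a"] != merged["pos_b"])).any():
            raise ValueError("site maps disagree between the two models")
    frames = [d for d in (A.df, B.df) if not d.empty]
    if not frames:
        return HitStore(df=A.df.copy(), category=A.category, replicate=A.replicate,
                        site_map=A.site_map)
    both = pd.concat(frames, ignore_index=True)
    both = both.sort_values("p_value", kind="stable").drop_duplicates(
        subset=["trait", "site_id"], keep="first")
    return HitStore(df=both, category=A.category, replicate=A.replicate,
                    site_map=A.site_map if A.site_map is not None else B.site_map)
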