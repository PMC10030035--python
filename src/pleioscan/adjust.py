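"""Nuisance-adjusted pleiotropy via leave-one-chromosome-out tree models.

Raw unique-trait counts confound biology with mapping resolution: intervals
with more scanned SNPs, longer spans, or higher internal LD accumulate more
associations regardless of any shared causal site.  Four models separate
the two:

* Model 1 (random forest) — nuisance features only: mean pairwise LD r2,
  number of input SNPs, interval size.
* Model 2 (random forest) — nuisance plus biological features: mean
  conservation over significant-hit sites, accessible-chromatin peak count,
  max RNA / protein expression over member genes, interval type, and
  (for non-expression categories) adjusted expression pleiotropy.
* Model 3 (random forest) — Model 2 plus 14 GO-term indicator columns.
* Model 4 (gradient boosting, eta=0.5, max_depth=6) — Model 2's features.

All models are trained and evaluated leave-one-chromosome-out (LOCO):
train on all other chromosomes, predict the held-out one; per-fold R2 is
the squared Pearson correlation of predicted vs observed.  The adjusted
pleiotropy of a unit is its observed count minus the held-out Model-1
prediction, so the adjustment never sees the unit during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .containers import AnnotationBundle, GenotypeMatrix
from .intervals import IntervalSet

__all__ = [
    "NUISANCE_FEATURES",
    "mean_r2_ld",
    "build_feature_table",
    "build_site_feature_table",
    "impute_features",
    "fit_loco",
    "relative_importance",
    "adjusted_pleiotropy",
    "LocoResult",
]

log = logging.getLogger(__name__)

NUISANCE_FEATURES = ("mean_ld_r2", "n_input_snps", "interval_size")


def mean_r2_ld(
    G: GenotypeMatrix,
    site_idx: Sequence[int],
    max_sites: int = 80,
    seed: int = 0,
) -> float:
    """Mean pairwise squared Pearson correlation among the given sites.

    Fewer than two polymorphic sites gives NaN (imputed downstream).  For
    very dense intervals a deterministic subsample of ``max_sites`` sites
    bounds the O(k^2) pair count.
    """
    idx = np.asarray(site_idx, dtype=int)
    if len(idx) > max_sites:
        idx = idx[np.random.default_rng(seed).choice(len(idx), max_sites, replace=False)]
        idx = np.sort(idx)
    X = G.dosages[:, idx]
    X = X[:, X.std(axis=0) > 0]
    k = X.shape[1]
    if k < 2:
        return float("nan")
    C = np.corrcoef(X.T)
    iu = np.triu_indices(k, 1)
    return float(np.mean(C[iu] ** 2))


def snp_mean_r2(G: GenotypeMatrix, focal: int, window_bp: int = 50_000) -> float:
    """Mean r2 between one site and all neighbors within +/- window_bp."""
    chrom = G.sites["chrom"].iloc[focal]
    pos = G.sites["pos"].iloc[focal]
    near = np.flatnonzero(
        (G.sites["chrom"] == chrom).to_numpy()
        & (np.abs(G.sites["pos"].to_numpy() - pos) <= window_bp))
    near = near[near != focal]
    g = G.dosages[:, focal]
    if g.std() == 0 or len(near) == 0:
        return float("nan")
    X = G.dosages[:, near]
    ok = X.std(axis=0) > 0
    if not ok.any():
        return float("nan")
    gz = (g - g.mean()) / g.std()
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / X[:, ok].std(axis=0)
    r = (Z.T @ gz) / len(g)
    return float(np.mean(r**2))


def _go_indicator_terms(ann: AnnotationBundle, n_terms: int = 14) -> list[str]:
    """The GO terms used as model indicator columns (BP/MF only, stable order)."""
    sub = ann.go_map[ann.go_map["ontology"].isin(["BP", "MF"])]
    terms = sorted(sub["go_id"].unique())
    return terms[:n_terms]


def build_feature_table(
    intervals: IntervalSet,
    G: GenotypeMatrix,
    annotations: AnnotationBundle,
    hits: pd.DataFrame | None = None,
    adj_expression: pd.Series | None = None,
    go_terms: Sequence[str] | None = None,
    ld_max_sites: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-interval nuisance + biological features, indexed by interval ID.

    Conservation is averaged only over sites that coincide exactly with
    significant hits in the interval (NaN when the interval has none); peak
    counts use interval overlap; expression maxima are taken over member
    genes (NaN for intergenic); GO indicators are 1 only for genic intervals
    containing an annotated gene.
    """
    ids = list(intervals.ids)
    iid_of_site = intervals.locate(G.sites["chrom"].to_numpy(),
                                   G.sites["pos"].to_numpy() - 1)
    site_groups = pd.Series(np.arange(G.n_sites)).groupby(iid_of_site).apply(list)

    F = pd.DataFrame(index=pd.Index(ids, name="interval_id"))
    F["interval_size"] = intervals.lengths().reindex(ids)
    F["n_input_snps"] = pd.Series({i: len(site_groups.get(i, [])) for i in ids})
    F["mean_ld_r2"] = pd.Series({
        i: mean_r2_ld(G, site_groups.get(i, []), max_sites=ld_max_sites, seed=seed)
        for i in ids})
    F["interval_type"] = (intervals.types().reindex(ids) == "genic").astype(int)

    # conservation over significant-hit positions only
    cons = annotations.conservation.set_index(["chrom", "pos"])["score"]
    gerp = pd.Series(np.nan, index=F.index)
    if hits is not None and not hits.empty:
        h = hits.drop_duplicates(subset=["site_id"])
        scores = cons.reindex(pd.MultiIndex.from_arrays([h["chrom"], h["pos"]]))
        tmp = pd.DataFrame({"interval_id": h["interval_id"].to_numpy(),
                            "score": scores.to_numpy()})
        gerp = tmp.groupby("interval_id")["score"].mean().reindex(F.index)
    F["mean_gerp"] = gerp

    # peak overlap counts per interval
    n_peaks = pd.Series(0, index=F.index)
    for row in annotations.peaks.itertuples():
        sub = intervals.df[intervals.df["chrom"] == row.chrom]
        hitmask = (sub["start"] < row.end) & (sub["end"] > row.start)
        n_peaks[sub.loc[hitmask, "interval_id"]] += 1
    F["n_atac_peaks"] = n_peaks

    expr = annotations.expression.set_index("gene_id")
    max_rna = pd.Series(np.nan, index=F.index)
    max_prot = pd.Series(np.nan, index=F.index)
    for iid, gene_list in intervals.interval_genes().items():
        present = [g for g in gene_list if g in expr.index]
        if present:
            max_rna[iid] = expr.loc[present, "max_rna"].max()
            max_prot[iid] = expr.loc[present, "max_protein"].max()
    F["max_rna_expression"] = max_rna
    F["max_protein_expression"] = max_prot

    if adj_expression is not None:
        F["adjusted_expression_pleiotropy"] = adj_expression.reindex(F.index)

    terms = list(go_terms) if go_terms is not None else _go_indicator_terms(annotations)
    gene_terms = annotations.go_map.groupby("gene_id")["go_id"].apply(set)
    for t in terms:
        col = pd.Series(0, index=F.index)
        for iid, gene_list in intervals.interval_genes().items():
            if any(t in gene_terms.get(g, ()) for g in gene_list):
                col[iid] = 1
        F[f"go_{t.replace(':', '_')}"] = col
    return F


def build_site_feature_table(
    G: GenotypeMatrix,
    site_idx: np.ndarray,
    intervals: IntervalSet,
    annotations: AnnotationBundle,
    genes: pd.DataFrame,
    ld_window_bp: int = 50_000,
    nearest_gene_bp: int = 5_000,
) -> pd.DataFrame:
    """Per-SNP features for SNP-level pleiotropy models.

    Expression features come from the nearest gene within 5 kb and are
    missing beyond that distance.
    """
    rows = []
    cons = annotations.conservation.set_index(["chrom", "pos"])["score"]
    expr = annotations.expression.set_index("gene_id")
    iid_of = intervals.locate(G.sites["chrom"].to_numpy()[site_idx],
                              G.sites["pos"].to_numpy()[site_idx] - 1)
    types = intervals.types()
    for k, j in enumerate(site_idx):
        chrom = G.sites["chrom"].iloc[j]
        pos = int(G.sites["pos"].iloc[j])
        gsub = genes[genes["chrom"] == chrom]
        dist = np.maximum(gsub["start"].to_numpy() - (pos - 1), 0) + \
            np.maximum((pos - 1) - (gsub["end"].to_numpy() - 1), 0)
        rna = prot = np.nan
        if len(dist) and dist.min() <= nearest_gene_bp:
            gid = gsub["gene_id"].iloc[int(dist.argmin())]
            if gid in expr.index:
                rna = expr.loc[gid, "max_rna"]
                prot = expr.loc[gid, "max_protein"]
        in_peak = int(((annotations.peaks["chrom"] == chrom)
                       & (annotations.peaks["start"] <= pos - 1)
                       & (annotations.peaks["end"] > pos - 1)).any())
        rows.append({
            "site_id": G.sites["site_id"].iloc[j],
            "mean_ld_r2": snp_mean_r2(G, j, ld_window_bp),
            "gerp_at_site": cons.get((chrom, pos), np.nan),
            "in_atac_peak": in_peak,
            "location_genic": int(types[iid_of[k]] == "genic"),
            "max_rna_expression": rna,
            "max_protein_expression": prot,
        })
    return pd.DataFrame(rows).set_index("site_id")


def impute_features(F: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing feature values, adding a missingness indicator
    per imputed column (tree models split on it freely)."""
    out = F.copy()
    for col in F.columns:
        miss = F[col].isna()
        if miss.any():
            med = F[col].median()
            out[col] = F[col].fillna(0.0 if np.isnan(med) else med)
            out[f"{col}_missing"] = miss.astype(int)
    return out


MODEL_FEATURES = {
    "model1": "nuisance",
    "model2": "nuisance+bio",
    "model3": "nuisance+bio+go",
    "model4": "nuisance+bio",
}


def _feature_columns(F: pd.DataFrame, model: str) -> list[str]:
    go_cols = [c for c in F.columns if c.startswith("go_")]
    base = [c for c in F.columns if not c.startswith("go_")]
    nuisance = [c for c in base
                if c.split("_missing")[0] in NUISANCE_FEATURES]
    if model == "model1":
        return nuisance
    if model in ("model2", "model4"):
        return base
    if model == "model3":
        return base + go_cols
    raise ValueError(f"unknown model {model!r}")


@dataclass
class LocoResult:
    """Leave-one-chromosome-out fit of one model."""

    model: str
    fold_r2: dict[str, float]
    predictions: pd.Series        # held-out prediction per unit
    importances: pd.DataFrame     # feature x fold raw importance
    hyperparameters: dict = field(default_factory=dict)
    train_r2: dict[str, float] = field(default_factory=dict)

    @property
    def mean_r2(self) -> float:
        vals = [v for v in self.fold_r2.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def importance_summary(self) -> pd.DataFrame:
        m = self.importances.mean(axis=1)
        se = self.importances.std(axis=1, ddof=1) / np.sqrt(self.importances.shape[1])
        return pd.DataFrame({"mean": m, "se": se})


def _make_estimator(model: str, seed: int, n_trees: int, xgb_params: Mapping | None):
    if model in ("model1", "model2", "model3"):
        return RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    import xgboost as xgb

    params = dict(learning_rate=0.5, max_depth=6, n_estimators=100,
                  random_state=seed, n_jobs=1, verbosity=0)
    params.update(xgb_params or {})
    return xgb.XGBRegressor(**params)


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0] ** 2)


def fit_loco(
    F: pd.DataFrame,
    y: pd.Series,
    chrom_of_unit: pd.Series,
    model: str = "model1",
    seed: int = 0,
    n_trees: int = 500,
    xgb_params: Mapping | None = None,
) -> LocoResult:
    """Fit one model with leave-one-chromosome-out evaluation.

    ``chrom_of_unit`` maps each unit to its chromosome; every fold must
    have non-empty train and test sets.  Per-fold seeds are
    fold_index + seed for reproducibility.
    """
    units = F.index
    y = y.reindex(units)
    chroms = chrom_of_unit.reindex(units)
    if chroms.nunique() < 2:
        raise ValueError("LOCO needs >= 2 chromosomes")
    cols = _feature_columns(F, model)
    Fi = impute_features(F[cols])
    preds = pd.Series(np.nan, index=units, dtype=float)
    fold_r2, train_r2 = {}, {}
    imps = {}
    for fold_i, chrom in enumerate(sorted(chroms.unique())):
        test = chroms == chrom
        if test.all() or not test.any():
            raise ValueError(f"fold {chrom!r} has an empty train or test set")
        est = _make_estimator(model, seed + fold_i, n_trees, xgb_params)
        Xtr, ytr = Fi.loc[~test].to_numpy(), y.loc[~test].to_numpy()
        est.fit(Xtr, ytr)
        yhat = est.predict(Fi.loc[test].to_numpy())
        preds.loc[test] = yhat
        fold_r2[str(chrom)] = _pearson_r2(yhat, y.loc[test].to_numpy())
        train_r2[str(chrom)] = _pearson_r2(est.predict(Xtr), ytr)
        imps[str(chrom)] = pd.Series(est.feature_importances_, index=Fi.columns)
    hp = ({"n_estimators": n_trees, "importance": "impurity"}
          if model != "model4"
          else {"eta": 0.5, "max_depth": 6, "n_rounds": 100, **(xgb_params or {})})
    return LocoResult(model=model, fold_r2=fold_r2, predictions=preds,
                      importances=pd.DataFrame(imps), hyperparameters=hp,
                      train_r2=train_r2)


def relative_importance(L: LocoResult) -> pd.Series:
    """Fold-mean importances divided by the maximum (top feature = 1.0)."""
    m = L.importances.mean(axis=1)
    top = m.max()
    if top <= 0:
        log.warning("all-zero importances for %s", L.model)
        return m * 0.0
    return m / top


def adjusted_pleiotropy(y: pd.Series, L_model1: LocoResult) -> pd.Series:
    """Observed count minus the held-out nuisance-model prediction."""
    pred = L_model1.predictions.reindex(y.index)
    missing = pred.isna()
    if missing.any():
        log.warning("%d units lack a held-out prediction, excluded", missing.sum())
    return (y - pred).dropna()
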