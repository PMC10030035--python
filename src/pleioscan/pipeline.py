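"""End-to-end orchestration: simulate -> covariates -> associate -> permute
-> count -> score -> adjust -> enrich, from one config and one master seed.

Each stage writes its artifacts under the output directory and records row
counts and checksums in ``manifest.json``.  With ``resume=True`` a stage
whose artifacts already exist is not recomputed: cheap deterministic stages
(simulation, covariates) are regenerated in memory without rewriting, and
expensive stages (association scans, counting, scoring, adjustment) are
loaded back from their files, so deleting only a late stage's outputs
re-executes only that stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .adjust import (LocoResult, adjusted_pleiotropy, build_feature_table,
                     fit_loco, relative_importance)
from .association import fast_association, maf_filter, union_min_p
from .containers import CATEGORIES, CovariateMatrix, TraitMatrix
from .covariates import (compute_global_pcs, compute_window_pcs,
                         estimate_hidden_factors, permute_phenotypes)
from .enrich import fisher_go_enrichment, percentile_sets, top_terms
from .intervals import assign_hits, build_count_table, subsample_sites
from .io import (write_bed, write_covariates, write_gff3, write_phenotypes,
                 write_vcf)
from .pleioscore import score_table, summarize_category
from .simdata import SimConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every global constant of a run, with the study defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_perm: Mapping[str, int] = field(default_factory=lambda: {
        "nam_field": 10, "gap_field": 10, "mass_feature": 10, "expression": 5})
    p_threshold: float = 1e-5
    min_maf: float = 0.01
    fold_threshold: float = 5.0
    percentile_pairs: tuple = ((75, 25), (90, 10), (99, 1))
    nam_mode: bool = True
    global_pc_k: int = 3
    window_genes: int = 20        # scaled to the synthetic genome (real-data value: 360)
    shift_genes: int = 10         # real-data value: 180
    var_target: float = 0.15
    n_hidden_factors: int = 3
    models: tuple = ("model1", "model2", "model3", "model4")
    n_trees: int = 500
    site_level: bool = False
    n_site_sample: int = 1000
    write_vcf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.n_perm.values()):
            raise ValueError("n_perm must be >= 1 per category")
        for name in ("p_threshold", "min_maf", "fold_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return RunConfig(sim=sim, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["traits_per_category"] = dict(d["sim"]["traits_per_category"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    """In-memory handle on a completed run."""

    config: RunConfig
    out_dir: Path
    cohort: object
    covariates: dict
    hits: dict          # category -> replicate -> labeled hit DataFrame
    counts: dict        # category -> count table
    scores: dict        # category -> score table
    summaries: dict     # category -> CategorySummary
    features: dict      # category -> feature table
    loco: dict          # category -> model -> LocoResult
    adjusted: dict      # category -> adjusted pleiotropy Series
    enrichment: dict    # (category, hi, lo, side) -> result table
    manifest: dict


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: dict[str, dict] = {}
        self.stages: dict[str, dict] = {}

    def record(self, path: Path, rows: int | None = None) -> None:
        rel = str(path.relative_to(self.out_dir))
        self.entries[rel] = {"rows": rows, "sha256": _checksum(path)}

    def stage(self, name: str, status: str, seconds: float) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3)}
        log.info("stage %-10s %-8s %.2fs", name, status, seconds)

    def write(self, cfg: RunConfig) -> dict:
        payload = {
            "config": yaml.safe_load(yaml.safe_dump(dataclasses.asdict(cfg))),
            "seed": cfg.seed,
            "stages": self.stages,
            "artifacts": self.entries,
        }
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        return payload


def _write_df(df: pd.DataFrame, path: Path, manifest: _Manifest, **kw) -> None:
    df.to_csv(path, **kw)
    manifest.record(path, rows=len(df))


def _category_covariates(cov: dict, category: str, nam_mode: bool):
    """Covariate blocks per scan model for one category."""
    g = cov["global"]
    if category == "nam_field" and nam_mode:
        return {"main_window": CovariateMatrix.hstack([g, cov["main"]]),
                "mid_window": CovariateMatrix.hstack([g, cov["mid"]])}
    if category == "expression" and cov.get("factors") is not None \
            and cov["factors"].values.shape[1]:
        return {"global": CovariateMatrix.hstack([g, cov["factors"]])}
    return {"global": g}


def run_pipeline(cfg: RunConfig, out_dir, resume: bool = False) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    categories = [c for c in CATEGORIES if cfg.sim.traits_per_category.get(c, 0) > 0]

    # ---- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    cohort = simulate_cohort(cfg.sim)
    sim_files = [out / "phenotypes.csv", out / "traits_meta.csv", out / "genes.gff3",
                 out / "intervals.bed", out / "conservation.tsv", out / "peaks.bed",
                 out / "expression.csv", out / "go_map.tsv", out / "truth.json"]
    if resume and all(p.exists() for p in sim_files):
        manifest.stage("simulate", "resumed", time.perf_counter() - t0)
    else:
        write_phenotypes(cohort.traits, out / "phenotypes.csv", out / "traits_meta.csv")
        write_gff3(cohort.genes, out / "genes.gff3")
        bed = cohort.intervals.df.rename(columns={"interval_id": "name"})
        write_bed(bed, out / "intervals.bed")
        cohort.annotations.conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)
        write_bed(cohort.annotations.peaks, out / "peaks.bed")
        cohort.annotations.expression.to_csv(out / "expression.csv", index=False)
        cohort.annotations.go_map.to_csv(out / "go_map.tsv", sep="\t", index=False)
        cohort.truth.to_json(out / "truth.json")
        if cfg.write_vcf:
            write_vcf(cohort.genotypes, out / "genotypes.vcf")
            manifest.record(out / "genotypes.vcf")
        for p in sim_files:
            manifest.record(p)
        manifest.stage("simulate", "computed", time.perf_counter() - t0)

    # ---- covariates -----------------------------------------------------
    t0 = time.perf_counter()
    G = cohort.genotypes
    cov = {"global": compute_global_pcs(G, G, k=cfg.global_pc_k)}
    if cfg.nam_mode and "nam_field" in categories:
        cov["main"], cov["mid"] = compute_window_pcs(
            G, cohort.genes, window_genes=cfg.window_genes,
            shift_genes=cfg.shift_genes, var_target=cfg.var_target)
    if "expression" in categories and cfg.n_hidden_factors > 0:
        expr = cohort.traits.subset(cohort.traits.category_traits("expression"))
        # factors of global-PC residuals, standing in for latent batch structure
        Xg = cov["global"].values.to_numpy()
        Q, _ = np.linalg.qr(np.column_stack([np.ones(len(expr.samples)), Xg]))
        Y = expr.values.to_numpy(dtype=float)
        resid = Y - Q @ (Q.T @ Y)
        resid_T = TraitMatrix(pd.DataFrame(resid, index=expr.values.index,
                                           columns=expr.values.columns),
                              expr.categories, expr.trait_types)
        cov["factors"] = estimate_hidden_factors(resid_T, cfg.n_hidden_factors)
    all_cov = CovariateMatrix.hstack([cov[k] for k in cov])
    cov_path = out / "covariates.csv"
    if not (resume and cov_path.exists()):
        write_covariates(all_cov, cov_path)
        manifest.record(cov_path, rows=all_cov.values.shape[0])
    manifest.stage("covariates", "computed", time.perf_counter() - t0)

    # ---- association ----------------------------------------------------
    t0 = time.perf_counter()
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    Gf = maf_filter(G, cfg.min_maf)
    hits: dict[str, dict[str, pd.DataFrame]] = {}
    assoc_resumed = True
    for cat in categories:
        models = _category_covariates(cov, cat, cfg.nam_mode)
        T_cat = cohort.traits.subset(cohort.traits.category_traits(cat))
        n_perm = cfg.n_perm.get(cat, 10)
        replicates = ["observed"] + [f"perm_{i + 1}" for i in range(n_perm)]
        paths = {rep: hits_dir / f"{cat}.{rep}.tsv" for rep in replicates}
        hits[cat] = {}
        if resume and all(p.exists() for p in paths.values()):
            for rep, p in paths.items():
                hits[cat][rep] = pd.read_csv(p, sep="\t")
            continue
        assoc_resumed = False
        perm_seed = int(substream(cfg.seed, f"perm/{cat}").integers(2**31))
        # residual-permute under each scan model's own covariates (a replicate
        # permuted under model A but scanned under model B would retain a
        # genotype-aligned fitted component B does not remove, inflating null
        # hits); the shuffle indices are shared across models via the seed
        perms_by_model = {tag: permute_phenotypes(T_cat, C, n_perm, seed=perm_seed)
                          for tag, C in models.items()}
        replicate_traits = {"observed": {tag: T_cat for tag in models}}
        for i in range(n_perm):
            replicate_traits[f"perm_{i + 1}"] = {
                tag: perms_by_model[tag].replicates[i] for tag in models}
        for rep, per_model in replicate_traits.items():
            stores = [fast_association(per_model[tag], Gf, C,
                                       p_threshold=cfg.p_threshold,
                                       model_tag=tag, category=cat, replicate=rep)
                      for tag, C in models.items()]
            store = stores[0]
            for other in stores[1:]:
                store = union_min_p(store, other)
            labeled = assign_hits(store.df, cohort.intervals)
            hits[cat][rep] = labeled
            labeled.to_csv(paths[rep], sep="\t", index=False)
            manifest.record(paths[rep], rows=len(labeled))
    manifest.stage("associate", "resumed" if assoc_resumed else "computed",
                   time.perf_counter() - t0)

    # ---- count ----------------------------------------------------------
    t0 = time.perf_counter()
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    units = list(cohort.intervals.ids)
    counts: dict[str, pd.DataFrame] = {}
    for cat in categories:
        path = counts_dir / f"{cat}.interval.csv"
        if resume and path.exists():
            counts[cat] = pd.read_csv(path, index_col="interval_id")
            continue
        reps = {("observed" if r == "observed" else r): h for r, h in hits[cat].items()}
        table = build_count_table(reps, units, level="interval")
        counts[cat] = table
        _write_df(table, path, manifest, index_label="interval_id")
    if cfg.site_level:
        site_seed = int(substream(cfg.seed, "site_subsample").integers(2**31))
        sub_idx = subsample_sites(Gf, min(cfg.n_site_sample, Gf.n_sites), site_seed)
        site_units = list(Gf.sites["site_id"].iloc[sub_idx])
        for cat in categories:
            path = counts_dir / f"{cat}.site.csv"
            if resume and path.exists():
                continue
            table = build_count_table(hits[cat], site_units, level="site")
            _write_df(table, path, manifest, index_label="site_id")
    manifest.stage("count", "computed", time.perf_counter() - t0)

    # ---- score ----------------------------------------------------------
    t0 = time.perf_counter()
    scores_dir = out / "scores"
    scores_dir.mkdir(exist_ok=True)
    types = cohort.intervals.types()
    scores, summaries = {}, {}
    for cat in categories:
        path = scores_dir / f"{cat}.csv"
        if resume and path.exists():
            scores[cat] = pd.read_csv(path, index_col="interval_id")
        else:
            scores[cat] = score_table(counts[cat], unit_types=types,
                                      fold_threshold=cfg.fold_threshold)
            _write_df(scores[cat], path, manifest, index_label="interval_id")
            # histogram export for the enrichment-distribution figure
            hist = (scores[cat].assign(bin=pd.cut(scores[cat]["enrichment"],
                                                  bins=np.linspace(-3, 3, 61)))
                    .groupby(["bin", "unit_type"], observed=True)
                    .size().rename("n_units").reset_index())
            _write_df(hist, scores_dir / f"{cat}.hist.csv", manifest, index=False)
        n_traits = cfg.sim.traits_per_category.get(cat, 0)
        summaries[cat] = summarize_category(scores[cat], category=cat, n_traits=n_traits)
    with open(scores_dir / "summary.json", "w") as fh:
        json.dump({c: s.as_dict() for c, s in summaries.items()}, fh, indent=1)
    manifest.record(scores_dir / "summary.json")
    manifest.stage("score", "computed", time.perf_counter() - t0)

    # ---- adjust ---------------------------------------------------------
    t0 = time.perf_counter()
    adj_dir = out / "adjusted"
    adj_dir.mkdir(exist_ok=True)
    chrom_of_unit = pd.Series(cohort.intervals.df["chrom"].to_numpy(),
                              index=cohort.intervals.df["interval_id"].to_numpy())
    features, loco, adjusted = {}, {}, {}
    adj_resumed = resume and all(
        (adj_dir / f"{cat}.csv").exists() for cat in categories)
    if adj_resumed:
        for cat in categories:
            adjusted[cat] = pd.read_csv(adj_dir / f"{cat}.csv",
                                        index_col="interval_id")["adjusted"]
        manifest.stage("adjust", "resumed", time.perf_counter() - t0)
    else:
        fit_seed = int(substream(cfg.seed, "loco").integers(2**20))
        # expression first: its adjusted scores feed the other categories
        order = (["expression"] if "expression" in categories else []) + \
            [c for c in categories if c != "expression"]
        adj_expr = None
        for cat in order:
            y = counts[cat]["observed"].astype(float)
            F = build_feature_table(
                cohort.intervals, Gf, cohort.annotations,
                hits=hits[cat]["observed"],
                adj_expression=None if cat == "expression" else adj_expr,
                seed=fit_seed)
            features[cat] = F
            loco[cat] = {}
            for model in cfg.models:
                loco[cat][model] = fit_loco(F, y, chrom_of_unit, model=model,
                                            seed=fit_seed, n_trees=cfg.n_trees)
            adjusted[cat] = adjusted_pleiotropy(y, loco[cat]["model1"])
            if cat == "expression":
                adj_expr = adjusted[cat]
            _write_df(F, out / "adjusted" / f"{cat}.features.csv", manifest,
                      index_label="interval_id")
            _write_df(adjusted[cat].rename("adjusted").to_frame(),
                      adj_dir / f"{cat}.csv", manifest, index_label="interval_id")
            imp = pd.DataFrame({m: relative_importance(loco[cat][m])
                                for m in cfg.models})
            _write_df(imp, adj_dir / f"{cat}.importance.csv", manifest,
                      index_label="feature")
        loco_payload = {
            cat: {m: {"fold_r2": L.fold_r2, "train_r2": L.train_r2,
                      "mean_r2": L.mean_r2,
                      "hyperparameters": L.hyperparameters,
                      "relative_importance": relative_importance(L).to_dict()}
                  for m, L in loco[cat].items()}
            for cat in loco}
        with open(adj_dir / "loco.json", "w") as fh:
            json.dump(loco_payload, fh, indent=1, default=float)
        manifest.record(adj_dir / "loco.json")
        manifest.stage("adjust", "computed", time.perf_counter() - t0)

    # ---- enrich ---------------------------------------------------------
    t0 = time.perf_counter()
    enrich_dir = out / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    interval_genes = cohort.intervals.interval_genes()
    genic_ids = set(cohort.intervals.genic()["interval_id"])
    enrichment = {}
    for cat in categories:
        adj_genic = adjusted[cat][adjusted[cat].index.isin(genic_ids)]
        for hi, lo in cfg.percentile_pairs:
            high, low, universe = percentile_sets(
                adj_genic, interval_genes, cohort.annotations.go_map,
                hi_pct=hi, lo_pct=lo)
            for side, genes in (("high", high), ("low", low)):
                path = enrich_dir / f"{cat}.p{hi}_{lo}.{side}.csv"
                if resume and path.exists():
                    enrichment[(cat, hi, lo, side)] = pd.read_csv(path)
                    continue
                res = fisher_go_enrichment(genes, universe, cohort.annotations.go_map)
                enrichment[(cat, hi, lo, side)] = res
                _write_df(res, path, manifest, index=False)
                _write_df(top_terms(res), enrich_dir / f"{cat}.p{hi}_{lo}.{side}.top.csv",
                          manifest, index=False)
    manifest.stage("enrich", "computed", time.perf_counter() - t0)

    payload = manifest.write(cfg)
    return PipelineResult(config=cfg, out_dir=out, cohort=cohort, covariates=cov,
                          hits=hits, counts=counts, scores=scores,
                          summaries=summaries, features=features, loco=loco,
                          adjusted=adjusted, enrichment=enrichment, manifest=payload)
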