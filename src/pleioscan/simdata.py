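"""Synthetic multi-trait GWAS cohorts with known, planted pleiotropy.

The generator emulates the structure of a maize-style many-trait mapping
study: LD-block genotypes with subpopulation differentiation, four
population-trait categories (structured-panel field traits, diversity-panel
field traits, mass-spectrometry features, RNA expression), a polygenic +
noise phenotype model in which a controllable fraction of genic intervals
carry causal sites shared across several traits, hidden batch factors for
the expression category, and functional annotation tracks (conservation,
chromatin peaks, expression maxima, GO terms) whose association with true
pleiotropy is tunable.

LD model
--------
Within an LD block every haplotype draws a per-site uniform that copies a
per-sample block anchor with probability sqrt(within_block_r) (one shared
allele frequency per block).  Two sites in a block then have dosage
correlation exactly within_block_r, so pairwise r2 within blocks equals
within_block_r**2 — a directly controllable LD dial without coalescent
machinery.  Subpopulation differentiation follows a Balding–Nichols
frequency model with divergence parameter ``fst_like_divergence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import CATEGORIES, AnnotationBundle, GenotypeMatrix, TraitMatrix
from .intervals import IntervalSet, build_intervals

__all__ = ["SimConfig", "SimTruth", "SimCohort", "simulate_genotypes",
           "simulate_gene_annotation", "simulate_traits", "simulate_annotations",
           "simulate_cohort"]

FIELD_TRAIT_TYPES = ("flowering", "disease", "tassel", "ear", "leaf", "height",
                     "vegetative", "kernel")


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults give a small structured panel."""

    n_samples: int = 400
    n_chrom: int = 5
    sites_per_chrom: int = 1500
    ld_block_len: int = 20
    within_block_r: float = 0.6
    n_subpops: int = 3
    fst_like_divergence: float = 0.1
    genes_per_chrom: int = 40
    gene_len_bp: int = 5000
    chrom_len_bp: int = 1_000_000
    traits_per_category: Mapping[str, int] = field(
        default_factory=lambda: {"nam_field": 25, "gap_field": 25,
                                 "mass_feature": 25, "expression": 30})
    pleiotropy_rate: float = 0.05
    traits_per_pleiotropic_site: int = 5
    h2: float = 0.6
    n_hidden_factors: int = 3
    seed: int = 0
    # secondary knobs
    causal_sites_per_trait: int = 3
    structure_confound_sd: float = 0.0
    confounded_trait_fraction: float = 0.3
    concordant_shared_effects: bool = False
    annotation_coupling: float | Mapping[str, float] = 0.0
    n_go_terms: int = 21

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_chrom", "sites_per_chrom", "ld_block_len",
                     "n_subpops", "genes_per_chrom", "gene_len_bp", "chrom_len_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (association needs residual df)")
        if not 0.0 <= self.within_block_r <= 1.0:
            raise ValueError("within_block_r must be in [0, 1]")
        if not 0.0 <= self.fst_like_divergence <= 0.5:
            raise ValueError("fst_like_divergence must be in [0, 0.5]")
        if self.ld_block_len > self.sites_per_chrom:
            raise ValueError("ld_block_len must be <= sites_per_chrom")
        if not 0.0 <= self.pleiotropy_rate <= 1.0:
            raise ValueError("pleiotropy_rate must be in [0, 1]")
        if self.traits_per_pleiotropic_site < 2:
            raise ValueError("traits_per_pleiotropic_site must be >= 2")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if any(v < 1 for v in self.traits_per_category.values()):
            raise ValueError("every category needs >= 1 trait")
        if self.genes_per_chrom * self.gene_len_bp >= self.chrom_len_bp:
            raise ValueError("genes do not fit in chrom_len_bp without overlap")

    def coupling(self, track: str) -> float:
        c = self.annotation_coupling
        if isinstance(c, Mapping):
            return float(c.get(track, 0.0))
        return float(c)

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lens(self) -> dict[str, int]:
        return {c: self.chrom_len_bp for c in self.chroms}


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for truth-based recovery tests."""

    causal_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    pleiotropic_intervals: set[str] = field(default_factory=set)
    shared_sites: dict[str, str] = field(default_factory=dict)  # site -> interval
    structure_labels: pd.Series | None = None
    hidden_factor_loadings: pd.DataFrame | None = None
    block_of_site: pd.Series | None = None

    def interval_degree(self, intervals: IntervalSet, G: GenotypeMatrix) -> pd.Series:
        """Distinct causally-affected traits per interval (0 where none)."""
        deg = pd.Series(0, index=intervals.ids)
        if not self.causal_map:
            return deg
        causal_sites = [s for s in self.causal_map]
        idx = G.site_indexer()
        present = [s for s in causal_sites if s in idx.index]
        sub = G.sites.set_index("site_id").loc[present]
        iid = intervals.locate(sub["chrom"].to_numpy(), sub["pos"].to_numpy() - 1)
        per_int: dict[str, set[str]] = {}
        for s, i in zip(present, iid):
            per_int.setdefault(i, set()).update(t for t, _ in self.causal_map[s])
        for i, traits in per_int.items():
            deg[i] = len(traits)
        return deg

    def to_json(self, path) -> None:
        payload = {
            "causal_map": {s: [[t, float(b)] for t, b in v] for s, v in self.causal_map.items()},
            "pleiotropic_intervals": sorted(self.pleiotropic_intervals),
            "shared_sites": self.shared_sites,
            "structure_labels": (self.structure_labels.astype(int).to_dict()
                                 if self.structure_labels is not None else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimCohort:
    """Everything one synthetic study needs, generated from a single seed."""

    config: SimConfig
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    intervals: IntervalSet
    traits: TraitMatrix
    annotations: AnnotationBundle
    truth: SimTruth


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    rng = substream(cfg.seed, "genotypes")
    n, F, c = cfg.n_samples, cfg.fst_like_divergence, np.sqrt(cfg.within_block_r)
    subpop = rng.integers(0, cfg.n_subpops, size=n)
    samples = [f"s{i:04d}" for i in range(n)]

    dosage_cols, recs, blocks = [], [], []
    block_id = 0
    for chrom in cfg.chroms:
        positions = np.unique(
            (np.arange(1, cfg.sites_per_chrom + 1)
             * (cfg.chrom_len_bp // (cfg.sites_per_chrom + 1))))
        s = 0
        while s < cfg.sites_per_chrom:
            blen = min(cfg.ld_block_len, cfg.sites_per_chrom - s)
            p0 = rng.uniform(0.1, 0.5)
            if F > 0 and cfg.n_subpops > 1:
                a = p0 * (1 - F) / F
                b = (1 - p0) * (1 - F) / F
                p_sub = np.clip(rng.beta(a, b, size=cfg.n_subpops), 0.02, 0.98)
            else:
                p_sub = np.full(cfg.n_subpops, p0)
            p_sample = p_sub[subpop][:, None]  # (n, 1) per haplotype broadcast
            anchor = rng.random((n, 2))
            for _ in range(blen):
                fresh = rng.random((n, 2))
                use_anchor = rng.random((n, 2)) < c
                u = np.where(use_anchor, anchor, fresh)
                dosage_cols.append((u < p_sample).sum(axis=1).astype(np.float64))
                recs.append((f"{chrom}_{positions[s]}", chrom, int(positions[s]), "A", "T"))
                blocks.append(block_id)
                s += 1
            block_id += 1
    sites = pd.DataFrame(recs, columns=["site_id", "chrom", "pos", "ref", "alt"])
    G = GenotypeMatrix(np.column_stack(dosage_cols), sites, samples)
    truth = SimTruth(
        structure_labels=pd.Series(subpop, index=samples),
        block_of_site=pd.Series(blocks, index=sites["site_id"]),
    )
    return G, truth


def simulate_gene_annotation(cfg: SimConfig, overlap: bool = False) -> pd.DataFrame:
    """Place non-overlapping genes in per-chromosome slots (0-based half-open).

    With ``overlap=True`` every second gene is shifted to overlap its
    predecessor by half a gene length, to exercise interval merging.
    """
    rng = substream(cfg.seed, "genes")
    slot = cfg.chrom_len_bp // cfg.genes_per_chrom
    if slot <= cfg.gene_len_bp:
        raise ValueError("genes do not fit: decrease genes_per_chrom or gene_len_bp")
    recs = []
    k = 0
    for chrom in cfg.chroms:
        starts = []
        for g in range(cfg.genes_per_chrom):
            start = g * slot + int(rng.integers(0, slot - cfg.gene_len_bp))
            starts.append(start)
        if overlap:
            for g in range(1, cfg.genes_per_chrom, 2):
                starts[g] = starts[g - 1] + cfg.gene_len_bp // 2
        for start in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append((f"gene{k:05d}", chrom, start, start + cfg.gene_len_bp, strand))
            k += 1
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"])


def _trait_ids(cfg: SimConfig) -> tuple[list[str], pd.Series, pd.Series]:
    ids, cats, types = [], [], []
    for cat in CATEGORIES:
        n_t = cfg.traits_per_category.get(cat, 0)
        for i in range(n_t):
            ids.append(f"{cat}.t{i:04d}")
            cats.append(cat)
            if cat in ("nam_field", "gap_field"):
                types.append(FIELD_TRAIT_TYPES[i % len(FIELD_TRAIT_TYPES)])
            elif cat == "mass_feature":
                types.append("mass")
            else:
                types.append(f"tissue{i % 7}")
    return ids, pd.Series(cats, index=ids), pd.Series(types, index=ids)


def simulate_traits(
    G: GenotypeMatrix, intervals: IntervalSet, cfg: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[TraitMatrix, SimTruth]:
    """Polygenic traits with planted shared causal sites.

    Each trait is a standardized genetic value (its own causal sites plus any
    shared sites) scaled to variance h2, plus subpopulation mean shifts on a
    random subset of traits (if structure_confound_sd > 0), plus hidden-factor
    contributions for expression traits, plus Gaussian noise of variance 1-h2.
    """
    rng = substream(cfg.seed, "traits")
    truth = truth or SimTruth()
    trait_ids, cats, types = _trait_ids(cfg)
    n = G.n_samples

    # map sites to intervals once
    iid_of_site = intervals.locate(G.sites["chrom"].to_numpy(),
                                   G.sites["pos"].to_numpy() - 1)
    genic_ids = list(intervals.genic()["interval_id"])
    sites_in = {i: np.flatnonzero(iid_of_site == i) for i in genic_ids}
    candidates = [i for i in genic_ids if len(sites_in[i]) > 0]

    n_pleio = int(round(cfg.pleiotropy_rate * len(genic_ids)))
    n_pleio = min(n_pleio, len(candidates))
    pleio_intervals = list(rng.choice(candidates, size=n_pleio, replace=False)) if n_pleio else []

    causal_map: dict[str, list[tuple[str, float]]] = {}

    def add_effect(site_id: str, trait: str, beta: float) -> None:
        causal_map.setdefault(site_id, []).append((trait, float(beta)))

    # private polygenic background
    for t in trait_ids:
        if cfg.causal_sites_per_trait > 0:
            picks = rng.choice(G.n_sites, size=cfg.causal_sites_per_trait, replace=False)
            for j in picks:
                add_effect(G.sites["site_id"].iloc[j], t, rng.normal())

    # shared causal sites: one per pleiotropic interval, all its traits from
    # one category so category-level counting can see the sharing
    by_cat = {c: [t for t in trait_ids if cats[t] == c] for c in CATEGORIES}
    cat_cycle = [c for c in CATEGORIES if by_cat[c]]
    for k, iid in enumerate(pleio_intervals):
        j = int(rng.choice(sites_in[iid]))
        site_id = G.sites["site_id"].iloc[j]
        cat = cat_cycle[k % len(cat_cycle)]
        pool = by_cat[cat]
        m = min(cfg.traits_per_pleiotropic_site, len(pool))
        chosen = rng.choice(pool, size=m, replace=False)
        mag = abs(rng.normal())  # one magnitude draw per shared site
        for t in chosen:
            sign = 1.0 if cfg.concordant_shared_effects else (1.0 if rng.random() < 0.5 else -1.0)
            add_effect(site_id, t, sign * mag)
        truth.shared_sites[site_id] = iid
        truth.pleiotropic_intervals.add(iid)

    # standardized genotypes for causal sites only
    idx = G.site_indexer()
    sd = G.dosages.std(axis=0)
    mean = G.dosages.mean(axis=0)

    Y = np.empty((n, len(trait_ids)))
    per_trait: dict[str, list[tuple[int, float]]] = {t: [] for t in trait_ids}
    for s, lst in causal_map.items():
        j = int(idx[s])
        for t, b in lst:
            per_trait[t].append((j, b))

    # structure confound: subpop mean shifts on a random trait subset
    confounded = (rng.random(len(trait_ids)) < cfg.confounded_trait_fraction) \
        if cfg.structure_confound_sd > 0 else np.zeros(len(trait_ids), bool)
    labels = (truth.structure_labels.to_numpy()
              if truth.structure_labels is not None else np.zeros(n, int))
    n_sub = int(labels.max()) + 1

    # hidden factors for the expression category
    k_f = cfg.n_hidden_factors
    factors = rng.normal(size=(n, k_f)) if k_f > 0 else np.zeros((n, 0))
    loadings = pd.DataFrame(0.0, index=trait_ids,
                            columns=[f"factor{j}" for j in range(k_f)])

    for ti, t in enumerate(trait_ids):
        eff = per_trait[t]
        gv = np.zeros(n)
        for j, b in eff:
            if sd[j] > 0:
                gv += b * (G.dosages[:, j] - mean[j]) / sd[j]
        gsd = gv.std()
        y = (np.sqrt(cfg.h2) * gv / gsd) if gsd > 0 else np.zeros(n)
        y = y + np.sqrt(1.0 - cfg.h2) * rng.normal(size=n)
        if confounded[ti]:
            shifts = rng.normal(scale=cfg.structure_confound_sd, size=n_sub)
            y = y + shifts[labels]
        if cats[t] == "expression" and k_f > 0:
            lam = rng.normal(scale=0.7, size=k_f)
            loadings.loc[t] = lam
            y = y + factors @ lam
        Y[:, ti] = y

    T = TraitMatrix(pd.DataFrame(Y, index=G.samples, columns=trait_ids), cats, types)
    truth.causal_map = causal_map
    truth.hidden_factor_loadings = loadings
    return T, truth


def simulate_annotations(
    intervals: IntervalSet, truth: SimTruth, genes: pd.DataFrame,
    G: GenotypeMatrix, cfg: SimConfig,
) -> AnnotationBundle:
    """Conservation, chromatin peaks, expression maxima and a GO map.

    Per-track coupling in [0, 1] ties the track to true pleiotropy:
    at 0 every track is independent of the planted signal by construction;
    at 1 pleiotropic intervals get deterministically shifted conservation and
    expression, extra peaks, and a dedicated GO term.
    """
    rng = substream(cfg.seed, "annotations")
    deg = truth.interval_degree(intervals, G)
    deg_z = (deg - deg.mean()) / (deg.std() if deg.std() > 0 else 1.0)
    iid_of_site = intervals.locate(G.sites["chrom"].to_numpy(),
                                   G.sites["pos"].to_numpy() - 1)
    in_pleio_interval = pd.Series(
        [i in truth.pleiotropic_intervals for i in iid_of_site],
        index=G.sites["site_id"].to_numpy())

    c_cons = cfg.coupling("conservation")
    cons_score = rng.normal(size=G.n_sites) + \
        c_cons * 2.0 * deg_z.loc[list(iid_of_site)].to_numpy()
    conservation = pd.DataFrame({
        "chrom": G.sites["chrom"], "pos": G.sites["pos"], "score": cons_score})

    c_peak = cfg.coupling("peaks")
    peak_recs = []
    for chrom, clen in intervals.chrom_lens.items():
        for _ in range(cfg.genes_per_chrom):
            start = int(rng.integers(0, clen - 1000))
            peak_recs.append((chrom, start, start + int(rng.integers(200, 1000))))
    for iid in sorted(truth.pleiotropic_intervals):
        row = intervals.df[intervals.df["interval_id"] == iid].iloc[0]
        if rng.random() < c_peak:
            width = max(200, min(500, int(row.end - row.start)))
            peak_recs.append((row.chrom, int(row.start), int(row.start) + width))
    peaks = pd.DataFrame(peak_recs, columns=["chrom", "start", "end"])
    peaks["name"] = [f"peak{i}" for i in range(len(peaks))]

    c_expr = cfg.coupling("expression")
    gene_iid = intervals.locate(genes["chrom"].to_numpy(), genes["start"].to_numpy())
    gene_pleio = np.array([i in truth.pleiotropic_intervals for i in gene_iid])
    expression = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "max_rna": np.exp(rng.normal(size=len(genes)) + 10.0 * c_expr * gene_pleio),
        "max_protein": np.exp(rng.normal(size=len(genes)) + 10.0 * c_expr * gene_pleio),
    })

    c_go = cfg.coupling("go")
    onts = ["BP", "MF", "CC"]
    terms = [f"GO:{7000001 + i:07d}" for i in range(cfg.n_go_terms)]
    term_ont = {t: onts[i % 3] for i, t in enumerate(terms)}
    coupled_term = terms[0]
    go_recs = []
    for g, is_pleio in zip(genes["gene_id"], gene_pleio):
        n_terms = 1 + rng.poisson(2)
        for t in rng.choice(terms[1:], size=min(n_terms, len(terms) - 1), replace=False):
            go_recs.append((g, t, term_ont[t]))
        p_hit = 0.05 + 0.75 * c_go if is_pleio else 0.05
        if rng.random() < p_hit:
            go_recs.append((g, coupled_term, term_ont[coupled_term]))
    go_map = pd.DataFrame(go_recs, columns=["gene_id", "go_id", "ontology"]).drop_duplicates()

    return AnnotationBundle(conservation=conservation, peaks=peaks,
                            expression=expression, go_map=go_map,
                            coupled_go_term=coupled_term)


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """One-call generation of a full synthetic study from a single seed."""
    G, truth = simulate_genotypes(cfg)
    genes = simulate_gene_annotation(cfg)
    intervals = build_intervals(genes, cfg.chrom_lens)
    traits, truth = simulate_traits(G, intervals, cfg, truth)
    ann = simulate_annotations(intervals, truth, genes, G, cfg)
    return SimCohort(config=cfg, genotypes=G, genes=genes, intervals=intervals,
                     traits=traits, annotations=ann, truth=truth)
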