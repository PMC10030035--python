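"""Percentile gene sets and Fisher-exact GO enrichment with FDR control.

Genic intervals are ranked by adjusted pleiotropy; genes in the top
percentile set (75th / 90th / 99th) are "highly pleiotropic", genes in the
bottom set (25th / 10th / 1st) "lowly pleiotropic".  Each GO term is tested
one-sided (enrichment) with Fisher's exact test on the 2x2 table of set
membership x term membership over the annotated-gene universe, and
Benjamini-Hochberg FDR is applied within each ontology (BP / MF / CC)
separately; terms with q < 0.05 are reported, capped at the 13 smallest q
per ontology in the report view (the full table is always returned).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["percentile_sets", "fisher_go_enrichment", "top_terms"]

log = logging.getLogger(__name__)


def percentile_sets(
    adj: pd.Series,
    interval_genes: Mapping[str, Iterable[str]],
    go_map: pd.DataFrame,
    hi_pct: float = 75.0,
    lo_pct: float = 25.0,
) -> tuple[set[str], set[str], set[str]]:
    """High / low adjusted-pleiotropy gene sets and the tested universe.

    ``adj`` must be indexed by genic interval IDs.  Percentiles use linear
    interpolation; ties at the cut are included (>= / <=), so sets can
    slightly exceed their nominal fraction.  The universe is every gene of
    a scored genic interval that carries at least one GO annotation.
    """
    if hi_pct <= lo_pct:
        raise ValueError("hi_pct must exceed lo_pct")
    vals = adj.to_numpy(dtype=float)
    hi_cut = np.percentile(vals, hi_pct)
    lo_cut = np.percentile(vals, lo_pct)
    if np.allclose(vals, vals[0]):
        log.warning("degenerate adjusted scores: all units equal, high = low = all")
    annotated = set(go_map["gene_id"])

    def genes_of(interval_ids) -> set[str]:
        out: set[str] = set()
        for iid in interval_ids:
            out.update(interval_genes.get(iid, ()))
        return out & annotated

    high = genes_of(adj.index[vals >= hi_cut])
    low = genes_of(adj.index[vals <= lo_cut])
    universe = genes_of(adj.index)
    return high, low, universe


def fisher_go_enrichment(
    set_genes: Iterable[str],
    universe: Iterable[str],
    go_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment per GO term with per-ontology BH FDR.

    Returns one row per term with >= 1 set gene: the 2x2 cells
    (a = set & term, b = set without term, c = term outside set, d = rest),
    odds ratio, p, q, gene ratio and a significance flag at q < alpha.
    """
    universe = set(universe)
    set_genes = set(set_genes) & universe
    if not set_genes:
        return pd.DataFrame(columns=[
            "go_id", "ontology", "a_in_set", "b_in_set_not_term",
            "c_term_not_set", "d_rest", "odds_ratio", "p_value", "q_value",
            "gene_ratio", "significant"])
    gm = go_map[go_map["gene_id"].isin(universe)]
    rows = []
    n_u, n_s = len(universe), len(set_genes)
    for (term, ont), sub in gm.groupby(["go_id", "ontology"]):
        term_genes = set(sub["gene_id"])
        a = len(term_genes & set_genes)
        if a == 0:
            continue
        b = n_s - a
        c = len(term_genes) - a
        d = n_u - a - b - c
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, ont, a, b, c, d, orr, p, a / n_s))
    out = pd.DataFrame(rows, columns=[
        "go_id", "ontology", "a_in_set", "b_in_set_not_term", "c_term_not_set",
        "d_rest", "odds_ratio", "p_value", "gene_ratio"])
    out["q_value"] = np.nan
    for ont, idx in out.groupby("ontology").groups.items():
        out.loc[idx, "q_value"] = stats.false_discovery_control(
            out.loc[idx, "p_value"], method="bh")
    out["significant"] = out["q_value"] < alpha
    return out.sort_values(["q_value", "p_value"]).reset_index(drop=True)


def top_terms(result: pd.DataFrame, cap: int = 13) -> pd.DataFrame:
    """Report view: significant terms only, at most ``cap`` per ontology."""
    sig = result[result["significant"]]
    return (sig.sort_values("q_value")
            .groupby("ontology", group_keys=False)
            .head(cap)
            .reset_index(drop=True))
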