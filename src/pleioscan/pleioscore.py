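"""Pseudo-count log enrichment of observed over permuted pleiotropy.

For each unit (interval or SNP) with observed unique-trait count ``obs`` and
mean permuted count ``perm_mean``, the enrichment statistic is

    ln((obs + 1) / (perm_mean + 1))

— the pseudo-count keeps every unit defined, zero counts included.  A unit
is "five-fold enriched" when the pseudo-counted ratio reaches the fold
threshold, i.e. (obs + 1) >= 5 * (perm_mean + 1); the raw ratio is also
reported but the pseudo-counted one carries the flag, consistent with the
plotted statistic whose reference line sits at ln 5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["enrichment_score", "score_table", "summarize_category", "CategorySummary"]


def enrichment_score(obs, perm_mean):
    """ln((obs + 1) / (perm_mean + 1)); vectorized, defined for all counts >= 0."""
    obs = np.asarray(obs, dtype=float)
    perm_mean = np.asarray(perm_mean, dtype=float)
    if (obs < 0).any() or (perm_mean < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.log((obs + 1.0) / (perm_mean + 1.0))
    return out if out.ndim else float(out)


def score_table(
    counts: pd.DataFrame,
    unit_types: pd.Series | None = None,
    fold_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-unit enrichment from an observed + permuted count table.

    ``counts`` must have an ``observed`` column and >= 1 ``perm_*`` columns,
    indexed by unit ID; all replicates must cover the same units (enforced
    by the shared index).  Returns columns observed, perm_mean, enrichment,
    raw_ratio, five_fold and (if given) unit_type.
    """
    perm_cols = [c for c in counts.columns if c.startswith("perm_")]
    if "observed" not in counts.columns or not perm_cols:
        raise ValueError("need an 'observed' column and >= 1 'perm_*' columns")
    if counts[["observed", *perm_cols]].isna().any().any():
        raise ValueError("replicate unit sets differ (missing counts)")
    obs = counts["observed"].astype(float)
    perm_mean = counts[perm_cols].mean(axis=1)
    out = pd.DataFrame({
        "observed": counts["observed"],
        "perm_mean": perm_mean,
        "enrichment": enrichment_score(obs.to_numpy(), perm_mean.to_numpy()),
        "raw_ratio": np.where(perm_mean > 0, obs / perm_mean, np.inf),
        "five_fold": (obs + 1.0) >= fold_threshold * (perm_mean + 1.0) - 1e-12,
    }, index=counts.index)
    if unit_types is not None:
        out["unit_type"] = unit_types.reindex(out.index)
    return out


@dataclass
class CategorySummary:
    """Headline numbers for one population-trait category."""

    category: str
    n_units: int
    pct_flagged: float                 # % of units five-fold enriched
    flagged_min: float | None          # min observed count among flagged units
    flagged_median: float | None
    flagged_max: float | None
    pct_units_le1: float               # % of units with observed count <= 1
    median_pct_traits_contributing: float | None  # median over flagged units of
                                       # observed count / category trait count, in %

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_category(
    scores: pd.DataFrame, category: str = "default", n_traits: int | None = None
) -> CategorySummary:
    """Flagged fraction and observed-count spread among flagged units."""
    if scores.empty:
        raise ValueError("empty score table")
    flagged = scores[scores["five_fold"]]
    obs = flagged["observed"].astype(float)
    frac = 100.0 * len(flagged) / len(scores)
    pct_le1 = 100.0 * float((scores["observed"] <= 1).mean())
    med_contrib = None
    if n_traits and len(flagged):
        med_contrib = float(np.median(100.0 * obs / n_traits))
    return CategorySummary(
        category=category,
        n_units=len(scores),
        pct_flagged=frac,
        flagged_min=float(obs.min()) if len(flagged) else None,
        flagged_median=float(obs.median()) if len(flagged) else None,
        flagged_max=float(obs.max()) if len(flagged) else None,
        pct_units_le1=pct_le1,
        median_pct_traits_contributing=med_contrib,
    )
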