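"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Dosages are diploid allele counts in [0, 2], stored samples x sites.
* Site positions are 1-based (VCF convention); interval arithmetic elsewhere
  converts to 0-based half-open.
* Sample order is the single source of alignment: genotype, trait and
  covariate containers must share it, and constructors check nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitMatrix",
    "CovariateMatrix",
    "AnnotationBundle",
]

#: Population-trait categories used throughout (field traits mapped in a
#: structured multi-family panel, field traits in a diversity panel,
#: mass-spectrometry features, and RNA expression traits).
CATEGORIES = ("nam_field", "gap_field", "mass_feature", "expression")


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with a site map.

    Attributes
    ----------
    dosages : float ndarray, shape (n_samples, n_sites)
    sites : DataFrame with columns site_id, chrom, pos (1-based), ref, alt
    samples : list of sample IDs, aligned with dosage rows
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"shape mismatch: dosages {self.dosages.shape}, "
                f"{len(self.samples)} samples, {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def take_sites(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def site_indexer(self) -> pd.Series:
        """site_id -> column index."""
        return pd.Series(np.arange(self.n_sites), index=self.sites["site_id"])


@dataclass
class TraitMatrix:
    """Samples x traits phenotype table with per-trait category labels."""

    values: pd.DataFrame  # index: sample IDs; columns: trait IDs
    categories: pd.Series  # trait ID -> category
    trait_types: pd.Series | None = None  # trait ID -> finer type label

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.categories.index)
        if missing:
            raise ValueError(f"{len(missing)} traits lack a category label")
        if self.trait_types is None:
            self.trait_types = pd.Series("generic", index=self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def category_traits(self, category: str) -> list[str]:
        return [t for t in self.values.columns if self.categories[t] == category]

    def subset(self, traits: Iterable[str]) -> "TraitMatrix":
        traits = list(traits)
        return TraitMatrix(
            values=self.values[traits],
            categories=self.categories.loc[traits],
            trait_types=self.trait_types.loc[traits],
        )


@dataclass
class CovariateMatrix:
    """Samples x covariates with a provenance tag per column.

    Provenance tags: ``global`` (whole-genome PCs), ``main_window`` /
    ``mid_window`` (gene-window PCs), ``hidden_factor`` (latent expression
    factors).
    """

    values: pd.DataFrame  # index: sample IDs; columns: covariate labels
    provenance: pd.Series  # label -> tag

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("covariates contain missing values")
        if self.values.shape[1] >= self.values.shape[0]:
            raise ValueError("covariate count must be < sample count")
        missing = set(self.values.columns) - set(self.provenance.index)
        if missing:
            raise ValueError("every covariate column needs a provenance tag")

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    @staticmethod
    def empty(samples: Sequence[str]) -> "CovariateMatrix":
        return CovariateMatrix(
            values=pd.DataFrame(index=list(samples)),
            provenance=pd.Series(dtype=object),
        )

    @staticmethod
    def hstack(parts: Sequence["CovariateMatrix"]) -> "CovariateMatrix":
        parts = [p for p in parts if p.values.shape[1] > 0 or len(parts) == 1]
        if not parts:
            raise ValueError("nothing to stack")
        idx = parts[0].values.index
        for p in parts[1:]:
            if not p.values.index.equals(idx):
                raise ValueError("sample order mismatch between covariate blocks")
        return CovariateMatrix(
            values=pd.concat([p.values for p in parts], axis=1),
            provenance=pd.concat([p.provenance for p in parts]),
        )


@dataclass
class AnnotationBundle:
    """Synthetic functional-annotation tracks keyed to one simulated genome.

    conservation : per-site scores (chrom, pos 1-based, score), GERP-like
    peaks : accessible-chromatin peaks, 0-based half-open (chrom, start, end, name)
    expression : per-gene expression maxima across tissues (gene_id, max_rna, max_protein)
    go_map : gene -> GO term table (gene_id, go_id, ontology in {BP, MF, CC})
    coupled_go_term : the GO term (if any) planted to track true pleiotropy
    """

    conservation: pd.DataFrame
    peaks: pd.DataFrame
    expression: pd.DataFrame
    go_map: pd.DataFrame
    coupled_go_term: str | None = None
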