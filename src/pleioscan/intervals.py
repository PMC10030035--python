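"""Genic/intergenic interval partition and unique-trait counting.

The genome is tiled by alternating intervals: overlapping or abutting gene
ranges are merged into single genic intervals, and the per-chromosome
complement forms the intergenic intervals.  Because high LD makes the causal
site of an association ambiguous, pleiotropy is quantified per interval as
the number of *distinct* traits with at least one significant hit inside it
(a trait hitting an interval through many SNPs counts once).

Internally all coordinates are 0-based half-open; GFF3 (1-based inclusive)
and VCF positions (1-based) are converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "IntervalSet",
    "build_intervals",
    "assign_hits",
    "count_unique_traits",
    "build_count_table",
    "subsample_sites",
]

log = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Ordered, disjoint intervals tiling each chromosome.

    ``df`` columns: chrom, start, end (0-based half-open), itype
    ("genic"/"intergenic"), interval_id, genes (comma-joined member gene IDs,
    empty for intergenic).
    """

    df: pd.DataFrame
    chrom_lens: dict[str, int]

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.df["interval_id"])

    def genic(self) -> pd.DataFrame:
        return self.df[self.df["itype"] == "genic"]

    def lengths(self) -> pd.Series:
        return pd.Series(
            (self.df["end"] - self.df["start"]).to_numpy(), index=self.df["interval_id"]
        )

    def types(self) -> pd.Series:
        return pd.Series(self.df["itype"].to_numpy(), index=self.df["interval_id"])

    def interval_genes(self) -> dict[str, list[str]]:
        """interval_id -> member gene IDs (genic intervals only)."""
        out: dict[str, list[str]] = {}
        for row in self.genic().itertuples():
            out[row.interval_id] = [g for g in row.genes.split(",") if g]
        return out

    def locate(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Interval ID containing each 0-based position; raises if any falls
        outside the tiling (signals a chromosome-length mismatch)."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0)
        out = np.empty(len(pos0), dtype=object)
        for c in np.unique(chrom):
            sub = self.df[self.df["chrom"] == c]
            if sub.empty:
                raise ValueError(f"unknown chromosome {c!r}")
            mask = chrom == c
            p = pos0[mask]
            if p.min(initial=0) < 0 or p.max(initial=0) >= self.chrom_lens[c]:
                raise ValueError(f"position outside chromosome {c!r} tiling")
            starts = sub["start"].to_numpy()
            idx = np.searchsorted(starts, p, side="right") - 1
            out[np.flatnonzero(mask)] = sub["interval_id"].to_numpy()[idx]
        return out


def _merge_ranges(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int, list[int]]]:
    """Merge sorted ranges that overlap or abut; returns (start, end, member idx)."""
    merged: list[tuple[int, int, list[int]]] = []
    for i in np.argsort(starts, kind="stable"):
        s, e = int(starts[i]), int(ends[i])
        if merged and s <= merged[-1][1]:  # overlap or abutting -> merge
            ps, pe, members = merged[-1]
            merged[-1] = (ps, max(pe, e), members + [i])
        else:
            merged.append((s, e, [i]))
    return merged


def build_intervals(genes: pd.DataFrame, chrom_lens: Mapping[str, int]) -> IntervalSet:
    """Partition each chromosome into merged genic and intergenic intervals.

    Parameters
    ----------
    genes : DataFrame with columns gene_id, chrom, start, end (0-based
        half-open; :func:`pleioscan.io.read_gff3` converts from GFF3).
    chrom_lens : chromosome -> length in bp.
    """
    records = []
    unknown = set(genes["chrom"]) - set(chrom_lens)
    if unknown:
        raise ValueError(f"genes on unknown chromosomes: {sorted(unknown)}")
    if ((genes["end"] - genes["start"]) <= 0).any():
        raise ValueError("zero- or negative-length gene range")
    for chrom, clen in chrom_lens.items():
        sub = genes[genes["chrom"] == chrom]
        if not sub.empty and int(sub["end"].max()) > clen:
            raise ValueError(f"gene extends beyond chromosome {chrom!r} length {clen}")
        gid = sub["gene_id"].to_numpy()
        merged = _merge_ranges(sub["start"].to_numpy(), sub["end"].to_numpy())
        cursor = 0
        for s, e, members in merged:
            if s > cursor:
                records.append((chrom, cursor, s, "intergenic", ""))
            records.append((chrom, s, e, "genic", ",".join(gid[j] for j in members)))
            cursor = e
        if cursor < clen:
            records.append((chrom, cursor, clen, "intergenic", ""))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "itype", "genes"])
    df["interval_id"] = [
        f"{c}:{s}-{e}:{t}" for c, s, e, t in zip(df["chrom"], df["start"], df["end"], df["itype"])
    ]
    return IntervalSet(df=df, chrom_lens=dict(chrom_lens))


def assign_hits(hits: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """Label each hit (1-based ``pos``) with the interval containing it."""
    out = hits.copy()
    if out.empty:
        out["interval_id"] = pd.Series(dtype=object)
        return out
    out["interval_id"] = intervals.locate(
        out["chrom"].to_numpy(), out["pos"].to_numpy() - 1
    )
    return out


def count_unique_traits(
    labeled_hits: pd.DataFrame, units: Sequence[str], level: str = "interval"
) -> pd.Series:
    """Distinct-trait count per unit for one (category, replicate).

    Units without hits are materialized with count 0: downstream fractions
    are taken over *all* units, not just hit ones.
    """
    key = "interval_id" if level == "interval" else "site_id"
    if labeled_hits.empty:
        counts = pd.Series(0, index=pd.Index(units, name=key))
    else:
        counts = (
            labeled_hits.groupby(key)["trait"].nunique().reindex(units, fill_value=0)
        )
    return counts.astype(int)


def build_count_table(
    hits_by_replicate: Mapping[str, pd.DataFrame],
    units: Sequence[str],
    level: str = "interval",
) -> pd.DataFrame:
    """Unit x replicate table of unique-trait counts.

    ``hits_by_replicate`` maps replicate labels ("observed", "perm_1", ...)
    to labeled hit tables.
    """
    cols = {
        rep: count_unique_traits(h, units, level=level)
        for rep, h in hits_by_replicate.items()
    }
    return pd.DataFrame(cols)


def subsample_sites(G: GenotypeMatrix, n: int, seed: int) -> np.ndarray:
    """Uniform without-replacement site subsample, genome order preserved."""
    if n > G.n_sites:
        raise ValueError(f"cannot subsample {n} of {G.n_sites} sites")
    rng = np.random.default_rng(seed)
    idx = rng.choice(G.n_sites, size=n, replace=False)
    return np.sort(idx)
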