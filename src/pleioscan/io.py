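"""Readers and writers for the standard interchange formats.

Coordinate conventions at the boundary: GFF3 is 1-based inclusive, BED and
the internal interval representation are 0-based half-open, VCF positions
are 1-based.  Round-trips are lossless for the fields the pipeline uses.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import CovariateMatrix, GenotypeMatrix, TraitMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "read_bed",
    "write_phenotypes",
    "read_phenotypes",
    "write_covariates",
    "read_covariates",
]


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write dosages as an uncompressed VCF with GT and DS fields.

    Dosage 0/1/2 maps to genotypes 0/0, 0/1, 1/1; fractional dosages (if
    any) are rounded for GT but kept exact in DS.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(G.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(G.sites.itertuples()):
            d = G.dosages[:, j]
            cells = [
                f"{gt_codes[int(round(x))]}:{x:g}" for x in d
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | os.PathLike, dialect: str = "GT") -> GenotypeMatrix:
    """Read a VCF into a dosage matrix via cyvcf2.

    dialect="GT" counts alternate alleles from genotypes; "DS" reads the
    dosage FORMAT field directly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, recs = [], []
    for var in vcf:
        if dialect == "DS":
            d = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            # cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
            gt = var.gt_types.astype(float)
            d = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows.append(d)
        recs.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
    sites = pd.DataFrame(recs, columns=["site_id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.asarray(rows).T, sites, samples)


def write_gff3(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene ranges (0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\tpleioscan\tgene\t{row.start + 1}\t{row.end}\t.\t{strand}\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene features from GFF3 into 0-based half-open ranges."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    recs = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        recs.append((feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand or "+"))
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_bed(ranges: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write 0-based half-open ranges as BED (chrom, start, end[, name])."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in ranges.columns else [])
    ranges[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_phenotypes(T: TraitMatrix, values_path, meta_path) -> None:
    """Samples x traits CSV (header row = trait IDs) plus a trait-metadata CSV."""
    T.values.to_csv(values_path, index_label="sample")
    pd.DataFrame(
        {"trait": T.traits, "category": T.categories.loc[T.traits].to_numpy(),
         "trait_type": T.trait_types.loc[T.traits].to_numpy()}
    ).to_csv(meta_path, index=False)


def read_phenotypes(values_path, meta_path) -> TraitMatrix:
    values = pd.read_csv(values_path, index_col="sample")
    values.index.name = None
    meta = pd.read_csv(meta_path).set_index("trait")
    cats = meta["category"]
    cats.index.name = None
    return TraitMatrix(values, cats, meta["trait_type"].rename_axis(None))


def write_covariates(C: CovariateMatrix, path) -> None:
    """CSV with a provenance header block (# label=tag lines) then the matrix."""
    with open(path, "w") as fh:
        for label in C.labels:
            fh.write(f"# {label}={C.provenance[label]}\n")
        C.values.to_csv(fh, index_label="sample")


def read_covariates(path) -> CovariateMatrix:
    prov = {}
    with open(path) as fh:
        body_start = 0
        for line in fh:
            if line.startswith("# ") and "=" in line:
                label, tag = line[2:].strip().split("=", 1)
                prov[label] = tag
                body_start += len(line)
            else:
                break
    with open(path) as fh:
        fh.seek(body_start)
        values = pd.read_csv(fh, index_col="sample")
    return CovariateMatrix(values, pd.Series(prov))
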