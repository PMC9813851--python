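"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (GT field, ``./.`` for missing; read back
through cyvcf2) or as a tab-separated dosage matrix (samples x SNPs, header
row of SNP ids). Region tables (gene maps, candidate regions) are BED-like
TSVs written 1-based inclusive — a deliberate deviation from half-open BED,
declared in a header comment on every file.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import Genome
from .types import GenotypeMatrix, TraitCatalog

_REGION_HEADER = "# coordinates: 1-based inclusive (chr, start, end[, name])\n"


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike,
              genome: Genome | None = None) -> None:
    """Write genotypes as uncompressed VCF v4.2 with GT calls.

    A1 (the counted allele) is emitted as ALT and A2 as REF, so the ALT
    allele count equals the stored dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vascgwas\n")
        if genome is not None:
            for name, length in genome.chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(G.snps["chr"].astype(str)):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(G.snps.itertuples()):
            calls = [gt.get(d, "./.") if np.isfinite(d) else "./."
                     for d in G.dosages[:, j]]
            fh.write(f"{snp.chr}\t{snp.bp}\t{snp.id}\t{snp.a2}\t{snp.a1}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT = A1 counted allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append((str(var.CHROM), int(var.POS), alt, str(var.REF)))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        dosage_cols.append(col)
    vcf.close()
    snps = pd.DataFrame(rows, columns=["chr", "bp", "a1", "a2"])
    snps.insert(0, "id", snps["chr"] + ":" + snps["bp"].astype(str))
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((len(sample_ids), 0)))
    snps["freq"] = (np.nanmean(dosages, axis=0) / 2.0 if dosage_cols else [])
    return GenotypeMatrix(sample_ids, snps, dosages)


def write_dosage_tsv(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """samples x SNPs dosage matrix; header row of SNP ids, NA for missing."""
    df = pd.DataFrame(G.dosages, columns=G.snps["id"])
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_snp_meta(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    G.snps.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | os.PathLike,
                    snp_meta: str | os.PathLike | None = None) -> GenotypeMatrix:
    """Read a dosage TSV (optionally with a sidecar SNP metadata TSV)."""
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].astype(str).tolist()
    dosages = df.drop(columns="sample_id").to_numpy(dtype=float)
    if snp_meta is not None:
        snps = pd.read_csv(snp_meta, sep="\t",
                           dtype={"chr": str, "a1": str, "a2": str})
    else:
        ids = [c for c in df.columns if c != "sample_id"]
        chrs, bps = zip(*(i.split(":") for i in ids))
        snps = pd.DataFrame({"id": ids, "chr": chrs,
                             "bp": [int(b) for b in bps],
                             "a1": "A", "a2": "B",
                             "freq": np.nanmean(dosages, axis=0) / 2.0})
    return GenotypeMatrix(sample_ids, snps, dosages)


def write_samples(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str})


def write_regions(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_REGION_HEADER)
        regions.to_csv(fh, sep="\t", index=False)


def read_regions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chr": str})


def write_catalog(catalog: TraitCatalog, path: str | os.PathLike) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path: str | os.PathLike) -> TraitCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return TraitCatalog.from_frame(df)


def write_grm(grm, path: str | os.PathLike) -> None:
    """Lower-triangle text GRM: id1, id2, n_snps, value."""
    grm.to_frame().to_csv(path, sep="\t", index=False)
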