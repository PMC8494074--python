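"""Readers and writers for PLINK bed/bim/fam, VCF, gene regions, and TSVs.

PLINK binary genotypes use the standard variant-major 2-bit encoding
(magic bytes 0x6c 0x1b, mode 0x01).  Within each variant's byte block the
two-bit codes are, per sample in little-endian bit order: 00 homozygous A1,
10 heterozygous, 11 homozygous A2, 01 missing — so with A1 the counted
(minor) allele the dosage map is {00: 2, 10: 1, 11: 0, 01: missing}.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .qc import MISSING, GeneRegion, GenotypeMatrix

__all__ = [
    "write_plink", "read_plink", "read_vcf",
    "read_gene_regions", "write_gene_regions_bed",
    "write_phenotype", "read_phenotype",
    "write_covariates", "read_covariates",
    "pedigree_to_fam", "fam_to_pedigree",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage value (index -1..2 via +1 offset) -> 2-bit code
_DOSAGE_TO_CODE = np.array([1, 3, 2, 0], dtype=np.uint8)   # [missing, 0, 1, 2]
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def pedigree_to_fam(ped: pd.DataFrame) -> pd.DataFrame:
    sex_code = ped["sex"].map({"male": 1, "female": 2}).fillna(0).astype(int)
    return pd.DataFrame({
        "fid": ped["family"],
        "iid": ped["iid"],
        "father": ped["father"].map(lambda v: "0" if v is None else str(v)),
        "mother": ped["mother"].map(lambda v: "0" if v is None else str(v)),
        "sex": sex_code,
        "phenotype": -9,
    })


def fam_to_pedigree(fam: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "family": fam["fid"].astype(str),
        "iid": fam["iid"].astype(str),
        "father": fam["father"].map(lambda v: None if str(v) == "0" else str(v)),
        "mother": fam["mother"].map(lambda v: None if str(v) == "0" else str(v)),
        "sex": fam["sex"].map({1: "male", 2: "female"}),
    })


def write_plink(G: GenotypeMatrix, ped: pd.DataFrame, prefix: str) -> None:
    """Write <prefix>.bed/.bim/.fam (bed in variant-major mode)."""
    fam = pedigree_to_fam(ped)
    if not np.array_equal(fam["iid"].to_numpy(dtype=object), G.sample_ids):
        raise ValueError("pedigree order does not match genotype sample order")
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    bim = pd.DataFrame({
        "chrom": G.snp_meta["chrom"],
        "id": G.snp_meta["id"],
        "cm": 0,
        "pos": G.snp_meta["pos"],
        "a1": G.snp_meta["a1"],
        "a2": G.snp_meta["a2"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    n = G.n_samples
    n_pad = (4 - n % 4) % 4
    codes = _DOSAGE_TO_CODE[G.dosage.T.astype(np.int16) + 1]    # (m, n)
    if n_pad:
        codes = np.concatenate(
            [codes, np.zeros((codes.shape[0], n_pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(codes.shape[0], -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str):
    """Read <prefix>.bed/.bim/.fam; returns (GenotypeMatrix, fam DataFrame)."""
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex",
                             "phenotype"], dtype=str)
    fam["sex"] = fam["sex"].astype(int)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError("not a variant-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * n_bytes:
        raise ValueError("bed file size does not match bim/fam dimensions")
    raw = raw.reshape(m, n_bytes)
    codes = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)],
                     axis=2).reshape(m, -1)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T.copy()
    meta = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    G = GenotypeMatrix(dosage, meta, fam["iid"].to_numpy(dtype=object))
    return G, fam


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs (GT field) from a VCF into a GenotypeMatrix.

    Dosages count the ALT allele; multi-allelic and non-SNP records are
    skipped.  Run SNP QC afterwards to recode to the minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.asarray(vcf.samples, dtype=object)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gt = np.asarray(var.gt_types)
        dos = np.full(gt.shape, MISSING, dtype=np.int8)
        dos[gt == 0] = 0     # hom ref
        dos[gt == 1] = 1     # het
        dos[gt == 3] = 2     # hom alt
        rows.append(dos)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     var.POS, var.ALT[0], var.REF))
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    dosage = np.stack(rows, axis=1)
    snp_meta = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    return GenotypeMatrix(dosage, snp_meta, samples)


def read_gene_regions(path: str):
    """Gene regions from BED4 (0-based half-open) or a headered TSV.

    TSV columns chrom/start/end/gene are interpreted with 1-based inclusive
    coordinates and converted to the internal 0-based half-open convention.
    """
    is_bed = os.path.splitext(path)[1].lower() == ".bed"
    if is_bed:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene"],
                         dtype={"chrom": str, "gene": str})
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
    else:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        for col in ("chrom", "start", "end", "gene"):
            if col not in df.columns:
                raise ValueError(f"gene TSV missing column '{col}'")
        starts = df["start"].astype(int) - 1
        ends = df["end"].astype(int)
    return [GeneRegion(str(g), str(c), int(s), int(e))
            for g, c, s, e in zip(df["gene"], df["chrom"], starts, ends)]


def write_gene_regions_bed(regions, path: str) -> None:
    pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "gene": [r.gene_id for r in regions],
    }).to_csv(path, sep="\t", header=False, index=False)


def write_phenotype(Y, sample_ids, path: str, name: str = "phenotype") -> None:
    pd.DataFrame({"iid": sample_ids, name: Y}).to_csv(path, sep="\t",
                                                      index=False)


def read_phenotype(path: str, column=None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    col = column if column is not None else df.columns[0]
    return df[col].astype(float)


def write_covariates(cov: pd.DataFrame, path: str) -> None:
    cov.rename_axis("iid").reset_index().to_csv(path, sep="\t", index=False)


def read_covariates(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.set_index(df.columns[0]).astype(float)
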