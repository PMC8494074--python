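"""Synthetic family-GWAS data with LD, pedigree structure, and a polygenic trait.

The generator emulates the statistical structure a gene-based association
analysis of a quantitative dental-caries-like index assumes: ~650 individuals
in ~200 nuclear families/trios plus unrelated singletons, biallelic SNPs laid
out in gene blocks with within-block LD, eight non-genetic covariates, and a
trait Y = Z beta + g + a + e where `a` is an additive polygenic effect with
covariance sigma_a^2 * 2*Phi and `e` is i.i.d. noise.

LD model: within each gene, founder haplotypes are drawn from a thresholded
one-factor latent Gaussian.  All SNPs of a gene share one minor-allele
frequency, and the latent factor loading is calibrated (through Owen's T for
the equal-threshold bivariate normal orthant) so the *allelic* correlation of
haplotypes within the block equals ``ld_block_rho`` exactly.  Offspring
inherit whole-block haplotypes (no recombination within a gene, free
recombination between genes), which preserves both LD and Mendelian
transmission.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

from .qc import GenotypeMatrix, GeneRegion, KinshipMatrix, pedigree_kinship

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_pedigree",
    "make_gene_regions",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_study",
    "design_matrix",
    "DESIGN_COLUMNS",
]

# Trait model defaults: total residual variance 33.211 split as narrow-sense
# heritability 0.4437, matching heritability estimates for the permanent-
# dentition DMFT index in family-based caries studies.
TOTAL_VARIANCE = 33.211
HERITABILITY = 0.4437

# Fixed-effect defaults (trait units per covariate unit) for the ten-column
# design: intercept, female sex, age (years), water-source indicators,
# tooth-brushing frequency code, saliva flow (ml/min), home water fluoride
# (ppm), education level code, oral S. mutans presence.
DEFAULT_EFFECTS = {
    "intercept": -1.365,
    "sex_female": 0.930,
    "age": 0.225,
    "water_well": 0.185,
    "water_other": 1.669,
    "brush_freq": 0.674,
    "saliva_flow": -0.180,
    "fluoride": 0.714,
    "education": -0.612,
    "s_mutans": 2.134,
}
DESIGN_COLUMNS = list(DEFAULT_EFFECTS)

# Marginal covariate distributions for a caries-study-like sample of 652:
# 281/652 male, age 25.4 +/- 13.3 y, water source 492/147/13, 74.1% S. mutans,
# fluoride 0.7 +/- 0.4 ppm, saliva flow 0.2 +/- 0.4 ml/min, education
# 452/115/85, 72.39% brushing more than once a day.
_P_FEMALE = 371 / 652
_AGE_MEAN, _AGE_SD = 25.4, 13.3
_P_WATER = (492 / 652, 147 / 652, 13 / 652)
_P_MUTANS = 0.741
_FLUO_MEAN, _FLUO_SD = 0.7, 0.4
_SALIVA_MEAN, _SALIVA_SD = 0.2, 0.4
_P_EDU = (452 / 652, 115 / 652, 85 / 652)
# brush codes 2..5 (3x/day .. <1x/day); codes 2-3 are "more than once a day"
_BRUSH_CODES = (2, 3, 4, 5)
_P_BRUSH = (0.35, 0.3739, 0.22, 0.0561)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``offspring_per_family`` may be an int (same for every family), a sequence
    (one count per family), or None for the default mix of 169 trios and 32
    childless founder couples per 201 families, which yields the canonical
    652-sample structure (571 family members + 81 singletons).
    """

    n_families: int = 201
    offspring_per_family: Union[int, Sequence[int], None] = None
    n_unrelated: int = 81
    n_genes: int = 200
    snps_per_gene: Union[int, tuple] = (1, 15)   # inclusive uniform range
    maf_range: tuple = (0.01, 0.5)
    ld_block_rho: float = 0.5
    sigma_a2: float = HERITABILITY * TOTAL_VARIANCE
    sigma_e2: float = (1.0 - HERITABILITY) * TOTAL_VARIANCE
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    causal_gene_fraction: float = 0.0
    causal_effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ValueError("counts must be non-negative")
        if self.n_families == 0 and self.n_unrelated == 0:
            raise ValueError("empty study: no families and no unrelated samples")
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("need sigma_a2 >= 0 and sigma_e2 > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.ld_block_rho < 1):
            raise ValueError("ld_block_rho must be in [0, 1)")
        if not (0 <= self.causal_gene_fraction <= 1):
            raise ValueError("causal_gene_fraction must be in [0, 1]")

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class SimulatedStudy:
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    covariates: pd.DataFrame
    gene_regions: list
    kinship: KinshipMatrix
    truth: dict


def _rng(config: SimConfig, op: str) -> np.random.Generator:
    """Per-operation substream of the study's single seed."""
    key = zlib.crc32(op.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# pedigree


def _offspring_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.offspring_per_family
    nf = config.n_families
    if spec is None:
        # deterministic default: ~32/201 childless couples, rest trios
        n_zero = int(round(nf * 32 / 201))
        counts = np.ones(nf, dtype=int)
        counts[:n_zero] = 0
        return counts
    if np.isscalar(spec):
        return np.full(nf, int(spec), dtype=int)
    counts = np.asarray(list(spec), dtype=int)
    if len(counts) != nf:
        raise ValueError("offspring_per_family sequence must have n_families entries")
    return counts


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Nuclear families (two founders + offspring) plus unrelated singletons.

    Deterministic given the config seed.  Returns a table with columns
    family, iid, father, mother, sex; founders have missing (None) parents.
    """
    rng = _rng(config, "pedigree")
    counts = _offspring_counts(config, rng)
    rows = []
    for f in range(config.n_families):
        fam = f"F{f + 1:04d}"
        dad, mom = f"{fam}_1", f"{fam}_2"
        rows.append((fam, dad, None, None, "male"))
        rows.append((fam, mom, None, None, "female"))
        for k in range(counts[f]):
            sex = "male" if rng.random() < 0.5 else "female"
            rows.append((fam, f"{fam}_{k + 3}", dad, mom, sex))
    for u in range(config.n_unrelated):
        fam = f"U{u + 1:04d}"
        sex = "male" if rng.random() < 0.5 else "female"
        rows.append((fam, f"{fam}_1", None, None, sex))
    return pd.DataFrame(rows, columns=["family", "iid", "father", "mother", "sex"])


# ---------------------------------------------------------------------------
# genotypes


def _resolve_snps_per_gene(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.snps_per_gene
    if np.isscalar(spec):
        return np.full(config.n_genes, int(spec), dtype=int)
    lo, hi = spec
    return rng.integers(int(lo), int(hi) + 1, size=config.n_genes)


def make_gene_regions(config: SimConfig):
    """Gene regions, SNP metadata, and per-gene MAFs for the configured layout.

    Genes are assigned to chromosomes 1..22 round-robin; SNPs are placed 1 kb
    apart inside each gene with a 10 kb gap between consecutive genes on the
    same chromosome.  One MAF per gene is drawn uniformly from ``maf_range``.
    Returns ``(regions, snp_meta, gene_maf)``.
    """
    rng = _rng(config, "regions")
    m_per_gene = _resolve_snps_per_gene(config, rng)
    gene_maf = rng.uniform(config.maf_range[0], config.maf_range[1],
                           size=config.n_genes)
    regions = []
    meta_rows = []
    next_pos0 = {}  # chrom -> next free 0-based position
    for g in range(config.n_genes):
        chrom = str(g % 22 + 1)
        start = next_pos0.get(chrom, 1000)
        m = int(m_per_gene[g])
        end = start + m * 1000
        gene_id = f"gene{g + 1:05d}"
        regions.append(GeneRegion(gene_id, chrom, start, end))
        for j in range(m):
            pos0 = start + j * 1000
            meta_rows.append((f"{gene_id}_snp{j + 1}", chrom, pos0 + 1, "A", "G", gene_id))
        next_pos0[chrom] = end + 10_000
    snp_meta = pd.DataFrame(meta_rows,
                            columns=["id", "chrom", "pos", "a1", "a2", "gene"])
    return regions, snp_meta, gene_maf


def _latent_rho(target_rho: float, maf: float) -> float:
    """Latent Gaussian correlation giving allelic correlation ``target_rho``.

    Solves P(Z1<t, Z2<t; rho*) = p^2 + target_rho * p(1-p), t = Phi^-1(p),
    using the equal-threshold orthant identity
    Phi2(t,t;rho) = Phi(t) - 2*T(t, sqrt((1-rho)/(1+rho))).
    """
    if target_rho <= 0:
        return 0.0
    p = maf
    t = norm.ppf(p)
    want = p * p + target_rho * p * (1.0 - p)

    def f(rho):
        return norm.cdf(t) - 2.0 * owens_t(t, np.sqrt((1.0 - rho) / (1.0 + rho))) - want

    return brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-10)


def simulate_genotypes(ped: pd.DataFrame, config: SimConfig,
                       return_annotation: bool = False):
    """LD-structured founder haplotypes plus Mendelian transmission.

    Founder haplotypes are thresholded one-factor Gaussians per gene block
    (see module docstring); each offspring inherits one whole-block haplotype
    from each parent, drawn independently across blocks.  Dosages count the
    minor allele.  With ``return_annotation=True`` also returns the gene
    region list.
    """
    from .qc import validate_pedigree, _topological_order

    ped = validate_pedigree(ped)
    rng = _rng(config, "genotypes")
    regions, snp_meta, gene_maf = make_gene_regions(config)
    n = len(ped)
    order = _topological_order(ped)
    idx = {iid: i for i, iid in enumerate(ped["iid"])}
    fathers, mothers = ped["father"].tolist(), ped["mother"].tolist()
    founder_mask = np.array([f is None for f in fathers])
    n_founders = int(founder_mask.sum())
    founder_row = {i: k for k, i in enumerate(np.flatnonzero(founder_mask))}

    n_snps = len(snp_meta)
    haps = np.zeros((n, 2, n_snps), dtype=np.int8)
    gene_slices = []
    col = 0
    for g, reg in enumerate(regions):
        m = (reg.end - reg.start) // 1000
        gene_slices.append(slice(col, col + m))
        col += m

    # founder haplotypes, block by block
    for g, sl in enumerate(gene_slices):
        m = sl.stop - sl.start
        p = gene_maf[g]
        t = norm.ppf(p)
        rho_lat = _latent_rho(config.ld_block_rho, p)
        u = rng.standard_normal((n_founders, 2, 1))
        eps = rng.standard_normal((n_founders, 2, m))
        z = np.sqrt(rho_lat) * u + np.sqrt(1.0 - rho_lat) * eps
        haps[founder_mask, :, sl] = (z < t).astype(np.int8)

    # transmission: one whole-block haplotype from each parent per offspring
    n_genes = len(gene_slices)
    for i in order:
        if fathers[i] is None:
            continue
        fi, mi = idx[fathers[i]], idx[mothers[i]]
        pick_f = rng.integers(0, 2, size=n_genes)
        pick_m = rng.integers(0, 2, size=n_genes)
        for g, sl in enumerate(gene_slices):
            haps[i, 0, sl] = haps[fi, pick_f[g], sl]
            haps[i, 1, sl] = haps[mi, pick_m[g], sl]

    dosage = haps.sum(axis=1, dtype=np.int8)
    G = GenotypeMatrix(dosage, snp_meta, ped["iid"].to_numpy(dtype=object))
    if return_annotation:
        return G, regions
    return G


# ---------------------------------------------------------------------------
# covariates and design


def simulate_covariates(ped: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Eight non-genetic covariates with caries-study-like marginals.

    Covariates are drawn independently of genotype and of pedigree structure
    (the pedigree's male/female labels only define transmission roles; the
    phenotype-model sex covariate reproduces the sample's marginal sex ratio).
    Columns are numeric and match ``DESIGN_COLUMNS`` minus the intercept.
    """
    rng = _rng(config, "covariates")
    n = len(ped)
    sex_female = (rng.random(n) < _P_FEMALE).astype(float)
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    water = rng.choice(3, size=n, p=_P_WATER)          # 0 city, 1 well, 2 other
    brush = np.asarray(_BRUSH_CODES)[rng.choice(4, size=n, p=_P_BRUSH)].astype(float)
    saliva = rng.normal(_SALIVA_MEAN, _SALIVA_SD, size=n)
    fluoride = rng.normal(_FLUO_MEAN, _FLUO_SD, size=n)
    education = rng.choice([1, 2, 3], size=n, p=_P_EDU).astype(float)
    mutans = (rng.random(n) < _P_MUTANS).astype(float)
    return pd.DataFrame({
        "sex_female": sex_female,
        "age": age,
        "water_well": (water == 1).astype(float),
        "water_other": (water == 2).astype(float),
        "brush_freq": brush,
        "saliva_flow": saliva,
        "fluoride": fluoride,
        "education": education,
        "s_mutans": mutans,
    }, index=ped["iid"].to_numpy())


def design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Fixed-effects design: intercept column prepended to the covariates."""
    X = covariates.to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(ped: pd.DataFrame, covariates: pd.DataFrame,
                       config: SimConfig, kinship: KinshipMatrix,
                       genotypes: Optional[GenotypeMatrix] = None,
                       regions: Optional[list] = None):
    """Quantitative trait Y = Z beta + g + a + e.

    ``a`` is multivariate normal with covariance sigma_a2 * (2 Phi), drawn by
    Cholesky factorization; ``e`` is i.i.d. N(0, sigma_e2).  When
    ``causal_gene_fraction > 0``, a random subset of genes receives a per-
    minor-allele effect ``causal_effect_size`` on every SNP (requires
    ``genotypes`` and ``regions``).  Returns ``(Y, truth)`` where truth holds
    the causal gene set, per-sample causal contribution, and the generating
    parameters.
    """
    n = len(ped)
    if len(covariates) != n or kinship.n != n:
        raise ValueError("pedigree, covariates, and kinship sizes differ")
    if not np.array_equal(np.asarray(kinship.ids, dtype=object),
                          ped["iid"].to_numpy(dtype=object)):
        raise ValueError("kinship rows do not match pedigree order")
    rng = _rng(config, "phenotype")
    Z = design_matrix(covariates)
    beta = np.array([config.covariate_effects[c] for c in DESIGN_COLUMNS])

    a = np.zeros(n)
    if config.sigma_a2 > 0:
        A = kinship.additive
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        a = np.sqrt(config.sigma_a2) * (L @ rng.standard_normal(n))
    e = np.sqrt(config.sigma_e2) * rng.standard_normal(n)

    causal = np.zeros(n)
    causal_genes: list = []
    snp_effects: dict = {}
    n_causal = int(round(config.causal_gene_fraction * config.n_genes))
    if n_causal > 0:
        if genotypes is None or regions is None:
            raise ValueError("causal effects require genotypes and regions")
        crng = _rng(config, "causal")
        pick = crng.choice(len(regions), size=n_causal, replace=False)
        gene_col = genotypes.snp_meta["gene"].to_numpy()
        for gi in sorted(pick):
            reg = regions[gi]
            cols = np.flatnonzero(gene_col == reg.gene_id)
            causal_genes.append(reg.gene_id)
            for j in cols:
                snp_effects[genotypes.snp_meta["id"].iloc[j]] = config.causal_effect_size
            causal = causal + config.causal_effect_size * \
                genotypes.dosage[:, cols].astype(float).sum(axis=1)

    Y = Z @ beta + causal + a + e
    truth = {
        "beta": dict(zip(DESIGN_COLUMNS, beta)),
        "sigma_a2": config.sigma_a2,
        "sigma_e2": config.sigma_e2,
        "heritability": config.heritability,
        "causal_genes": causal_genes,
        "snp_effects": snp_effects,
        "polygenic": a,
        "noise": e,
        "causal_contribution": causal,
    }
    return Y, truth


# ---------------------------------------------------------------------------
# full study


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a complete, internally consistent study from one seed."""
    ped = simulate_pedigree(config)
    kin = pedigree_kinship(ped)
    G, regions = simulate_genotypes(ped, config, return_annotation=True)
    cov = simulate_covariates(ped, config)
    Y, truth = simulate_phenotype(ped, cov, config, kin, genotypes=G,
                                  regions=regions)
    return SimulatedStudy(ped, G, Y, cov, regions, kin, truth)
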