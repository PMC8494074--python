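"""Sample/SNP quality control, pedigree kinship, and per-gene partitioning.

Genotypes are biallelic dosages of a counted allele (the minor allele after
QC), stored as int8 with ``MISSING`` (-1) marking uncalled genotypes.  QC
follows the usual family-GWAS order: samples first (completeness, empirical
self-kinship), then SNPs (call rate, MAF recomputed on the retained samples).
After QC the genotype matrix is split into per-gene submatrices; within each
gene, monomorphic and exactly duplicated columns are dropped so the gene's
sample covariance matrix is invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "KinshipMatrix",
    "GeneRegion",
    "GenePartition",
    "QCReport",
    "empirical_self_kinship",
    "filter_samples",
    "filter_snps",
    "run_qc",
    "partition_by_gene",
    "pedigree_kinship",
    "validate_pedigree",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) plus per-SNP metadata.

    Parameters
    ----------
    dosage : int8 array, shape (n_samples, n_snps)
        Counts of the counted allele in {0, 1, 2}; -1 marks missing calls.
    snp_meta : DataFrame
        One row per SNP with at least columns ``id``, ``chrom``, ``pos``
        (1-based source coordinate), ``a1`` (counted allele), ``a2``.
        Must be sorted by position within each chromosome.
    sample_ids : array of str
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"snp_meta not sorted by position on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP, over called genotypes."""
        called = self.called()
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(called, self.dosage, 0).sum(axis=0) / (2.0 * n_called)
        return np.where(n_called > 0, freq, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of samples with a called genotype."""
        return self.called().mean(axis=0)

    def completeness(self) -> np.ndarray:
        """Per-sample fraction of SNPs with a called genotype."""
        return self.called().mean(axis=1)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[keep], self.snp_meta.copy(),
                              self.sample_ids[keep])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[:, keep],
                              self.snp_meta.loc[np.asarray(keep)].copy(),
                              self.sample_ids)


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients phi for a set of samples.

    ``additive`` (= 2*phi) is the additive genetic relationship matrix that
    scales the polygenic variance component in the trait covariance.
    """

    ids: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square and match ids")
        if not np.allclose(self.phi, self.phi.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def additive(self) -> np.ndarray:
        return 2.0 * self.phi

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep: np.ndarray) -> "KinshipMatrix":
        keep = np.asarray(keep)
        return KinshipMatrix(self.ids[keep], self.phi[np.ix_(keep, keep)])


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic interval, stored 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})")


@dataclass
class GenePartition:
    """Cleaned genotype submatrix for one gene (mean-imputed float dosages)."""

    region: GeneRegion
    genotypes: np.ndarray          # float64, (n_samples, m), no missing
    snp_ids: list
    dropped_monomorphic: list = field(default_factory=list)
    dropped_duplicate: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class QCReport:
    samples_removed: pd.DataFrame   # columns: sample_id, reason
    snps_removed: pd.DataFrame      # columns: snp_id, reason
    thresholds: dict

    def to_log(self) -> str:
        lines = [f"thresholds: {self.thresholds}"]
        lines.append(f"samples removed: {len(self.samples_removed)}")
        for _, r in self.samples_removed.iterrows():
            lines.append(f"  {r['sample_id']}\t{r['reason']}")
        lines.append(f"snps removed: {len(self.snps_removed)}")
        for _, r in self.snps_removed.iterrows():
            lines.append(f"  {r['snp_id']}\t{r['reason']}")
        return "\n".join(lines)

    @staticmethod
    def merge(a: "QCReport", b: "QCReport") -> "QCReport":
        return QCReport(
            pd.concat([a.samples_removed, b.samples_removed], ignore_index=True),
            pd.concat([a.snps_removed, b.snps_removed], ignore_index=True),
            {**a.thresholds, **b.thresholds},
        )


def _empty_removed(col: str) -> pd.DataFrame:
    return pd.DataFrame({col: pd.Series(dtype=object),
                         "reason": pd.Series(dtype=object)})


# ---------------------------------------------------------------------------
# sample QC


def empirical_self_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Empirical self-kinship (1 + h_i)/2 from frequency-standardized dosages.

    h_i is the genomic inbreeding estimate averaged over informative SNPs,

        h_i = mean_j [ g_ij^2 - (1 + 2 p_j) g_ij + 2 p_j^2 ] / (2 p_j (1 - p_j)),

    with p_j the sample allele frequency of the counted allele.  Under
    Hardy-Weinberg draws each term has mean 0, so an outbred sample tends to
    self-kinship 0.5; a fully inbred (all-homozygous) sample tends to 1.
    Monomorphic SNPs carry no information and are excluded from the average.
    """
    p = G.allele_freq()
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    if not informative.any():
        raise ValueError("no informative (polymorphic) SNPs for self-kinship")
    p = p[informative]
    g = G.dosage[:, informative].astype(float)
    called = g != MISSING
    num = g * g - (1.0 + 2.0 * p) * g + 2.0 * p * p
    den = 2.0 * p * (1.0 - p)
    term = np.where(called, num / den, 0.0)
    n_used = called.sum(axis=1)
    if (n_used == 0).any():
        bad = G.sample_ids[n_used == 0]
        raise ValueError(f"samples with no called informative genotypes: {list(bad)}")
    h = term.sum(axis=1) / n_used
    return (1.0 + h) / 2.0


def filter_samples(G: GenotypeMatrix, completeness_min: float = 0.96,
                   self_kinship_max: float = 0.525):
    """Remove samples with completeness below threshold or excess self-kinship.

    A sample is retained iff completeness >= ``completeness_min`` and empirical
    self-kinship <= ``self_kinship_max`` (exclusion is strict on both sides of
    the stated boundaries: exactly 96% complete or exactly 0.525 is kept).
    """
    if not (0 < completeness_min <= 1):
        raise ValueError("completeness_min must be in (0, 1]")
    if not (0.5 <= self_kinship_max <= 1):
        raise ValueError("self_kinship_max must be in [0.5, 1]")
    comp = G.completeness()
    phi_self = empirical_self_kinship(G)
    low_comp = comp < completeness_min
    inbred = phi_self > self_kinship_max
    drop = low_comp | inbred
    if drop.all():
        raise ValueError("sample QC removed every sample")
    reasons = []
    for i in np.flatnonzero(drop):
        r = []
        if low_comp[i]:
            r.append("low_completeness")
        if inbred[i]:
            r.append("high_self_kinship")
        reasons.append((G.sample_ids[i], ";".join(r)))
    report = QCReport(
        pd.DataFrame(reasons, columns=["sample_id", "reason"])
        if reasons else _empty_removed("sample_id"),
        _empty_removed("snp_id"),
        {"completeness_min": completeness_min, "self_kinship_max": self_kinship_max},
    )
    return G.subset_samples(~drop), report


def filter_snps(G: GenotypeMatrix, call_rate_min: float = 0.96,
                maf_min: float = 0.01):
    """Remove SNPs with call rate or MAF below threshold; recode to minor allele.

    MAF is computed on the samples present in ``G`` (i.e. after sample QC).
    Retained SNPs whose counted-allele frequency exceeds 0.5 are flipped
    (dosage -> 2 - dosage, allele labels swapped) so dosages count the minor
    allele.  Boundary values (exactly the threshold) are retained.
    """
    if not (0 < call_rate_min <= 1) or not (0 < maf_min <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    cr = G.call_rate()
    maf = G.maf()
    low_cr = cr < call_rate_min
    low_maf = ~(maf >= maf_min)          # NaN maf (all-missing) fails too
    drop = low_cr | low_maf
    if drop.all():
        raise ValueError("SNP QC removed every SNP")
    reasons = []
    for j in np.flatnonzero(drop):
        r = []
        if low_cr[j]:
            r.append("low_call_rate")
        if low_maf[j]:
            r.append("low_maf")
        reasons.append((G.snp_meta["id"].iloc[j], ";".join(r)))
    kept = G.subset_snps(~drop)

    # recode so the counted allele is the minor one
    p = kept.allele_freq()
    flip = p > 0.5
    if flip.any():
        dos = kept.dosage.copy()
        cols = np.flatnonzero(flip)
        block = dos[:, cols]
        miss = block == MISSING
        block = 2 - block
        block[miss] = MISSING
        dos[:, cols] = block
        meta = kept.snp_meta.copy()
        a1 = meta["a1"].to_numpy().copy()
        a2 = meta["a2"].to_numpy().copy()
        a1[cols], a2[cols] = a2[cols], a1[cols].copy()
        meta["a1"], meta["a2"] = a1, a2
        kept = GenotypeMatrix(dos, meta, kept.sample_ids)

    report = QCReport(
        _empty_removed("sample_id"),
        pd.DataFrame(reasons, columns=["snp_id", "reason"])
        if reasons else _empty_removed("snp_id"),
        {"call_rate_min": call_rate_min, "maf_min": maf_min},
    )
    return kept, report


def run_qc(G: GenotypeMatrix, completeness_min: float = 0.96,
           self_kinship_max: float = 0.525, call_rate_min: float = 0.96,
           maf_min: float = 0.01):
    """Sample QC followed by SNP QC; returns the cleaned matrix and a report."""
    G1, rep_s = filter_samples(G, completeness_min, self_kinship_max)
    G2, rep_v = filter_snps(G1, call_rate_min, maf_min)
    return G2, QCReport.merge(rep_s, rep_v)


# ---------------------------------------------------------------------------
# gene partitioning


def _impute_columns(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per column (float output)."""
    X = dosage.astype(float)
    miss = dosage == MISSING
    if miss.any():
        X[miss] = np.nan
        means = np.nanmean(X, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        idx = np.where(miss)
        X[idx] = means[idx[1]]
    return X


def partition_by_gene(G: GenotypeMatrix, regions) -> list:
    """Split the genotype matrix into cleaned per-gene submatrices.

    A SNP belongs to a gene iff its 0-based position (source ``pos`` - 1)
    falls in the gene's half-open interval; SNPs in overlapping genes are
    assigned to every such gene.  Within each gene, missing dosages are
    mean-imputed, then constant (monomorphic) columns are dropped, then exact
    duplicate columns are dropped keeping the first in position order.  Genes
    left with no SNPs are omitted (and logged).
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no gene regions supplied")
    pos0 = G.snp_meta["pos"].to_numpy() - 1
    chrom = G.snp_meta["chrom"].to_numpy().astype(str)
    ids = G.snp_meta["id"].to_numpy()
    out = []
    for reg in regions:
        sel = np.flatnonzero((chrom == str(reg.chrom))
                             & (pos0 >= reg.start) & (pos0 < reg.end))
        if sel.size == 0:
            logger.info("gene %s: no SNPs in region, omitted", reg.gene_id)
            continue
        X = _impute_columns(G.dosage[:, sel])
        snp_ids = list(ids[sel])

        poly = X.std(axis=0) > 0
        dropped_mono = [s for s, ok in zip(snp_ids, poly) if not ok]
        X = X[:, poly]
        snp_ids = [s for s, ok in zip(snp_ids, poly) if ok]

        seen: dict = {}
        keep_idx, dropped_dup = [], []
        for j, s in enumerate(snp_ids):
            key = X[:, j].tobytes()
            if key in seen:
                dropped_dup.append(s)
            else:
                seen[key] = j
                keep_idx.append(j)
        X = X[:, keep_idx]
        snp_ids = [snp_ids[j] for j in keep_idx]

        if X.shape[1] == 0:
            logger.info("gene %s: no polymorphic unique SNPs, omitted", reg.gene_id)
            continue
        out.append(GenePartition(reg, X, snp_ids, dropped_mono, dropped_dup))
    return out


# ---------------------------------------------------------------------------
# pedigree kinship


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check ids, parent references, and acyclicity; return a normalized copy.

    Founders have both parents missing (None/NaN/"0"); anyone with exactly one
    named parent, a parent absent from the table, or an ancestry cycle raises.
    """
    ped = ped.copy().reset_index(drop=True)
    req = {"family", "iid", "father", "mother"}
    if not req.issubset(ped.columns):
        raise ValueError(f"pedigree needs columns {sorted(req)}")

    def norm(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("0", ""):
            return None
        return str(v)

    ped["iid"] = ped["iid"].astype(str)
    if ped["iid"].duplicated().any():
        raise ValueError("duplicate individual ids in pedigree")
    ped["father"] = ped["father"].map(norm)
    ped["mother"] = ped["mother"].map(norm)
    known = set(ped["iid"])
    for _, row in ped.iterrows():
        f, m = row["father"], row["mother"]
        if (f is None) != (m is None):
            raise ValueError(f"individual {row['iid']} has exactly one named parent")
        for par in (f, m):
            if par is not None and par not in known:
                raise ValueError(f"parent {par} of {row['iid']} not in pedigree")
    # cycle check via Kahn's algorithm on parent -> child edges
    _topological_order(ped)
    return ped


def _topological_order(ped: pd.DataFrame) -> list:
    idx = {iid: i for i, iid in enumerate(ped["iid"])}
    children: dict = {i: [] for i in range(len(ped))}
    indeg = np.zeros(len(ped), dtype=int)
    for i, row in ped.iterrows():
        for par in (row["father"], row["mother"]):
            if par is not None:
                children[idx[par]].append(i)
                indeg[i] += 1
    order = list(np.flatnonzero(indeg == 0))
    head = 0
    while head < len(order):
        u = order[head]
        head += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                order.append(v)
    if len(order) != len(ped):
        raise ValueError("pedigree contains a cycle (individual is its own ancestor)")
    return order


def pedigree_kinship(ped: pd.DataFrame) -> KinshipMatrix:
    """Kinship matrix by the recursive tabular method.

    Founders: phi_ii = 0.5 and 0 with all previously placed individuals.
    Non-founder i with parents f, m:
    phi_ij = (phi_fj + phi_mj)/2 for any j placed before i, and
    phi_ii = 0.5 + 0.5 * phi_fm.
    """
    ped = validate_pedigree(ped)
    order = _topological_order(ped)
    n = len(ped)
    idx = {iid: i for i, iid in enumerate(ped["iid"])}
    phi = np.zeros((n, n))
    done: list = []
    fathers = ped["father"].tolist()
    mothers = ped["mother"].tolist()
    for i in order:
        f, m = fathers[i], mothers[i]
        if f is None:
            phi[i, i] = 0.5
        else:
            fi, mi = idx[f], idx[m]
            if done:
                d = np.array(done)
                vals = 0.5 * (phi[fi, d] + phi[mi, d])
                phi[i, d] = vals
                phi[d, i] = vals
            phi[i, i] = 0.5 + 0.5 * phi[fi, mi]
        done.append(i)
    return KinshipMatrix(ped["iid"].to_numpy(dtype=object), phi)
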