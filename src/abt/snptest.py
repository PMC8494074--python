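"""Single-SNP retrospective score test and per-gene Bonferroni calls.

The statistic is the single-SNP specialization of the gene-based quadratic
form: for a dosage vector g with sample variance s_g^2,

    T = (g'V)^2 / (s_g^2 * V'AV),

referred to chi^2_1 (MASTOR-style: score numerator (g'V)^2, retrospective
variance from the genotype dispersion and V'AV).  A gene is called
significant by the SNP-based analysis when at least one of its m tested SNPs
has p-value below the within-gene Bonferroni threshold alpha / m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = ["SnpTestResult", "GeneCall", "snp_score_test", "test_all_snps",
           "gene_calls", "snp_results_to_frame", "calls_to_frame"]


@dataclass
class SnpTestResult:
    snp_id: str
    gene_id: str
    stat: float
    p_value: float


@dataclass
class GeneCall:
    gene_id: str
    m: int
    min_p: float
    threshold: float
    significant: bool


def snp_score_test(g, fit, kin=None, snp_id: str = "snp",
                   gene_id: str = "gene") -> SnpTestResult:
    """Retrospective score test of one SNP against the fitted null model."""
    g = np.asarray(g, dtype=float).ravel()
    V = fit.V
    if len(g) != len(V):
        raise ValueError("dosage length does not match fitted samples")
    if np.isnan(g).any():               # mean-impute any residual missingness
        g = np.where(np.isnan(g), np.nanmean(g), g)
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0:
        raise ValueError(f"SNP {snp_id} is constant (monomorphic)")
    A = fit.model.A if kin is None else (
        2.0 * kin.phi if fit.model.relatedness == "2phi" else kin.phi)
    vav = float(V @ (A @ V))
    if vav <= 0:
        raise ValueError("V'AV <= 0: degenerate transformed residual")
    stat = float(g @ V) ** 2 / (var_g * vav)
    return SnpTestResult(snp_id, gene_id, stat, float(chi2.sf(stat, 1)))


def test_all_snps(partitions, fit, kin=None) -> list:
    """Score-test every SNP of every gene partition (SNPs shared by
    overlapping genes are tested once per gene)."""
    out = []
    for part in partitions:
        for j, snp_id in enumerate(part.snp_ids):
            out.append(snp_score_test(part.genotypes[:, j], fit, kin=kin,
                                       snp_id=snp_id,
                                       gene_id=part.region.gene_id))
    return out


def gene_calls(snp_results, alpha: float = 0.05) -> list:
    """Per-gene significance under the within-gene Bonferroni rule.

    significant  <=>  min_j p_j < alpha / m, with m the number of tested SNPs
    in the gene.  Genes with zero tested SNPs are omitted (and logged).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    by_gene: dict = {}
    for r in snp_results:
        by_gene.setdefault(r.gene_id, []).append(r.p_value)
    calls = []
    for gene_id, ps in by_gene.items():
        if not ps:
            logger.info("gene %s has no tested SNPs, omitted", gene_id)
            continue
        m = len(ps)
        thr = alpha / m
        mp = float(min(ps))
        calls.append(GeneCall(gene_id, m, mp, thr, mp < thr))
    return calls


def snp_results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": [r.snp_id for r in results],
        "gene": [r.gene_id for r in results],
        "stat": [r.stat for r in results],
        "p_value": [r.p_value for r in results],
    })


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [c.gene_id for c in calls],
        "n_snp": [c.m for c in calls],
        "min_p": [c.min_p for c in calls],
        "threshold": [c.threshold for c in calls],
        "significant": [c.significant for c in calls],
    })
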