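"""Comparison of gene- and SNP-based results, inflation factor, and plots.

The gene sets found by the two tests are crossed in a 2x2 contingency table
(significant/non-significant by each test) and checked for independence with
a Pearson chi-square (1 df, no continuity correction by default).  The
genomic inflation factor is the GWAS-standard median-based lambda:

    lambda = median( qchisq(1 - p, 1) ) / qchisq(0.5, 1)

with qchisq(0.5, 1) ~= 0.4549364.  QQ/Manhattan plot data are always emitted
as TSV so checks can assert on numbers rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency

__all__ = ["ComparisonTable", "InflationReport", "compare_gene_sets",
           "genomic_inflation", "qq_manhattan"]

CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))


@dataclass
class ComparisonTable:
    """2x2 cross-classification of gene significance by the two tests.

    a: significant by both; b: gene-based only; c: SNP-based only; d: neither.
    ``overlap_fraction`` = a / (a + c) is the share of SNP-test genes captured
    by the gene-based test.
    """

    a: int
    b: int
    c: int
    d: int
    chi2_stat: float
    chi2_p: float
    overlap_fraction: float
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int,
                    correction: bool = False) -> "ComparisonTable":
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be non-negative")
        table = np.array([[a, b], [c, d]], dtype=float)
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            stat, p = np.nan, np.nan
        else:
            res = chi2_contingency(table, correction=correction)
            stat, p = float(res[0]), float(res[1])
        overlap = a / (a + c) if (a + c) > 0 else np.nan
        return cls(a, b, c, d, stat, p, overlap, degenerate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_significant": [self.a, self.c],
             "snp_nonsignificant": [self.b, self.d]},
            index=["gene_significant", "gene_nonsignificant"])


@dataclass
class InflationReport:
    lambda_: float
    n_pvalues: int


def compare_gene_sets(gene_results, calls, alpha: float = 0.05,
                      correction: bool = False) -> ComparisonTable:
    """Cross-classify genes by ABT significance (p < alpha) vs the SNP-based
    Bonferroni calls, over the intersection of gene ids tested by both."""
    abt_sig = {r.gene_id: (r.p_value < alpha) for r in gene_results if r.ok}
    snp_sig = {c.gene_id: c.significant for c in calls}
    common = set(abt_sig) & set(snp_sig)
    if not common:
        raise ValueError("no genes tested by both methods")
    a = b = c = d = 0
    for gid in common:
        ga, sa = abt_sig[gid], snp_sig[gid]
        if ga and sa:
            a += 1
        elif ga:
            b += 1
        elif sa:
            c += 1
        else:
            d += 1
    return ComparisonTable.from_counts(a, b, c, d, correction=correction)


def genomic_inflation(p_values) -> InflationReport:
    """Median-based genomic inflation factor of a set of p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    lam = float(np.median(chi2.isf(p, 1)) / CHI2_MEDIAN_1DF)
    return InflationReport(lam, int(p.size))


_CHROM_ORDER = {str(c): c for c in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25})


def _chrom_key(c) -> float:
    return _CHROM_ORDER.get(str(c), 100)


def qq_manhattan(results_frame: pd.DataFrame, out_prefix: Optional[str] = None,
                 make_plots: bool = True):
    """Manhattan and QQ data (and optionally PNG plots) for gene p-values.

    ``results_frame`` needs columns gene, chrom, start, p_value.  Returns
    ``(manhattan_df, qq_df, inflation)``; with ``out_prefix`` the frames are
    written as <prefix>.manhattan.tsv / <prefix>.qq.tsv and, when
    ``make_plots``, <prefix>.manhattan.png / <prefix>.qq.png.
    """
    df = results_frame.dropna(subset=["p_value"]).copy()
    if df.empty:
        raise ValueError("no p-values to plot")
    df["chrom_order"] = df["chrom"].map(_chrom_key)
    df = df.sort_values(["chrom_order", "start"]).reset_index(drop=True)
    df["genome_index"] = np.arange(1, len(df) + 1)
    df["neg_log10_p"] = -np.log10(df["p_value"])
    man = df[["gene", "chrom", "start", "genome_index", "p_value",
              "neg_log10_p"]]

    n = len(df)
    obs = np.sort(df["p_value"].to_numpy())
    expected = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame({
        "expected_p": expected,
        "observed_p": obs,
        "expected_neg_log10": -np.log10(expected),
        "observed_neg_log10": -np.log10(obs),
    })
    infl = genomic_inflation(obs) if n >= 2 else None

    if out_prefix is not None:
        man.to_csv(f"{out_prefix}.manhattan.tsv", sep="\t", index=False)
        qq.to_csv(f"{out_prefix}.qq.tsv", sep="\t", index=False)
        if make_plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(9, 3.5))
            for i, (_, grp) in enumerate(man.groupby("chrom", sort=False)):
                ax.scatter(grp["genome_index"], grp["neg_log10_p"], s=6,
                           color="C0" if i % 2 == 0 else "C1")
            ax.set_xlabel("gene (genomic order)")
            ax.set_ylabel(r"$-\log_{10}\,p$")
            ax.set_title("Gene-based association: Manhattan plot")
            fig.tight_layout()
            fig.savefig(f"{out_prefix}.manhattan.png", dpi=120)
            plt.close(fig)

            fig, ax = plt.subplots(figsize=(4.2, 4.2))
            ax.scatter(qq["expected_neg_log10"], qq["observed_neg_log10"], s=8)
            lim = max(qq["expected_neg_log10"].max(),
                      qq["observed_neg_log10"].max())
            ax.plot([0, lim], [0, lim], "k--", lw=1)
            ax.set_xlabel(r"expected $-\log_{10}\,p$")
            ax.set_ylabel(r"observed $-\log_{10}\,p$")
            title = (f"QQ plot (lambda = {infl.lambda_:.3f})"
                     if infl is not None else "QQ plot")
            ax.set_title(title)
            fig.tight_layout()
            fig.savefig(f"{out_prefix}.qq.png", dpi=120)
            plt.close(fig)

    return man, qq, infl
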