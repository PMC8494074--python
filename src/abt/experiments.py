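"""Simulation studies: null calibration and parameter recovery.

These drive the full pipeline (generator -> QC partitioning -> null model ->
gene/SNP tests) on replicated synthetic studies and summarize type-I error,
p-value uniformity, genomic inflation, heritability recovery, and fixed-
effect confidence-interval coverage.  Used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import kstest

from .genetest import test_all_genes
from .model import PolygenicModel
from .qc import partition_by_gene, pedigree_kinship
from .report import genomic_inflation
from .simulate import (SimConfig, design_matrix, simulate_covariates,
                       simulate_pedigree, simulate_phenotype, simulate_study,
                       DESIGN_COLUMNS)

__all__ = ["null_calibration", "heritability_recovery"]


def _child_seed(seed: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def null_calibration(n_replicates: int = 25, seed: int = 0,
                     config: SimConfig | None = None, alpha: float = 0.05) -> dict:
    """Gene-based test under the effect-free null across replicated studies.

    Each replicate simulates a fresh study (no causal genes), fits the null
    polygenic model, and runs the ABT on every gene.  Returns the pooled
    p-values with the empirical rejection rate at ``alpha``, a KS test
    against Uniform(0,1), and the genomic inflation factor.
    """
    base = config if config is not None else SimConfig()
    if base.causal_gene_fraction != 0:
        raise ValueError("null calibration requires causal_gene_fraction = 0")
    pvals = []
    for rep in range(n_replicates):
        study = simulate_study(replace(base, seed=_child_seed(seed, rep)))
        Z = design_matrix(study.covariates)
        fit = PolygenicModel(study.phenotype, Z, study.kinship,
                             exog_names=DESIGN_COLUMNS).fit()
        parts = partition_by_gene(study.genotypes, study.gene_regions)
        for r in test_all_genes(parts, fit):
            if r.ok:
                pvals.append(r.p_value)
    pvals = np.asarray(pvals)
    ks = kstest(pvals, "uniform")
    return {
        "p_values": pvals,
        "n_tests": int(pvals.size),
        "rejection_rate": float(np.mean(pvals < alpha)),
        "alpha": alpha,
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "lambda": genomic_inflation(pvals).lambda_,
    }


def heritability_recovery(n_replicates: int = 500, seed: int = 0,
                          config: SimConfig | None = None,
                          coverage_replicates: int = 200,
                          true_age_effect: float | None = None) -> dict:
    """Repeated ML fits on one pedigree: heritability and age-effect recovery.

    The pedigree (hence kinship) is fixed across replicates so the
    relatedness eigendecomposition is computed once; covariates, polygenic
    effects, and noise are redrawn each time.  Reports the mean estimated
    heritability and the fraction of 95% Wald intervals for the age effect
    that cover the generating value (over the first ``coverage_replicates``
    replicates).
    """
    base = config if config is not None else SimConfig()
    ped = simulate_pedigree(replace(base, seed=_child_seed(seed, 10_000)))
    kin = pedigree_kinship(ped)
    eig = np.linalg.eigh(kin.additive)
    truth_h2 = base.heritability
    if true_age_effect is None:
        true_age_effect = base.covariate_effects["age"]
    age_ix = DESIGN_COLUMNS.index("age")

    h2_hats, covered = [], []
    for rep in range(n_replicates):
        cfg = replace(base, seed=_child_seed(seed, rep))
        cov = simulate_covariates(ped, cfg)
        Y, _ = simulate_phenotype(ped, cov, cfg, kin)
        fit = PolygenicModel(Y, design_matrix(cov), kin,
                             exog_names=DESIGN_COLUMNS,
                             eig=(eig.eigenvalues, eig.eigenvectors)).fit()
        h2_hats.append(fit.heritability)
        if rep < coverage_replicates:
            lo = fit.params[age_ix] - 1.959964 * fit.bse[age_ix]
            hi = fit.params[age_ix] + 1.959964 * fit.bse[age_ix]
            covered.append(lo <= true_age_effect <= hi)
    h2_hats = np.asarray(h2_hats)
    return {
        "h2_hats": h2_hats,
        "mean_h2": float(h2_hats.mean()),
        "true_h2": float(truth_h2),
        "age_coverage": float(np.mean(covered)),
        "n_replicates": int(n_replicates),
        "coverage_replicates": int(len(covered)),
    }
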