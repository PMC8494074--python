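"""Independent brute-force oracles used only by the tests.

These deliberately re-derive every quantity from first principles with plain
dense matrix arithmetic (explicit inverses, matrix square roots, Monte Carlo
simulation) so they share no code path with the package implementation.
"""

import numpy as np
from scipy.linalg import sqrtm


def brute_force_abt(Y, Z, phi, sigma_a2, sigma_e2, G, use_2phi=True):
    """Gene statistic and null spectrum straight from the defining formulas.

    Recomputes Sigma0, beta_gls, V, and P with explicit inverses, the gene
    covariance with np.cov, and the weighted spectrum through a dense matrix
    square root.  Returns (statistic, eigenvalues sorted descending).
    """
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)
    G = np.asarray(G, float)
    n = len(Y)
    A = 2.0 * phi if use_2phi else np.asarray(phi, float)
    Sigma0 = sigma_e2 * np.eye(n) + sigma_a2 * A
    Si = np.linalg.inv(Sigma0)
    ZtSiZ_inv = np.linalg.inv(Z.T @ Si @ Z)
    beta = ZtSiZ_inv @ (Z.T @ Si @ Y)
    V = Si @ (Y - Z @ beta)
    P = Si - Si @ Z @ ZtSiZ_inv @ Z.T @ Si

    SigG = np.atleast_2d(np.cov(G.T, ddof=1))
    vav = V @ A @ V
    stat = V @ G @ np.linalg.inv(SigG) @ G.T @ V / vav

    W = np.real(sqrtm(np.linalg.inv(SigG))) / np.sqrt(vav)
    M = W @ G.T @ P @ G @ W
    eig = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    return float(stat), np.clip(eig, 0.0, None)


def mc_mixture_sf(lam, s, n_draws, seed):
    """Monte Carlo survival probability of sum_k lam_k * chi2_1."""
    rng = np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for lv in np.asarray(lam, float):
        total += lv * rng.chisquare(1, n_draws)
    p_hat = float((total > s).mean())
    se = np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
    return p_hat, se


def gene_drop_kinship(ped, n_reps, seed):
    """Kinship by gene dropping: founders carry unique allele labels, each
    child inherits one random allele per parent; phi_ij is the probability a
    random allele from i and one from j are identical by descent."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    idx = {iid: i for i, iid in enumerate(ped["iid"])}
    alleles = np.zeros((n, 2, n_reps), dtype=np.int32)
    next_label = 0
    # process in order; assumes parents listed before children
    for i, row in ped.reset_index(drop=True).iterrows():
        f, m = row["father"], row["mother"]
        if f is None:
            alleles[i, 0] = next_label
            alleles[i, 1] = next_label + 1
            next_label += 2
        else:
            fi, mi = idx[f], idx[m]
            pick_f = rng.integers(0, 2, n_reps)
            pick_m = rng.integers(0, 2, n_reps)
            alleles[i, 0] = alleles[fi, pick_f, np.arange(n_reps)]
            alleles[i, 1] = alleles[mi, pick_m, np.arange(n_reps)]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_reps)
            for a in range(2):
                for b in range(2):
                    ibd += alleles[i, a] == alleles[j, b]
            phi[i, j] = phi[j, i] = ibd.mean() / 4.0
    return phi


def grid_loglik(Y, Z, phi, h, use_2phi=True):
    """Profile log-likelihood at heritability ratio h from the raw density.

    Dense evaluation: GLS beta via explicit inverses, ML sigma^2 = weighted
    RSS / n, Gaussian log-density via slogdet and solve.
    """
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)
    n = len(Y)
    A = 2.0 * phi if use_2phi else np.asarray(phi, float)
    C = (1 - h) * np.eye(n) + h * A        # Sigma0 / sigma^2
    Ci = np.linalg.inv(C)
    beta = np.linalg.inv(Z.T @ Ci @ Z) @ (Z.T @ Ci @ Y)
    r = Y - Z @ beta
    sigma2 = float(r @ Ci @ r) / n
    sign, logdet = np.linalg.slogdet(sigma2 * C)
    assert sign > 0
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet
                         + r @ np.linalg.inv(sigma2 * C) @ r))
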