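"""Null polygenic mixed model fitted by maximum likelihood.

The trait is modelled as Y ~ N(Z beta, Sigma0) with

    Sigma0 = sigma_e^2 I + sigma_a^2 A,

where A is the additive relationship matrix.  By default A = 2*Phi (unit
diagonal for outbred samples), so sigma_a^2 / (sigma_a^2 + sigma_e^2) is the
narrow-sense heritability; ``relatedness="phi"`` uses the kinship matrix Phi
itself inside Sigma0 instead, in which case the ratio is not interpretable as
h^2.

The likelihood is profiled: writing sigma^2 = sigma_a^2 + sigma_e^2 and
h = sigma_a^2 / sigma^2, Sigma0 = sigma^2 [(1-h) I + h A].  After a single
eigendecomposition A = U diag(w) U', both beta and sigma^2 have closed-form
ML solutions given h, leaving a 1-D optimization of h on (0, 1) by bounded
Brent search.  The fit exposes the transformed residual V = Sigma0^-1 (Y -
Z beta) and the projection P = Sigma0^-1 - Sigma0^-1 Z (Z' Sigma0^-1 Z)^-1
Z' Sigma0^-1 used by the association tests (V = P Y; P Z = 0; P Sigma0 P = P).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .qc import KinshipMatrix

__all__ = ["PolygenicModel", "PolygenicResults", "fit_null"]

_H_EPS = 1e-6


class PolygenicModel:
    """Gaussian polygenic model for a quantitative trait on related samples.

    Parameters
    ----------
    endog : (n,) array
        Trait values (count-like indices are treated as continuous).
    exog : (n, p) array
        Fixed-effects design including an intercept column; full column rank.
    kinship : KinshipMatrix or (n, n) array of kinship coefficients
    relatedness : {"2phi", "phi"}
        Matrix used inside Sigma0 (and in the test denominators downstream).
    eig : optional (w, U) pair
        Precomputed eigendecomposition of the relatedness matrix, for
        repeated fits on the same pedigree.
    """

    def __init__(self, endog, exog, kinship, relatedness: str = "2phi",
                 exog_names: Optional[Sequence[str]] = None,
                 sample_ids=None, eig=None):
        y = np.asarray(endog, dtype=float).ravel()
        Z = np.asarray(exog, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        n, p = Z.shape
        if len(y) != n:
            raise ValueError("endog/exog length mismatch")
        if not (np.isfinite(y).all() and np.isfinite(Z).all()):
            raise ValueError("non-finite values in endog/exog")
        if n < p + 2:
            raise ValueError("need n >= p + 2 observations")
        if np.linalg.matrix_rank(Z) < p:
            raise ValueError("exog is rank deficient")
        if relatedness not in ("2phi", "phi"):
            raise ValueError("relatedness must be '2phi' or 'phi'")
        if isinstance(kinship, KinshipMatrix):
            phi = kinship.phi
            if sample_ids is None:
                sample_ids = kinship.ids
        else:
            phi = np.asarray(kinship, dtype=float)
        if phi.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        A = 2.0 * phi if relatedness == "2phi" else phi

        if eig is None:
            w, U = np.linalg.eigh(A)
        else:
            w, U = eig
            w = np.asarray(w, dtype=float)
            U = np.asarray(U, dtype=float)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("relatedness matrix is not positive semidefinite")
        w = np.clip(w, 0.0, None)

        self.endog, self.exog = y, Z
        self.nobs, self.k_exog = n, p
        self.A = A
        self.relatedness = relatedness
        self.sample_ids = sample_ids
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(p)])
        self._w, self._U = w, U
        self._yt = U.T @ y
        self._Zt = U.T @ Z

    # -- profile likelihood pieces -------------------------------------

    def _profile(self, h: float):
        """GLS beta, sigma^2_hat, and profile log-likelihood at ratio h."""
        d = (1.0 - h) + h * self._w
        Zd = self._Zt / d[:, None]
        Gm = self._Zt.T @ Zd
        b = Zd.T @ self._yt
        beta = np.linalg.solve(Gm, b)
        resid = self._yt - self._Zt @ beta
        rss = float(resid @ (resid / d))
        n = self.nobs
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + np.log(d).sum())
        return beta, sigma2, ll, d, Gm

    def loglike(self, h: float) -> float:
        """Profile log-likelihood (beta and sigma^2 maximized out) at h."""
        return self._profile(h)[2]

    def fit(self, xtol: float = 1e-8) -> "PolygenicResults":
        """Maximize the likelihood over h in [0, 1); never errors at h = 0."""
        res = minimize_scalar(lambda h: -self.loglike(h),
                              bounds=(_H_EPS, 1.0 - _H_EPS), method="bounded",
                              options={"xatol": xtol})
        h_hat = float(res.x)
        ll_hat = -float(res.fun)
        ll0 = self.loglike(_H_EPS)
        # boundary / flat-ridge resolution: when A = I the likelihood is
        # constant in h and any split is equivalent; report h = 0.
        if ll_hat - ll0 < 1e-6:
            h_hat = 0.0
        beta, sigma2, ll, d, Gm = self._profile(max(h_hat, 0.0) if h_hat > 0 else 0.0)
        cov_beta = sigma2 * np.linalg.inv(Gm)
        return PolygenicResults(self, h_hat, beta, sigma2, cov_beta, ll, d,
                                converged=True)


class PolygenicResults:
    """ML estimates, uncertainties, and the V/P machinery of the null fit."""

    def __init__(self, model: PolygenicModel, h: float, beta: np.ndarray,
                 sigma2: float, cov_beta: np.ndarray, llf: float,
                 d: np.ndarray, converged: bool):
        self.model = model
        self.h = h
        self.params = beta
        self.sigma2 = sigma2
        self.sigma_a2 = h * sigma2
        self.sigma_e2 = (1.0 - h) * sigma2
        self.heritability = h
        self.cov_params = cov_beta
        self.bse = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues = np.where(self.bse > 0, beta / self.bse, 0.0)
        self.pvalues = 2.0 * norm.sf(np.abs(self.zvalues))
        self.llf = llf
        self.converged = converged
        self._d = d
        self._P: Optional[np.ndarray] = None

        # transformed residual V = Sigma0^-1 (Y - Z beta)
        m = model
        resid_t = m._yt - m._Zt @ beta
        self.V = m._U @ (resid_t / (sigma2 * d))
        self.resid = m.endog - m.exog @ beta

    # -- matrices -------------------------------------------------------

    @property
    def sigma0_inv(self) -> np.ndarray:
        m = self.model
        return (m._U / (self.sigma2 * self._d)) @ m._U.T

    @property
    def P(self) -> np.ndarray:
        """Projection Sigma0^-1 - Sigma0^-1 Z (Z'Sigma0^-1 Z)^-1 Z'Sigma0^-1."""
        if self._P is None:
            Si = self.sigma0_inv
            Z = self.model.exog
            SZ = Si @ Z
            self._P = Si - SZ @ np.linalg.solve(Z.T @ SZ, SZ.T)
        return self._P

    def vav(self) -> float:
        """Quadratic form V' A V in the fitted relatedness convention."""
        return float(self.V @ (self.model.A @ self.V))

    # -- summaries ------------------------------------------------------

    def covariate_effect_table(self) -> pd.DataFrame:
        """Estimate, Wald SE, z, and two-sided normal p-value per covariate."""
        return pd.DataFrame({
            "covariate": self.model.exog_names,
            "estimate": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "p_value": self.pvalues,
        })

    def variance_component_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": ["sigma2", "sigma_a2/sigma2", "sigma_e2/sigma2"],
            "estimate": [self.sigma2, self.heritability, 1.0 - self.heritability],
        })

    def summary(self) -> str:
        lines = ["Polygenic null model (ML)",
                 f"n = {self.model.nobs}, p = {self.model.k_exog}, "
                 f"relatedness = {self.model.relatedness}",
                 f"log-likelihood = {self.llf:.4f}",
                 "",
                 "Variance components",
                 f"  sigma^2 (total)     {self.sigma2:10.4f}",
                 f"  sigma_a^2/sigma^2   {self.heritability:10.4f}",
                 f"  sigma_e^2/sigma^2   {1 - self.heritability:10.4f}",
                 "",
                 "Covariate effects      estimate        SE   p-value"]
        for name, b, se, p in zip(self.model.exog_names, self.params,
                                  self.bse, self.pvalues):
            lines.append(f"  {name:<18s} {b:10.4f} {se:9.4f}  {p:.3g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Variance components and covariate effects as one TSV table."""
        vc = self.variance_component_table().rename(columns={"component": "term"})
        vc["se"] = np.nan
        vc["p_value"] = np.nan
        ce = self.covariate_effect_table().rename(columns={"covariate": "term"})
        ce = ce[["term", "estimate", "se", "p_value"]]
        pd.concat([vc[["term", "estimate", "se", "p_value"]], ce],
                  ignore_index=True).to_csv(path, sep="\t", index=False)

    # -- association tests ----------------------------------------------

    def test_gene(self, partition_or_G, **kwargs):
        from .genetest import test_gene
        return test_gene(partition_or_G, self, **kwargs)

    def test_genes(self, partitions, **kwargs):
        from .genetest import test_all_genes
        return test_all_genes(partitions, self, **kwargs)

    def test_snp(self, g, **kwargs):
        from .snptest import snp_score_test
        return snp_score_test(g, self, **kwargs)


def fit_null(Y, Z, kinship, relatedness: str = "2phi", exog_names=None,
             eig=None) -> PolygenicResults:
    """Fit the null polygenic model; convenience wrapper over PolygenicModel."""
    return PolygenicModel(Y, Z, kinship, relatedness=relatedness,
                          exog_names=exog_names, eig=eig).fit()
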