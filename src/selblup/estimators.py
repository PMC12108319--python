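"""Scikit-learn style estimator for selection-adjusted GBLUP.

``GBLUPRegressor`` wraps the GRM construction and REML machinery behind a
fit/predict interface so the model composes with sklearn pipelines and
model selection. ``X`` is an individuals x SNPs dosage matrix (0/1/2, nan
for missing); ``y`` is the phenotype vector.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinship import _scaled_centered_matrix, MAF_BIN_EDGES
from .kinship import KinshipMatrix
from .mixedmodel import fit_reml, lrt, FitResult
from . import mixedmodel
from scipy import linalg


class GBLUPRegressor(BaseEstimator, RegressorMixin):
    """Genomic BLUP with a selection-adjusted relationship matrix.

    Parameters
    ----------
    s_value : float, default 0.0
        Assumed MAF/effect-size exponent. Centered dosages are scaled by
        ``[2p(1-p)]^(s_value/2)``; 0 gives the VanRaden GRM, -1 the GCTA
        (per-SNP standardized) GRM.
    maf_stratified : bool, default False
        If True, fit one variance component per MAF bin (five-component
        model) instead of a single GRM.
    allele_freq : array-like or None
        Counted-allele frequencies to use for centering and scaling. When
        None they are estimated from the training ``X``. Supplying
        frequencies estimated on the full reference+candidate panel puts
        training and candidate genotypes on a common scale.
    max_iter : int, default 200
        REML iteration cap.
    tol : float, default 1e-6
        REML log-likelihood convergence tolerance.

    Attributes
    ----------
    sigma_a2_ : ndarray
        Estimated additive variance(s), one per component.
    sigma_e2_ : float
        Estimated residual variance.
    h2_ : float
        Total genomic heritability estimate.
    h2_per_component_ : ndarray
        Per-bin heritability shares (stratified model).
    loglik_ : float
        Restricted log-likelihood at the optimum.
    lrt_ : float
        Likelihood-ratio statistic against the residual-only null.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        s_value: float = 0.0,
        maf_stratified: bool = False,
        allele_freq=None,
        max_iter: int = 200,
        tol: float = 1e-6,
    ):
        self.s_value = s_value
        self.maf_stratified = maf_stratified
        self.allele_freq = allele_freq
        self.max_iter = max_iter
        self.tol = tol

    def _validate_x(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-D (individuals x SNPs)")
        finite = x[~np.isnan(x)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        return x

    def _components(self, freq: np.ndarray) -> list[np.ndarray]:
        """SNP-column index sets, one per variance component."""
        maf = np.minimum(freq, 1.0 - freq)
        if not self.maf_stratified:
            return [np.arange(len(freq))]
        inner = np.array(MAF_BIN_EDGES[1:-1])
        assignment = np.digitize(maf, inner, right=True)
        return [
            np.flatnonzero(assignment == t)
            for t in range(len(MAF_BIN_EDGES) - 1)
            if np.any(assignment == t)
        ]

    def fit(self, X, y):
        """Estimate variance components by REML on the training data."""
        x = self._validate_x(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != x.shape[0]:
            raise ValueError("X and y have inconsistent numbers of individuals")

        if self.allele_freq is not None:
            freq = np.asarray(self.allele_freq, dtype=float)
            if len(freq) != x.shape[1]:
                raise ValueError("allele_freq length does not match X columns")
        else:
            n_called = np.sum(~np.isnan(x), axis=0)
            freq = np.nansum(x, axis=0) / (2.0 * n_called)
        if np.any((freq <= 0.0) | (freq >= 1.0)):
            raise ValueError(
                "monomorphic SNP (p of 0 or 1); remove it or pass panel-wide "
                "allele_freq"
            )

        comps = self._components(freq)
        ms, denoms, grms = [], [], []
        individuals = [("0", str(j)) for j in range(x.shape[0])]
        for idx in comps:
            m, d = _scaled_centered_matrix(x[:, idx], freq[idx], self.s_value)
            ms.append(m)
            denoms.append(d)
            grms.append(
                KinshipMatrix(
                    values=(m @ m.T) / d,
                    individuals=individuals,
                    s_value=float(self.s_value),
                    snp_ids=[str(i) for i in idx],
                    denominator=d,
                )
            )

        fit = fit_reml(y, grms, max_iter=self.max_iter, tol=self.tol)
        null = fit_reml(y, [], max_iter=self.max_iter, tol=self.tol)

        self.freq_ = freq
        self.components_ = comps
        self.X_train_ = x
        self.y_train_ = y
        self.fit_result_ = fit
        self.sigma_a2_ = fit.sigma_a2
        self.sigma_e2_ = fit.sigma_e2
        self.h2_ = fit.h2_total
        self.h2_per_component_ = fit.h2_per_component
        self.loglik_ = fit.loglik
        self.lrt_ = lrt(fit, null)
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.n_features_in_ = x.shape[1]
        # cache P y for prediction (training-block REML projection)
        n = len(y)
        v = fit.sigma_e2 * np.eye(n)
        for t, g in enumerate(grms):
            v += fit.sigma_a2[t] * g.values
        c, low = linalg.cho_factor(v, lower=True)
        ones = np.ones((n, 1))
        vi_y = linalg.cho_solve((c, low), y)
        vi_x = linalg.cho_solve((c, low), ones)
        beta = float((ones.T @ vi_y).item() / (ones.T @ vi_x).item())
        self.intercept_ = beta
        self._py = vi_y - vi_x.ravel() * beta
        self._ms = ms
        self._denoms = denoms
        return self

    def predict(self, X):
        """GEBV (plus the fitted intercept) for candidate individuals.

        The candidate dosages are centered and scaled with the training
        (or user-supplied) allele frequencies, the cross-relationships to
        the training individuals are formed, and each component's BLUP is
        accumulated.
        """
        check_is_fitted(self, "fit_result_")
        x = self._validate_x(X)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of SNPs than at fit")
        gebv = np.zeros(x.shape[0])
        for t, idx in enumerate(self.components_):
            if self.sigma_a2_[t] <= 0.0:
                continue
            m_cand, _ = _scaled_centered_matrix(
                x[:, idx], self.freq_[idx], self.s_value
            )
            g_cross = (m_cand @ self._ms[t].T) / self._denoms[t]
            gebv += self.sigma_a2_[t] * (g_cross @ self._py)
        return self.intercept_ + gebv

    def gebv(self, X):
        """Centered genetic values (no intercept) for candidates."""
        return self.predict(X) - self.intercept_
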