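"""REML variance components, likelihood-ratio statistics and BLUP.

The model is y = 1*mu + sum_t a_t + e with a_t ~ N(0, G_t sigma_t^2) and
e ~ N(0, I sigma_e^2); phenotypes are expected to be pre-adjusted for fixed
effects, but an intercept is always projected out for robustness.

Single-GRM fits use an eigendecomposition of G and a bounded 1-D search
over the heritability ratio (the profile restricted likelihood is exact and
cheap in the rotated basis). Multi-GRM fits use average-information REML
with an expectation-maximization fallback whenever an AI step would leave
the nonnegative orthant or decrease the restricted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .kinship import KinshipMatrix

_PSD_TOL = 1e-8  # relative floor on GRM eigenvalues


@dataclass
class FitResult:
    """REML estimates for one model fit."""

    sigma_a2: np.ndarray  # per-component additive variances
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    _y_fingerprint: tuple = ()

    @property
    def h2_total(self) -> float:
        tot = float(np.sum(self.sigma_a2))
        return tot / (tot + self.sigma_e2)

    @property
    def h2_per_component(self) -> np.ndarray:
        denom = float(np.sum(self.sigma_a2)) + self.sigma_e2
        return np.asarray(self.sigma_a2) / denom

    @property
    def n_components(self) -> int:
        return len(np.atleast_1d(self.sigma_a2))


@dataclass
class PredictionResult:
    """Genomic estimated breeding values for candidate individuals."""

    gebv: np.ndarray
    individuals: list[tuple[str, str]]
    model: dict

    def __post_init__(self) -> None:
        if len(self.gebv) != len(self.individuals):
            raise ValueError("GEBV length does not match candidate count")


def _fingerprint(y: np.ndarray) -> tuple:
    return (len(y), round(float(np.sum(y)), 9), round(float(np.sum(y * y)), 9))


def _check_psd(g: np.ndarray) -> None:
    w = np.linalg.eigvalsh(g)
    if w[0] < -_PSD_TOL * max(w[-1], 1.0):
        raise ValueError("GRM is not positive semi-definite beyond tolerance")


def restricted_loglik(
    y: np.ndarray, v: np.ndarray, x: np.ndarray | None = None
) -> float:
    """Dense REML log-likelihood of y ~ N(X b, V) with X defaulting to 1.

    Includes the -(n-p)/2 log(2*pi) + 1/2 log|X'X| constants, so values
    from different fitting paths on the same data are directly comparable.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x is None:
        x = np.ones((n, 1))
    p = x.shape[1]
    c, low = linalg.cho_factor(v, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vi_y = linalg.cho_solve((c, low), y)
    vi_x = linalg.cho_solve((c, low), x)
    xtvix = x.T @ vi_x
    beta = np.linalg.solve(xtvix, x.T @ vi_y)
    ypy = float(y @ vi_y - (x.T @ vi_y) @ beta)
    _, logdet_xtvix = np.linalg.slogdet(xtvix)
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)
    return float(
        -0.5 * (logdet_v + logdet_xtvix + ypy)
        - 0.5 * (n - p) * np.log(2.0 * np.pi)
        + 0.5 * logdet_xtx
    )


def _fit_single(
    y: np.ndarray, grm: KinshipMatrix, max_iter: int
) -> FitResult:
    """Profile-REML over h2 for one GRM via eigendecomposition."""
    n = len(y)
    lam, u = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0.0, None)
    yt = u.T @ y
    xt = u.T @ np.ones(n)

    def neg_profile(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        xtvix = np.sum(xt * xt / d)
        beta = np.sum(xt * yt / d) / xtvix
        r = yt - beta * xt
        quad = np.sum(r * r / d)
        sigma_p2 = quad / (n - 1)
        return 0.5 * (
            np.sum(np.log(d))
            + (n - 1) * np.log(sigma_p2)
            + np.log(xtvix)
            + (n - 1)
        )

    # coarse grid guards against local minima, then a bounded refine
    grid = np.linspace(0.0, 1.0 - 1e-9, 101)
    vals = [neg_profile(h) for h in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    h2 = float(res.x)
    if neg_profile(0.0) <= res.fun:
        h2 = 0.0

    d = h2 * lam + (1.0 - h2)
    xtvix = np.sum(xt * xt / d)
    beta = np.sum(xt * yt / d) / xtvix
    r = yt - beta * xt
    sigma_p2 = float(np.sum(r * r / d) / (n - 1))
    sigma_a2 = h2 * sigma_p2
    sigma_e2 = (1.0 - h2) * sigma_p2
    v = sigma_a2 * grm.values + sigma_e2 * np.eye(n)
    return FitResult(
        sigma_a2=np.array([sigma_a2]),
        sigma_e2=sigma_e2,
        loglik=restricted_loglik(y, v),
        converged=bool(res.success),
        n_iter=int(res.nfev) + len(grid),
        n_obs=n,
        _y_fingerprint=_fingerprint(y),
    )


def _fit_multi(
    y: np.ndarray,
    gs: list[np.ndarray],
    max_iter: int,
    tol: float,
    param_tol: float = 1e-6,
) -> FitResult:
    """AI-REML over k genetic components plus a residual."""
    n = len(y)
    k = len(gs)
    x = np.ones((n, 1))
    var_y = float(np.var(y, ddof=1))
    floor = 1e-8 * var_y
    theta = np.full(k + 1, var_y / (k + 1))  # genetic components + residual

    def build_v(th: np.ndarray) -> np.ndarray:
        v = th[k] * np.eye(n)
        for t in range(k):
            v += th[t] * gs[t]
        return v

    def loglik(th: np.ndarray) -> float:
        return restricted_loglik(y, build_v(th), x)

    ll = loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = build_v(theta)
        c, low = linalg.cho_factor(v, lower=True)
        vi = linalg.cho_solve((c, low), np.eye(n))
        vix = vi @ x
        proj = vi - vix @ np.linalg.solve(x.T @ vix, vix.T)
        py = proj @ y

        # columns of u: G_t P y per component, then P y for the residual
        u_cols = [g @ py for g in gs] + [py]
        u = np.column_stack(u_cols)
        grad = np.empty(k + 1)
        for t in range(k):
            grad[t] = -0.5 * (np.sum(proj * gs[t]) - py @ u_cols[t])
        grad[k] = -0.5 * (np.trace(proj) - py @ py)
        ai = 0.5 * (u.T @ proj @ u)

        def em_step(th: np.ndarray) -> np.ndarray:
            new = th.copy()
            for t in range(k):
                new[t] = th[t] + th[t] ** 2 * (py @ u_cols[t] - np.sum(proj * gs[t])) / n
            new[k] = th[k] + th[k] ** 2 * (py @ py - np.trace(proj)) / n
            return np.maximum(new, floor)

        # active set: components pinned at the floor whose gradient points
        # further negative are frozen out of the AI system (boundary optimum)
        free = ~((theta <= 1.001 * floor) & (grad < 0.0))
        free[k] = True  # residual variance always free
        step_kind = "ai"
        delta = np.zeros(k + 1)
        try:
            delta[free] = np.linalg.solve(
                ai[np.ix_(free, free)], grad[free]
            )
            # components driven negative jump to the floor rather than
            # creeping toward it via EM
            candidate = np.maximum(theta + delta, floor)
        except np.linalg.LinAlgError:
            candidate = em_step(theta)
            step_kind = "em"

        ll_new = loglik(candidate)
        if step_kind == "ai" and ll_new < ll - 1e-8:
            # halve the projected AI step; fall back to EM if it never helps
            for _ in range(10):
                delta *= 0.5
                candidate = np.maximum(theta + delta, floor)
                ll_new = loglik(candidate)
                if ll_new >= ll - 1e-8:
                    break
            else:
                candidate = em_step(theta)
                ll_new = loglik(candidate)

        # components pinned near the zero floor are excluded from the
        # relative-change criterion (EM creeps there without moving loglik)
        rel_change = np.max(
            np.abs(candidate - theta) / np.maximum(np.abs(theta), 1e-4 * var_y)
        )
        dll = ll_new - ll
        theta, ll = candidate, ll_new
        if abs(dll) < tol and rel_change < param_tol:
            converged = True
            break

    theta = np.where(theta <= 2 * floor, 0.0, theta)
    return FitResult(
        sigma_a2=theta[:k].copy(),
        sigma_e2=float(max(theta[k], floor)),
        loglik=loglik(np.maximum(theta, floor)),
        converged=converged,
        n_iter=it,
        n_obs=n,
        _y_fingerprint=_fingerprint(y),
    )


def fit_reml(
    y: np.ndarray,
    grms: list[KinshipMatrix],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FitResult:
    """REML fit of y against zero or more kinship components.

    With one GRM the exact profile likelihood is optimized over the
    heritability ratio; with several, AI-REML with nonnegativity projection
    is used. An empty GRM list fits the residual-only null model. All GRMs
    must share the individual ordering of y.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    for g in grms:
        if g.n != n:
            raise ValueError("GRM dimension does not match phenotype length")
        _check_psd(g.values)

    if len(grms) == 0:
        x = np.ones((n, 1))
        resid = y - y.mean()
        sigma_e2 = float(resid @ resid / (n - 1))
        return FitResult(
            sigma_a2=np.zeros(0),
            sigma_e2=sigma_e2,
            loglik=restricted_loglik(y, sigma_e2 * np.eye(n), x),
            converged=True,
            n_iter=0,
            n_obs=n,
            _y_fingerprint=_fingerprint(y),
        )
    if len(grms) == 1:
        return _fit_single(y, grms[0], max_iter)
    return _fit_multi(y, [g.values for g in grms], max_iter, tol)


def lrt(full: FitResult, null: FitResult) -> float:
    """Likelihood-ratio statistic 2*(loglik_full - loglik_null), floored at 0.

    ``null`` must be the residual-only fit of the same phenotype vector.
    """
    if null.n_components != 0:
        raise ValueError("null fit must have no genetic components")
    if full._y_fingerprint != null._y_fingerprint:
        raise ValueError("full and null fits used different phenotype vectors")
    return max(0.0, 2.0 * (full.loglik - null.loglik))


def lrt_pvalue(statistic: float) -> float:
    """Boundary-null p-value for a single-component LRT.

    Uses the 0.5*chi2_0 + 0.5*chi2_1 mixture appropriate when one variance
    is tested against its zero boundary.
    """
    if statistic <= 0.0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(statistic, df=1))


def predict_gebv(
    fit: FitResult,
    grms_full: list[KinshipMatrix],
    y_train: np.ndarray,
    train_idx: np.ndarray,
    cand_idx: np.ndarray,
) -> PredictionResult:
    """BLUP of candidate genetic values from a training-set REML fit.

    Per component t, a_t(cand) = sigma_t^2 G_t[cand,train] P y where P is
    the REML projection built on the training block; the GEBV is the sum
    over components. Equivalent to solving the mixed-model equations on the
    training block and extending by the genomic covariance.
    """
    train_idx = np.asarray(train_idx)
    cand_idx = np.asarray(cand_idx)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if len(y_train) != len(train_idx):
        raise ValueError("y_train length does not match train_idx")
    if fit.n_components != len(grms_full):
        raise ValueError("fit component count does not match GRM list")
    sig = np.atleast_1d(fit.sigma_a2)
    if np.all(sig <= 0.0) and fit.sigma_e2 <= 0.0:
        raise ValueError("all variance components are zero; V is singular")

    n_train = len(train_idx)
    v = fit.sigma_e2 * np.eye(n_train)
    for t, g in enumerate(grms_full):
        v += sig[t] * g.values[np.ix_(train_idx, train_idx)]
    c, low = linalg.cho_factor(v, lower=True)
    x = np.ones((n_train, 1))
    vi_y = linalg.cho_solve((c, low), y_train)
    vi_x = linalg.cho_solve((c, low), x)
    beta = np.linalg.solve(x.T @ vi_x, x.T @ vi_y)
    py = vi_y - vi_x @ beta

    gebv = np.zeros(len(cand_idx))
    for t, g in enumerate(grms_full):
        if sig[t] > 0.0:
            gebv += sig[t] * (g.values[np.ix_(cand_idx, train_idx)] @ py)

    individuals = [grms_full[0].individuals[i] for i in cand_idx]
    return PredictionResult(
        gebv=gebv,
        individuals=individuals,
        model={
            "s_value": grms_full[0].s_value,
            "n_components": fit.n_components,
            "n_train": n_train,
        },
    )
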