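"""Random-intercept binomial logit GLMM with Laplace-approximated likelihood.

The model for observation j in group (pair) i with successes k out of m is

    k_ij ~ Binomial(m_ij, p_ij),   logit(p_ij) = β0 + β1 x_ij + u_i [+ e_ij]

with u_i ~ N(0, σ_u²) and, in the observation-level random effect (OLRE)
variant used to absorb overdispersion, e_ij ~ N(0, σ_obs²).

The marginal likelihood integrates the random effects out per group.  That
integral is approximated by Laplace's method: the joint log-density is
maximised over the group's random-effect vector by a damped Newton
iteration (the objective is strictly concave, so the iteration is
globally convergent with step halving), and the Gaussian curvature
correction −½ log det(−H) is added at the mode.  At σ_u = 0 the marginal
likelihood is the plain binomial GLM likelihood, computed exactly.

Inference on the dye coefficient β1 uses a Wald t with residual degrees of
freedom n_obs − n_fixed − n_variance_components (17 for the study's
10-pair reciprocal design), with a Wald Z variant also available.
Overdispersion is diagnosed from deviance and Pearson residuals at the
conditional fit (fixed effects plus conditional modes).
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from .records import DispersionReport, GLMMFit, TestResult

log = logging.getLogger("spermcomp.glmm")

_LOG_SIGMA_BOUNDS = (-7.0, 3.0)
_BETA_BOUND = 15.0


class GLMMError(RuntimeError):
    """Numerical failure while fitting or evaluating the model."""


class SeparationWarning(UserWarning):
    """A treatment arm is all-successes or all-failures."""


class GLMMData:
    """Grouped binomial observations with a binary treatment covariate."""

    def __init__(self, group: np.ndarray, x: np.ndarray, k: np.ndarray,
                 m: np.ndarray, group_labels: Optional[Sequence] = None):
        self.group = np.asarray(group, dtype=np.intp)
        self.x = np.asarray(x, dtype=float)
        self.k = np.asarray(k, dtype=float)
        self.m = np.asarray(m, dtype=float)
        if not (len(self.group) == len(self.x) == len(self.k) == len(self.m)):
            raise ValueError("group, x, k, m must have equal length")
        if np.any(self.k < 0) or np.any(self.k > self.m) or np.any(self.m < 1):
            raise ValueError("need 0 <= k <= m and m >= 1")
        self.n_groups = int(self.group.max()) + 1 if len(self.group) else 0
        if group_labels is None:
            group_labels = [str(g) for g in range(self.n_groups)]
        self.group_labels = list(group_labels)
        counts = np.bincount(self.group, minlength=self.n_groups)
        if np.any(counts == 0):
            raise ValueError("every group must have at least one observation")
        # binomial normalising constants, fixed given the data
        self.log_choose = (
            special.gammaln(self.m + 1)
            - special.gammaln(self.k + 1)
            - special.gammaln(self.m - self.k + 1)
        )

    @classmethod
    def from_observations(
        cls, obs: Iterable[Tuple[object, float, int, int]]
    ) -> "GLMMData":
        """Build from (group_id, x, successes k, denominator m) tuples."""
        obs = list(obs)
        labels: List[object] = []
        index = {}
        codes = []
        for g, _, _, _ in obs:
            if g not in index:
                index[g] = len(labels)
                labels.append(g)
            codes.append(index[g])
        return cls(
            np.array(codes),
            np.array([o[1] for o in obs], float),
            np.array([o[2] for o in obs], float),
            np.array([o[3] for o in obs], float),
            group_labels=labels,
        )

    @property
    def n_obs(self) -> int:
        return len(self.k)


# ---------------------------------------------------------------------------
# likelihood machinery


def _binom_ll_terms(data: GLMMData, eta: np.ndarray) -> np.ndarray:
    """Per-observation binomial log-likelihood at linear predictor eta."""
    return data.log_choose + data.k * eta - data.m * np.logaddexp(0.0, eta)


def glm_loglik(beta0: float, beta1: float, data: GLMMData) -> float:
    """Exact binomial GLM log-likelihood (the σ_u = 0 limit)."""
    eta = beta0 + beta1 * data.x
    return float(_binom_ll_terms(data, eta).sum())


def _group_objective(data: GLMMData, eta0: np.ndarray, u: np.ndarray,
                     su2: float) -> np.ndarray:
    eta = eta0 + u[data.group]
    per_obs = data.k * eta - data.m * np.logaddexp(0.0, eta)
    h = np.bincount(data.group, per_obs, minlength=data.n_groups)
    return h - u ** 2 / (2.0 * su2)


def _inner_modes_1d(data: GLMMData, eta0: np.ndarray, sigma: float,
                    tol: float = 1e-9, max_iter: int = 100):
    """Damped Newton for the per-group 1-D random-intercept modes.

    Returns (u_hat, neg_hessian_per_group).  Vectorised over groups; the
    per-group objective is strictly concave so damped Newton converges.
    """
    su2 = sigma * sigma
    G = data.n_groups
    u = np.zeros(G)
    h = _group_objective(data, eta0, u, su2)
    for _ in range(max_iter):
        eta = eta0 + u[data.group]
        p = special.expit(eta)
        resid = data.k - data.m * p
        grad = np.bincount(data.group, resid, minlength=G) - u / su2
        w = data.m * p * (1.0 - p)
        neg_hess = np.bincount(data.group, w, minlength=G) + 1.0 / su2
        step = grad / neg_hess
        # scale-invariant criterion: Newton step relative to the mode
        step_max = np.max(np.abs(step))
        if step_max < tol * (1.0 + np.max(np.abs(u))):
            return u, neg_hess
        if step_max < 1e-4:
            # terminal pure-Newton phase: concavity guarantees convergence,
            # and objective changes are below round-off, so no damping
            u = u + step
            continue
        # elementwise step halving until every group's objective improves
        factor = np.ones(G)
        h_scale = 1e-12 * (1.0 + np.abs(h))
        for _ in range(40):
            u_new = u + factor * step
            h_new = _group_objective(data, eta0, u_new, su2)
            bad = h_new < h - h_scale
            if not np.any(bad):
                break
            factor[bad] *= 0.5
        u, h = u_new, np.maximum(h, h_new)
    if np.max(np.abs(step)) > 1e-6:
        worst = int(np.argmax(np.abs(step)))
        raise GLMMError(
            f"inner Newton failed to converge (group "
            f"{data.group_labels[worst]}, |step|={np.max(np.abs(step)):.2e})"
        )
    return u, neg_hess


def _laplace_1d(beta0: float, beta1: float, sigma: float, data: GLMMData,
                group_index: Optional[np.ndarray] = None):
    """Laplace log-marginal for a single Gaussian intercept per group.

    With ``group_index`` = arange(n_obs) this doubles as the pure-OLRE
    integrator (one intercept per observation).
    """
    eta0 = beta0 + beta1 * data.x
    if group_index is None:
        group_index = data.group
        n_groups = data.n_groups
        labels = data.group_labels
    else:
        n_groups = len(group_index)
        labels = [str(i) for i in range(n_groups)]
    sub = GLMMData.__new__(GLMMData)
    sub.group = group_index
    sub.x, sub.k, sub.m = data.x, data.k, data.m
    sub.n_groups, sub.group_labels = n_groups, labels
    sub.log_choose = data.log_choose
    u, neg_hess = _inner_modes_1d(sub, eta0, sigma)
    eta = eta0 + u[group_index]
    ll = float(_binom_ll_terms(data, eta).sum())
    ll -= float((u ** 2).sum()) / (2.0 * sigma * sigma)
    ll -= n_groups * np.log(sigma)
    ll -= 0.5 * float(np.log(neg_hess).sum())
    return ll, u


def _laplace_2level(beta0: float, beta1: float, sigma_u: float,
                    sigma_obs: float, data: GLMMData,
                    tol: float = 1e-9, max_iter: int = 100):
    """Laplace log-marginal with pair intercepts u_i and OLRE e_ij.

    Per group the random vector is (u, e_1..e_n); the Newton step solves
    the arrow-structured Hessian exactly via its Schur complement, and
    log det(−H) = log S + Σ log d with S the Schur complement of the u
    block and d the e-block diagonal.
    """
    su2, se2 = sigma_u * sigma_u, sigma_obs * sigma_obs
    G, n = data.n_groups, data.n_obs
    g = data.group
    eta0 = beta0 + beta1 * data.x
    u = np.zeros(G)
    e = np.zeros(n)

    def objective(u, e):
        eta = eta0 + u[g] + e
        per_obs = data.k * eta - data.m * np.logaddexp(0.0, eta)
        h = np.bincount(g, per_obs - e ** 2 / (2.0 * se2), minlength=G)
        return h - u ** 2 / (2.0 * su2)

    h = objective(u, e)
    for _ in range(max_iter):
        eta = eta0 + u[g] + e
        p = special.expit(eta)
        resid = data.k - data.m * p
        w = data.m * p * (1.0 - p)
        g_u = np.bincount(g, resid, minlength=G) - u / su2
        g_e = resid - e / se2
        d = w + 1.0 / se2                      # e-block diagonal of −H
        c_over_d = w / d
        S = np.bincount(g, w * (1.0 - c_over_d), minlength=G) + 1.0 / su2
        s_u = (g_u - np.bincount(g, c_over_d * g_e, minlength=G)) / S
        s_e = (g_e - w * s_u[g]) / d
        smax = max(np.max(np.abs(s_u)), np.max(np.abs(s_e)))
        if smax < tol * (1.0 + max(np.max(np.abs(u)), np.max(np.abs(e)))):
            break
        if smax < 1e-4:
            u, e = u + s_u, e + s_e
            continue
        factor = np.ones(G)
        h_scale = 1e-12 * (1.0 + np.abs(h))
        for _ in range(40):
            u_new = u + factor * s_u
            e_new = e + factor[g] * s_e
            h_new = objective(u_new, e_new)
            bad = h_new < h - h_scale
            if not np.any(bad):
                break
            factor[bad] *= 0.5
        u, e, h = u_new, e_new, np.maximum(h, h_new)
    else:
        raise GLMMError("inner Newton (OLRE) failed to converge")

    eta = eta0 + u[g] + e
    ll = float(_binom_ll_terms(data, eta).sum())
    ll -= float((u ** 2).sum()) / (2.0 * su2) + float((e ** 2).sum()) / (2.0 * se2)
    ll -= G * np.log(sigma_u) + n * np.log(sigma_obs)
    ll -= 0.5 * (float(np.log(S).sum()) + float(np.log(d).sum()))
    return ll, u, e


def laplace_loglik(beta0: float, beta1: float, sigma_u: float,
                   data: GLMMData, sigma_obs: Optional[float] = None) -> float:
    """Laplace-approximated marginal log-likelihood of the model.

    Exactly equals the binomial GLM log-likelihood when all variance
    components are zero.
    """
    if sigma_u < 0 or (sigma_obs is not None and sigma_obs < 0):
        raise ValueError("variance-component SDs must be nonnegative")
    has_olre = sigma_obs is not None and sigma_obs > 0
    if sigma_u == 0 and not has_olre:
        return glm_loglik(beta0, beta1, data)
    if sigma_u == 0 and has_olre:
        ll, _ = _laplace_1d(beta0, beta1, sigma_obs, data,
                            group_index=np.arange(data.n_obs))
        return ll
    if not has_olre:
        ll, _ = _laplace_1d(beta0, beta1, sigma_u, data)
        return ll
    ll, _, _ = _laplace_2level(beta0, beta1, sigma_u, sigma_obs, data)
    return ll


# ---------------------------------------------------------------------------
# fitting


def _irls_glm(data: GLMMData, max_iter: int = 60, tol: float = 1e-12):
    """Binomial logit GLM on (intercept, x) by iteratively reweighted LS."""
    beta = np.zeros(2)
    X = np.column_stack([np.ones(data.n_obs), data.x])
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = data.m * p * (1.0 - p)
        resid = data.k - data.m * p
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ resid
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise GLMMError(f"GLM warm start failed: {exc}") from exc
        beta = np.clip(beta + step, -_BETA_BOUND, _BETA_BOUND)
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _detect_separation(data: GLMMData) -> bool:
    for val in (0.0, 1.0):
        mask = data.x == val
        if mask.any():
            if np.all(data.k[mask] == 0) or np.all(data.k[mask] == data.m[mask]):
                return True
    return False


def _beta_block_se(nll, beta0: float, beta1: float) -> Tuple[float, float]:
    """SEs from the observed information of the fixed-effect block.

    Central-difference 2×2 Hessian of the negative log-likelihood in
    (β0, β1) with the variance components held at their estimates — the
    standard conditional covariance of the fixed effects.
    """
    h0 = 1e-5 * max(1.0, abs(beta0))
    h1 = 1e-5 * max(1.0, abs(beta1))
    f = nll

    def d2(fpp, fpm, fmp, fmm, ha, hb):
        return (fpp - fpm - fmp + fmm) / (4.0 * ha * hb)

    f00 = f(beta0, beta1)
    H = np.empty((2, 2))
    H[0, 0] = (f(beta0 + h0, beta1) - 2 * f00 + f(beta0 - h0, beta1)) / h0 ** 2
    H[1, 1] = (f(beta0, beta1 + h1) - 2 * f00 + f(beta0, beta1 - h1)) / h1 ** 2
    H[0, 1] = H[1, 0] = d2(
        f(beta0 + h0, beta1 + h1), f(beta0 + h0, beta1 - h1),
        f(beta0 - h0, beta1 + h1), f(beta0 - h0, beta1 - h1), h0, h1,
    )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise GLMMError(f"observed information is singular: {exc}") from exc
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        raise GLMMError("observed information is not positive definite")
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


def fit_glmm(data: GLMMData, olre: bool = False, *,
             start: Optional[Sequence[float]] = None,
             gtol: float = 1e-8) -> GLMMFit:
    """Maximise the Laplace marginal likelihood by quasi-Newton iteration.

    Parameters are (β0, β1, log σ_u[, log σ_obs]); optimisation starts
    from an IRLS logistic-GLM warm start with a small initial σ.  A fit
    whose σ_u collapses to the lower bound is refitted exactly at σ_u = 0
    (plain GLM for the base model) and flagged as a boundary fit.
    Fixed-effect SEs come from the observed-information (2×2 β block,
    variance components held fixed).
    """
    if data.n_groups < 2:
        raise ValueError("need at least 2 groups")
    if len(np.unique(data.x)) < 2:
        raise ValueError("both treatment levels must be present")
    separation = _detect_separation(data)
    if separation:
        log.warning("complete separation in a treatment arm; estimates are "
                    "bounded at |beta| <= %.0f", _BETA_BOUND)

    beta_start = _irls_glm(data) if start is None else np.asarray(start[:2], float)
    n_var = 2 if olre else 1
    theta0 = np.concatenate([beta_start, np.full(n_var, np.log(0.3))])
    trace: List[float] = []

    def nll(theta):
        b0, b1 = theta[0], theta[1]
        sig_u = float(np.exp(theta[2]))
        sig_e = float(np.exp(theta[3])) if olre else None
        try:
            return -laplace_loglik(b0, b1, sig_u, data, sigma_obs=sig_e)
        except GLMMError:
            return np.inf

    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * 2 + [_LOG_SIGMA_BOUNDS] * n_var
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        callback=lambda th: trace.append(-nll(th)),
        options={"gtol": gtol, "ftol": 1e-13, "maxiter": 500},
    )
    if not res.success and "ROUND" not in str(res.message).upper():
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
        if not (res.success or res2.success):
            raise GLMMError(f"optimizer did not converge: {res.message}")

    theta = res.x
    beta0, beta1 = float(theta[0]), float(theta[1])
    sigma_u = float(np.exp(theta[2]))
    sigma_obs = float(np.exp(theta[3])) if olre else None
    boundary = theta[2] <= _LOG_SIGMA_BOUNDS[0] + 0.2
    loglik = -float(res.fun)

    if boundary and not olre:
        # exact sigma_u = 0 refit: plain GLM
        beta_glm = _irls_glm(data)
        ll_glm = glm_loglik(*beta_glm, data)
        if ll_glm >= loglik - 1e-9:
            beta0, beta1 = float(beta_glm[0]), float(beta_glm[1])
            sigma_u, loglik = 0.0, float(ll_glm)

    def nll_beta(b0, b1, _su=sigma_u, _se=sigma_obs):
        return -laplace_loglik(b0, b1, _su, data, sigma_obs=_se)

    se0, se1 = _beta_block_se(nll_beta, beta0, beta1)

    if sigma_u == 0 and sigma_obs is None:
        u_hat = np.zeros(data.n_groups)
        e_hat = None
    elif sigma_obs is None:
        _, u_hat = _laplace_1d(beta0, beta1, sigma_u, data)
        e_hat = None
    elif sigma_u == 0:
        _, e_hat = _laplace_1d(beta0, beta1, sigma_obs, data,
                               group_index=np.arange(data.n_obs))
        u_hat = np.zeros(data.n_groups)
    else:
        _, u_hat, e_hat = _laplace_2level(beta0, beta1, sigma_u, sigma_obs, data)

    return GLMMFit(
        beta0=beta0, beta1=beta1, sigma_u=sigma_u, sigma_obs=sigma_obs,
        loglik=loglik, se_beta0=se0, se_beta1=se1,
        conditional_modes=u_hat, olre_modes=e_hat,
        n_obs=data.n_obs, n_groups=data.n_groups,
        boundary=bool(boundary),
        converged=True, separation=separation, loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# inference and diagnostics


def residual_df(n_obs: int, n_fixed: int = 2, n_variance: int = 1) -> int:
    """Residual degrees of freedom: n_obs − n_fixed − n_variance.

    The study's design (10 pairs × 2 observations, intercept + dye effect,
    one pair variance component) gives 20 − 2 − 1 = 17.  The OLRE variance
    is not counted, matching the convention under which the study reports
    17 df for both model variants.
    """
    df = n_obs - n_fixed - n_variance
    if df < 1:
        raise ValueError("residual df < 1")
    return df


def t_pvalue(statistic: float, df: float) -> float:
    """Two-sided p-value of a t statistic."""
    return float(2.0 * stats.t.sf(abs(statistic), df))


def wald_test(fit: GLMMFit, df_policy: object = "design", dist: str = "t",
              se_inflation: Optional[float] = None) -> TestResult:
    """Wald test of the dye coefficient β1.

    ``df_policy`` is either the string "design" (n_obs − n_fixed − 1) or an
    explicit integer.  ``dist`` selects the t reference (default) or the
    normal ("z").  ``se_inflation`` optionally multiplies the SE by
    √dispersion for a quasi-likelihood sensitivity check.
    """
    se = fit.se_beta1
    if se_inflation is not None:
        se = se * float(np.sqrt(se_inflation))
    if se <= 0 or not np.isfinite(se):
        raise GLMMError("degenerate fit: se(beta1) is zero or non-finite")
    t = fit.beta1 / se
    if df_policy == "design":
        df = residual_df(fit.n_obs, fit.n_fixed, 1)
    else:
        df = int(df_policy)
    if dist == "t":
        p = t_pvalue(t, df)
    elif dist == "z":
        p = float(2.0 * stats.norm.sf(abs(t)))
    else:
        raise ValueError("dist must be 't' or 'z'")
    return TestResult(statistic=float(t), df=float(df), p_value=p,
                      estimate=float(fit.beta1), stderr=float(se), kind=dist)


def conditional_fitted(fit: GLMMFit, data: GLMMData) -> np.ndarray:
    """Fitted probabilities at fixed effects + conditional modes."""
    eta = fit.beta0 + fit.beta1 * data.x + fit.conditional_modes[data.group]
    if fit.olre_modes is not None:
        eta = eta + fit.olre_modes
    return special.expit(eta)


def deviance_residuals(k: np.ndarray, m: np.ndarray, p: np.ndarray) -> np.ndarray:
    # xlogy(0, 0) = 0 handles the saturated boundary (k = 0 or k = m) exactly
    term = (special.xlogy(k, k) - special.xlogy(k, m * p)
            + special.xlogy(m - k, m - k) - special.xlogy(m - k, m * (1.0 - p)))
    term = np.maximum(term, 0.0)  # guard tiny negative round-off
    return np.sign(k - m * p) * np.sqrt(2.0 * term)


def pearson_residuals(k: np.ndarray, m: np.ndarray, p: np.ndarray) -> np.ndarray:
    return (k - m * p) / np.sqrt(m * p * (1.0 - p))


def dispersion_ratio(deviance: float, df: int) -> float:
    """Dispersion parameter: residual deviance (or χ²) over residual df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return deviance / df


def dispersion(fit: GLMMFit, data: GLMMData,
               df_policy: object = "design") -> DispersionReport:
    """Deviance- and Pearson-based dispersion at the conditional fit."""
    p = conditional_fitted(fit, data)
    D = float((deviance_residuals(data.k, data.m, p) ** 2).sum())
    chi2 = float((pearson_residuals(data.k, data.m, p) ** 2).sum())
    if df_policy == "design":
        df = residual_df(fit.n_obs, fit.n_fixed, 1)
    else:
        df = int(df_policy)
    return DispersionReport(
        residual_deviance=D, pearson_chi2=chi2, residual_df=df,
        dispersion_deviance=dispersion_ratio(D, df),
        dispersion_pearson=dispersion_ratio(chi2, df),
    )
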