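"""Stage 2: stochastic-frontier regression of input slacks on the environment.

For each input, the total slack s_i of observation i is modelled as

    s_i = z_i' beta + v_i + u_i,   v_i ~ N(0, sigma_v^2),  u_i ~ N+(0, sigma_u^2),

a cost-frontier-style composed error: symmetric statistical noise v plus a
one-sided managerial-inefficiency term u (half-normal).  Estimation is maximum
likelihood in the Battese-Corra parameterization sigma^2 = sigma_u^2 +
sigma_v^2, gamma = sigma_u^2 / sigma^2.  The composed residual is split with
the Jondrow-Lovell-Materov-Schmidt (JLMS) conditional mean

    E[u | eps] = sigma_* * ( phi(a) / Phi(a) + a ),
    a = eps * lam / sigma,   lam = sigma_u / sigma_v,
    sigma_* = sigma * lam / (1 + lam^2) = sigma_u * sigma_v / sigma,

and the environmental-harmonisation adjustment raises every observation's
input to the level implied by the least favourable environment and the worst
luck in the sample:

    x*_i = x_i + [max_k(z_k' beta) - z_i' beta] + [max_k(v_k) - v_i].

The observation attaining both maxima keeps its original input; all others
can only increase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .panel_io import DMUPanel

logger = logging.getLogger("tsdea")

_GAMMA_BOUND = 16.0          # logit-scale bound: gamma in (1.1e-7, 1 - 1.1e-7)
_BOUNDARY_GAMMA = 1e-4

# Kodde-Palm 5% critical value of the one-degree mixed chi-square
# (1/2 chi2_0 + 1/2 chi2_1) used by the one-sided LR test of gamma = 0.
MIXED_CHISQ_1DF_5PCT = 2.706


class SFAError(RuntimeError):
    pass


class SFADegenerateError(SFAError):
    """The slack data carry (numerically) no error component to decompose."""


@dataclass
class SFAFit:
    """Half-normal stochastic-frontier fit for one input's slack equation."""

    input_index: int
    beta: np.ndarray           # raw-scale coefficients, intercept first
    sigma_sq: float            # sigma_u^2 + sigma_v^2
    gamma: float               # sigma_u^2 / sigma^2, in [0, 1]
    log_likelihood: float
    lr_one_sided: float        # 2 (logL_full - logL_OLS), clipped at 0
    converged: bool
    n_obs: int = 0
    beta_se: np.ndarray | None = None   # asymptotic, raw scale; None if the
                                        # Hessian is not invertible
    sigma_sq_se: float | None = None    # delta method from log sigma^2
    gamma_se: float | None = None       # delta method from logit gamma

    @property
    def sigma_u_sq(self) -> float:
        return self.gamma * self.sigma_sq

    @property
    def sigma_v_sq(self) -> float:
        return (1.0 - self.gamma) * self.sigma_sq

    @property
    def lam(self) -> float:
        """sigma_u / sigma_v (the SFA lambda, not a DEA intensity weight)."""
        if self.gamma >= 1.0:
            return np.inf
        return float(np.sqrt(self.gamma / (1.0 - self.gamma)))


@dataclass
class ErrorDecomposition:
    """JLMS split of the composed residual, one entry per observation."""

    residual: np.ndarray   # eps = slack - z beta
    u_hat: np.ndarray      # E[u | eps] >= 0
    v_hat: np.ndarray      # eps - u_hat
    env_effect: np.ndarray  # z beta (fitted environmental contribution)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _inv_mills(a):
    """phi(a)/Phi(a) without cancellation.

    For a < 0 this uses the scaled complementary error function
    (Phi(a) = 0.5 exp(-a^2/2) erfcx(-a/sqrt 2)), which stays accurate to
    machine precision arbitrarily deep in the tail; the naive
    exp(log phi - log Phi) loses ~a^2 ulps there.
    """
    a = np.asarray(a, float)
    neg = a < 0
    out = np.empty_like(a)
    out[neg] = np.sqrt(2.0 / np.pi) / special.erfcx(-a[neg] / np.sqrt(2.0))
    an = a[~neg]
    out[~neg] = np.exp(-0.5 * an ** 2 - 0.5 * np.log(2.0 * np.pi)) \
        / special.ndtr(an)
    return out


def _composed_loglik(params, y, Zd):
    """Log-likelihood and gradient in internal coordinates.

    ``params`` = (beta on the design scale, log sigma^2, logit gamma);
    ``Zd`` includes the intercept column.
    """
    k = Zd.shape[1]
    beta = params[:k]
    lsig2 = params[k]
    g = params[k + 1]
    sigma2 = np.exp(lsig2)
    sigma = np.sqrt(sigma2)
    gamma = special.expit(g)
    lam = np.sqrt(gamma / (1.0 - gamma))
    eps = y - Zd @ beta
    a = eps * lam / sigma
    log_phi = special.log_ndtr(a)
    ll = (np.log(2.0) - 0.5 * np.log(2.0 * np.pi) - 0.5 * lsig2
          - eps ** 2 / (2.0 * sigma2) + log_phi)
    mills = _inv_mills(a)
    dll_deps = -eps / sigma2 + mills * lam / sigma
    grad_beta = -Zd.T @ dll_deps
    grad_lsig2 = np.sum(-0.5 + eps ** 2 / (2.0 * sigma2) - 0.5 * mills * a)
    # d lam / d g = lam / 2 and a is linear in lam, hence da/dg = a/2
    grad_g = np.sum(0.5 * mills * a)
    grad = np.concatenate([grad_beta, [grad_lsig2, grad_g]])
    return float(np.sum(ll)), grad


def _neg_loglik(params, y, Zd):
    ll, grad = _composed_loglik(params, y, Zd)
    return -ll, -grad


def _ols_fit(y, Zd):
    """Closed-form normal-regression MLE: beta, sigma2_mle, loglik."""
    beta, *_ = np.linalg.lstsq(Zd, y, rcond=None)
    resid = y - Zd @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return beta, sigma2, np.inf
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return beta, sigma2, ll


def fit_sfa(
    slacks: np.ndarray,
    Z: np.ndarray,
    input_index: int = 0,
    compute_se: bool = True,
) -> SFAFit:
    """Fit the half-normal frontier ``slack = z beta + v + u`` by ML.

    ``Z`` holds the raw environmental covariates (no intercept column); they
    are z-scored internally for optimizer stability and the coefficients are
    reported back on the raw scale.  Several starts are tried (the OLS start,
    a moment-based start from the OLS residual skewness, and a small gamma
    grid); the best converged optimum wins.  A boundary estimate (gamma near
    0 or 1) is reported with a warning, not an error.
    """
    y = np.asarray(slacks, float).ravel()
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != len(y):
        raise ValueError("slacks and Z have mismatched observation counts")
    n, p = Z.shape
    if n < p + 3:
        raise SFAError(f"need at least {p + 3} observations, got {n}")

    mu_z = Z.mean(axis=0)
    sd_z = Z.std(axis=0)
    if np.any(sd_z == 0):
        raise SFAError("a zero-variance environmental covariate cannot be fit")
    Zs = (Z - mu_z) / sd_z
    Zd = np.column_stack([np.ones(n), Zs])
    k = Zd.shape[1]

    beta_ols, sig2_ols, ll_ols = _ols_fit(y, Zd)
    if sig2_ols <= 1e-12 * max(1.0, float(np.mean(y ** 2))):
        raise SFADegenerateError(
            "slack is (numerically) an exact linear function of the "
            "environment; the composed-error likelihood is degenerate"
        )

    starts = []
    # moment start: the half-normal third central moment is
    # sqrt(2/pi) (4/pi - 1) su^3 > 0 (positive skew on the cost side)
    resid = y - Zd @ beta_ols
    m3 = float(np.mean(resid ** 3))
    if m3 > 0:
        su = (m3 / (np.sqrt(2.0 / np.pi) * (4.0 / np.pi - 1.0))) ** (1.0 / 3.0)
        sv2 = max(sig2_ols - (1.0 - 2.0 / np.pi) * su ** 2, 0.05 * sig2_ols)
        g_mom = su ** 2 / (su ** 2 + sv2)
        starts.append((np.clip(g_mom, 0.05, 0.95), su ** 2 + sv2))
    for g0 in (0.05, 0.5, 0.9):
        starts.append((g0, sig2_ols / max(1e-12, 1.0 - (1.0 - 2.0 / np.pi) * g0)))

    bounds = [(None, None)] * k + [(None, None), (-_GAMMA_BOUND, _GAMMA_BOUND)]
    best = None
    traces = []
    for g0, s20 in starts:
        b0 = beta_ols.copy()
        # OLS intercept absorbs E[u] = sigma_u sqrt(2/pi); shift it back
        b0[0] -= np.sqrt(2.0 / np.pi) * np.sqrt(g0 * s20)
        x0 = np.concatenate([b0, [np.log(s20), special.logit(g0)]])
        res = optimize.minimize(_neg_loglik, x0, args=(y, Zd), jac=True,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
        traces.append(f"start gamma={g0:.3f}: status={res.status} "
                      f"ll={-res.fun:.4f} msg={res.message}")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise SFAError("all optimizer starts failed:\n" + "\n".join(traces))

    if -best.fun <= ll_ols:
        # the boundary MLE at gamma = 0 is exactly the OLS solution; return it
        # rather than a stalled interior point on the flat likelihood shelf
        warnings.warn(
            "gamma estimate at boundary (0): the slack regression carries no "
            "detectable one-sided component", stacklevel=2)
        beta_raw = np.empty(k)
        beta_raw[1:] = beta_ols[1:] / sd_z
        beta_raw[0] = beta_ols[0] - float(np.sum(beta_ols[1:] * mu_z / sd_z))
        beta_se = None
        if compute_se:
            cov = sig2_ols * n / max(n - k, 1) * np.linalg.inv(Zd.T @ Zd)
            se_std = np.sqrt(np.diag(cov))
            beta_se = np.empty(k)
            beta_se[1:] = se_std[1:] / sd_z
            beta_se[0] = se_std[0]
        return SFAFit(input_index=input_index, beta=beta_raw,
                      sigma_sq=sig2_ols, gamma=0.0,
                      log_likelihood=float(ll_ols), lr_one_sided=0.0,
                      converged=True, n_obs=n, beta_se=beta_se)

    # convergence is judged by likelihood dominance over the OLS null; an
    # "abnormal" line-search exit at a gamma boundary still yields a usable
    # boundary optimum and is downgraded to a warning
    converged = bool(np.isfinite(best.fun)) and -best.fun >= ll_ols - 1e-5
    if converged and not best.success:
        warnings.warn(
            f"optimizer stopped at a boundary ({best.message}); estimates "
            "retained as the best likelihood found", stacklevel=2)
    params = best.x
    ll_full = -best.fun
    sigma_sq = float(np.exp(params[k]))
    gamma = float(special.expit(params[k + 1]))
    if gamma < _BOUNDARY_GAMMA or gamma > 1.0 - _BOUNDARY_GAMMA:
        warnings.warn(
            f"gamma estimate at boundary ({gamma:.2e}); the inefficiency "
            "share is weakly identified on these slacks", stacklevel=2)

    # coefficients back on the raw covariate scale
    beta_std = params[:k]
    beta_raw = np.empty(k)
    beta_raw[1:] = beta_std[1:] / sd_z
    beta_raw[0] = beta_std[0] - float(np.sum(beta_std[1:] * mu_z / sd_z))

    beta_se = sigma_sq_se = gamma_se = None
    if compute_se:
        ses = _raw_param_se(params, y, Zd, sd_z)
        if ses is not None:
            beta_se, se_lsig2, se_g = ses
            sigma_sq_se = sigma_sq * se_lsig2
            gamma_se = gamma * (1.0 - gamma) * se_g

    lr = max(0.0, 2.0 * (ll_full - ll_ols))
    return SFAFit(
        input_index=input_index,
        beta=beta_raw,
        sigma_sq=sigma_sq,
        gamma=gamma,
        log_likelihood=float(ll_full),
        lr_one_sided=float(lr),
        converged=converged,
        n_obs=n,
        beta_se=beta_se,
        sigma_sq_se=sigma_sq_se,
        gamma_se=gamma_se,
    )


def _raw_param_se(params, y, Zd, sd_z):
    """Asymptotic SEs via a central-difference Hessian of the log-likelihood.

    Returns (raw-scale beta SEs, SE of log sigma^2, SE of logit gamma) or
    None when the Hessian is not positive definite.
    """
    k = Zd.shape[1]

    def grad(p):
        return _neg_loglik(p, y, Zd)[1]

    h = 1e-5 * np.maximum(1.0, np.abs(params))
    dim = len(params)
    H = np.zeros((dim, dim))
    for j in range(dim):
        step = np.zeros(dim)
        step[j] = h[j]
        H[:, j] = (grad(params + step) - grad(params - step)) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return None
    se = np.sqrt(var)
    se_raw = np.empty(k)
    se_raw[1:] = se[1:k] / sd_z
    # the raw intercept mixes all design coefficients; report the design-scale
    # intercept SE as an approximation (stars only, no inferential claim)
    se_raw[0] = se[0]
    return se_raw, float(se[k]), float(se[k + 1])


# ---------------------------------------------------------------------------
# JLMS decomposition
# ---------------------------------------------------------------------------

def jlms_conditional_mean(epsilon, sigma: float, lam: float) -> np.ndarray:
    """Conditional mean E[u | v + u = epsilon] for the half-normal model.

    Stable for strongly negative residuals: the Mills ratio phi/Phi is
    evaluated through ``erfcx`` so the result decays smoothly toward the
    asymptote sigma_*^2 / |mu_*| instead of underflowing to a 0/0.
    """
    if sigma <= 0 or lam <= 0:
        raise ValueError("sigma and lam must be strictly positive")
    eps = np.asarray(epsilon, float)
    a = eps * lam / sigma
    sigma_star = sigma * lam / (1.0 + lam ** 2)
    out = sigma_star * (_inv_mills(a) + a)
    return out if out.ndim else float(out)


def decompose_errors(fit: SFAFit, slacks, Z) -> ErrorDecomposition:
    """Split each slack into fitted environment, inefficiency and noise."""
    if not fit.converged:
        raise SFAError("refusing to decompose a non-converged fit")
    y = np.asarray(slacks, float).ravel()
    Z = np.atleast_2d(np.asarray(Z, float))
    zb = fit.beta[0] + Z @ fit.beta[1:]
    eps = y - zb
    if fit.gamma <= _BOUNDARY_GAMMA:
        warnings.warn("gamma ~ 0: treating the whole residual as noise",
                      stacklevel=2)
        u_hat = np.zeros_like(eps)
    else:
        sigma = float(np.sqrt(fit.sigma_sq))
        u_hat = jlms_conditional_mean(eps, sigma, fit.lam)
    return ErrorDecomposition(residual=eps, u_hat=u_hat, v_hat=eps - u_hat,
                              env_effect=zb)


# ---------------------------------------------------------------------------
# input adjustment
# ---------------------------------------------------------------------------

def adjust_inputs(
    panel: DMUPanel,
    fits: list[SFAFit],
    decomps: list[ErrorDecomposition],
) -> DMUPanel:
    """Harmonise environments: raise inputs to the worst-environment,
    worst-luck level, one fit/decomposition per input, maxima taken over the
    pooled estimation sample.  Outputs and environment are copied unchanged.
    """
    X = panel.inputs
    n_inputs = X.shape[1]
    if len(fits) != n_inputs or len(decomps) != n_inputs:
        raise ValueError(
            f"need one fit and decomposition per input ({n_inputs}), got "
            f"{len(fits)} fits / {len(decomps)} decompositions")
    adjusted = X.copy()
    for idx, (fit, dec) in enumerate(zip(fits, decomps)):
        if len(dec.v_hat) != panel.n_obs:
            raise ValueError(
                f"decomposition for input {idx} covers {len(dec.v_hat)} "
                f"observations, panel has {panel.n_obs}")
        env_gap = np.max(dec.env_effect) - dec.env_effect
        luck_gap = np.max(dec.v_hat) - dec.v_hat
        adjusted[:, idx] = X[:, idx] + env_gap + luck_gap
    if np.any(adjusted < X - 1e-9):
        raise SFAError("adjustment decreased an input; internal error")
    return panel.with_inputs(adjusted)
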