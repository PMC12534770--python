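"""Three-mediator path analysis with BCa bootstrap inference.

The model is the recursive linear system

    M_k = alpha_k + a_k * x + e_k,        k = 1, 2, 3
    Y   = alpha_Y + c' * x + sum_k b_k * M_k + e_Y

with the (1,2) and (1,3) mediator residual covariances free and the (2,3)
covariance fixed at zero.  The indirect effect through mediator k is
a_k * b_k and the total effect is c = c' + sum_k a_k * b_k, an identity of
the point estimates.

Estimation is equation-wise least squares with moment-based residual
(co)variances (denominator n).  For a recursive path model of this form the
least-squares coefficients coincide with the maximum-likelihood path
solution, so no iterative optimizer is needed; fit indices evaluate the ML
discrepancy function at these estimates.  With 15 observed moments of the
five variables and 14 free parameters (3 a's, c' and 3 b's, var(x), 3
mediator residual variances, 2 residual covariances, 1 outcome residual
variance) the model has one degree of freedom: the (2,3) mediator
covariance constraint.

Inference is a case-resampling bootstrap: whole rows are resampled, the
model refit per replicate, and each effect gets a bootstrap SE plus a
bias-corrected and accelerated (BCa) confidence interval.  The bias
correction z0 is the normal quantile of the fraction of replicates below
the point estimate; the acceleration constant comes from the skewness of
leave-one-out jackknife values, computed here with the exact closed-form
leave-one-out update for least squares rather than n refits.  Two-sided
p-values invert the interval: the smallest level at which the BCa interval
excludes zero, searched on a grid of step 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "PathModelSpec",
    "PathEstimates",
    "EffectEstimate",
    "MediationFit",
    "EstimationError",
    "fit_paths",
    "implied_covariance",
    "fit_indices",
    "bootstrap_effects",
    "bca_interval",
    "bias_correction",
    "acceleration",
]

EFFECT_NAMES = (
    "a1", "a2", "a3", "b1", "b2", "b3", "c_prime",
    "indirect_1", "indirect_2", "indirect_3", "total",
)

#: free parameters of this specification (see module docstring)
N_FREE_PARAMS = 14


class EstimationError(ValueError):
    pass


@dataclass
class PathModelSpec:
    exposure: str = "extreme_hot"
    mediators: tuple[str, str, str] = ("affiliation", "analytic", "somatosensory")
    outcome: str = "ewb"
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.mediators)) != 3:
            raise ValueError("mediators must be three distinct names")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PathEstimates:
    a: np.ndarray            # exposure -> mediator
    b: np.ndarray            # mediator -> outcome
    c_prime: float
    mediator_intercepts: np.ndarray
    y_intercept: float
    psi: np.ndarray          # 3x3 mediator residual covariance, psi[1,2] == 0
    theta_y: float           # outcome residual variance
    var_x: float             # sample variance of the exposure (denominator n)
    n: int

    @property
    def indirect(self) -> np.ndarray:
        return self.a * self.b

    @property
    def total(self) -> float:
        return float(self.c_prime + self.indirect.sum())

    def effects(self) -> dict[str, float]:
        ind = self.indirect
        return {
            "a1": self.a[0], "a2": self.a[1], "a3": self.a[2],
            "b1": self.b[0], "b2": self.b[1], "b3": self.b[2],
            "c_prime": self.c_prime,
            "indirect_1": ind[0], "indirect_2": ind[1], "indirect_3": ind[2],
            "total": self.total,
        }


@dataclass
class EffectEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class MediationFit:
    effects: dict[str, EffectEstimate]
    estimates: PathEstimates
    fit: dict[str, float]
    n_used: int
    n_boot: int
    ci_level: float
    seed: int
    n_degenerate_redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": name,
                    "estimate": e.estimate,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                }
                for name, e in self.effects.items()
            ]
        )


def _solve_ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Coefficients of Y on X via the normal equations (X small and well
    conditioned here; callers guard the singular case)."""
    G = X.T @ X
    try:
        return np.linalg.solve(G, X.T @ Y)
    except np.linalg.LinAlgError as err:
        raise EstimationError(f"singular design: {err}") from err


def _fit_arrays(x: np.ndarray, M: np.ndarray, y: np.ndarray) -> PathEstimates:
    n = x.size
    if np.ptp(x) == 0:
        raise EstimationError("constant exposure: path model not identified")
    X1 = np.column_stack([np.ones(n), x])
    A = _solve_ols(X1, M)                       # 2 x 3
    X2 = np.column_stack([X1, M])
    beta = _solve_ols(X2, y)                    # 5
    resid_m = M - X1 @ A
    resid_y = y - X2 @ beta
    psi = resid_m.T @ resid_m / n
    psi[1, 2] = psi[2, 1] = 0.0                 # fixed by specification
    return PathEstimates(
        a=A[1].copy(),
        b=beta[2:5].copy(),
        c_prime=float(beta[1]),
        mediator_intercepts=A[0].copy(),
        y_intercept=float(beta[0]),
        psi=psi,
        theta_y=float(resid_y @ resid_y / n),
        var_x=float(x.var()),
        n=n,
    )


def _model_arrays(rows: pd.DataFrame, spec: PathModelSpec):
    cols = [spec.exposure, *spec.mediators, spec.outcome]
    data = rows[cols].dropna()
    n = len(data)
    if n <= 20:
        raise EstimationError(f"need n > 20 complete cases, got {n}")
    x = data[spec.exposure].to_numpy(float)
    M = data[list(spec.mediators)].to_numpy(float)
    y = data[spec.outcome].to_numpy(float)
    return x, M, y


def fit_paths(rows: pd.DataFrame, spec: PathModelSpec) -> PathEstimates:
    """Point estimates of all paths and residual (co)variances."""
    return _fit_arrays(*_model_arrays(rows, spec))


def implied_covariance(est: PathEstimates) -> np.ndarray:
    """Model-implied 5x5 covariance in the order (x, m1, m2, m3, y)."""
    sx = est.var_x
    a, b, cp = est.a, est.b, est.c_prime
    S = np.zeros((5, 5))
    S[0, 0] = sx
    S[0, 1:4] = S[1:4, 0] = a * sx
    S[1:4, 1:4] = np.outer(a, a) * sx + est.psi
    w = np.concatenate([[cp], b])               # y on (x, m1, m2, m3)
    S[0:4, 4] = S[4, 0:4] = S[0:4, 0:4] @ w
    S[4, 4] = w @ S[0:4, 0:4] @ w + est.theta_y
    return S


def _logdet_pd(mat: np.ndarray, name: str) -> float:
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise EstimationError(f"{name} matrix is not positive definite")
    return logdet


def fit_indices(
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    n: int,
    q_free: int = N_FREE_PARAMS,
) -> dict[str, float]:
    """ML-discrepancy chi-square, df, CFI, GFI, RMSEA.

    The baseline (independence) model is the diagonal of the sample
    covariance.  Covariances carry denominator n; the chi-square multiplier
    is n - 1, the conventional pairing.
    """
    S = np.asarray(sample_cov, float)
    Sigma = np.asarray(implied_cov, float)
    p = S.shape[0]
    logdet_S = _logdet_pd(S, "sample covariance")
    logdet_Sig = _logdet_pd(Sigma, "implied covariance")
    F = logdet_Sig - logdet_S + float(np.trace(S @ np.linalg.inv(Sigma))) - p
    F = max(F, 0.0)
    chi2 = (n - 1) * F
    df = p * (p + 1) // 2 - q_free
    Sigma_b = np.diag(np.diag(S))
    F_b = float(np.log(np.diag(S)).sum()) - logdet_S + float(
        np.trace(S @ np.linalg.inv(Sigma_b))
    ) - p
    chi2_b = (n - 1) * max(F_b, 0.0)
    df_b = p * (p + 1) // 2 - p
    eps = np.finfo(float).tiny
    excess = max(chi2 - df, 0.0)
    cfi = 1.0 - excess / max(chi2_b - df_b, chi2 - df, eps)
    rmsea = np.sqrt(excess / (df * (n - 1))) if df > 0 else float("nan")
    Sig_inv_S = np.linalg.inv(Sigma) @ S
    resid = Sig_inv_S - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(Sig_inv_S @ Sig_inv_S)
    return {
        "chi_square": float(chi2),
        "df": int(df),
        "chi_square_baseline": float(chi2_b),
        "df_baseline": int(df_b),
        "cfi": float(min(cfi, 1.0)),
        "gfi": float(gfi),
        "rmsea": float(rmsea),
    }


def bias_correction(theta_star: np.ndarray, theta_hat: float) -> float:
    """z0 = Phi^-1 of the fraction of replicates below the point estimate,
    clamped away from 0 and 1."""
    B = theta_star.size
    prop = np.count_nonzero(theta_star < theta_hat) / B
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    return float(ndtri(prop))


def acceleration(loo_values: np.ndarray) -> float:
    """Jackknife acceleration: skewness of leave-one-out estimates."""
    d = loo_values.mean() - loo_values
    denom = 6.0 * (d @ d) ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / denom)


def _bca_quantile_levels(z0: float, ahat: float, q) -> np.ndarray:
    z = ndtri(np.asarray(q, float))
    adj = z0 + (z0 + z) / (1.0 - ahat * (z0 + z))
    return ndtr(adj)


def bca_interval(
    theta_star: np.ndarray, z0: float, ahat: float, level: float = 0.95
) -> tuple[float, float]:
    """BCa interval endpoints from bootstrap replicates.

    With z0 = 0 and ahat = 0 this reduces exactly to the percentile
    interval.  Quantiles use the linear-interpolation convention.
    """
    alpha = 1.0 - level
    q = _bca_quantile_levels(z0, ahat, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo, hi = np.quantile(theta_star, q, method="linear")
    return float(lo), float(hi)


def _bca_p(theta_star: np.ndarray, z0: float, ahat: float, step: float = 1e-4) -> float:
    """Smallest two-sided level at which the BCa interval excludes zero."""
    alphas = np.arange(step, 1.0, step)
    q_lo = _bca_quantile_levels(z0, ahat, alphas / 2.0)
    q_hi = _bca_quantile_levels(z0, ahat, 1.0 - alphas / 2.0)
    sorted_ts = np.sort(theta_star)
    lo = np.quantile(sorted_ts, q_lo, method="linear")
    hi = np.quantile(sorted_ts, q_hi, method="linear")
    excludes = (lo > 0.0) | (hi < 0.0)
    if not excludes.any():
        return 1.0
    return float(alphas[int(np.argmax(excludes))])


def _loo_coefs(X: np.ndarray, Y: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Exact leave-one-out OLS coefficients via the hat-matrix downdate.

    Returns an array of shape (n, p[, k]) with row i the coefficients of the
    fit excluding observation i.
    """
    G_inv = np.linalg.inv(X.T @ X)
    U = X @ G_inv                         # n x p
    h = np.einsum("ij,ij->i", U, X)
    resid = Y - X @ coefs                 # n [x k]
    scale = resid / (1.0 - h)[:, None] if resid.ndim == 2 else resid / (1.0 - h)
    if resid.ndim == 2:
        return coefs[None, :, :] - U[:, :, None] * scale[:, None, :]
    return coefs[None, :] - U * scale[:, None]


def _jackknife_effects(x: np.ndarray, M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out values of all 11 effects, shape (n, 11)."""
    n = x.size
    X1 = np.column_stack([np.ones(n), x])
    A = _solve_ols(X1, M)
    X2 = np.column_stack([X1, M])
    beta = _solve_ols(X2, y)
    loo_A = _loo_coefs(X1, M, A)          # n x 2 x 3
    loo_beta = _loo_coefs(X2, y, beta)    # n x 5
    a = loo_A[:, 1, :]                    # n x 3
    b = loo_beta[:, 2:5]
    cp = loo_beta[:, 1]
    ind = a * b
    total = cp + ind.sum(axis=1)
    return np.column_stack([a, b, cp, ind, total])


def bootstrap_effects(rows: pd.DataFrame, spec: PathModelSpec) -> MediationFit:
    """Case-resampling bootstrap of the full path model.

    Whole rows are resampled with replacement ``n_boot`` times and the model
    refit per replicate.  A replicate with a constant exposure cannot be fit
    and is redrawn (counted); more than 10% redraws aborts.  Reproducible
    given ``spec.seed``.
    """
    x, M, y = _model_arrays(rows, spec)
    n = x.size
    est = _fit_arrays(x, M, y)
    point = est.effects()
    rng = np.random.default_rng(spec.seed)
    B = spec.n_boot
    theta = np.empty((B, len(EFFECT_NAMES)))
    redraws = 0
    max_redraws = max(1, int(0.1 * B))
    for bidx in range(B):
        while True:
            idx = rng.integers(0, n, n)
            xb = x[idx]
            if np.ptp(xb) > 0:
                break
            redraws += 1
            if redraws > max_redraws:
                raise EstimationError(
                    f"more than 10% of bootstrap resamples ({redraws}) had a "
                    "constant exposure; sample too small or exposure too rare"
                )
        eb = _fit_arrays(xb, M[idx], y[idx])
        e = eb.effects()
        theta[bidx] = [e[k] for k in EFFECT_NAMES]
    loo = _jackknife_effects(x, M, y)
    effects: dict[str, EffectEstimate] = {}
    for j, name in enumerate(EFFECT_NAMES):
        ts = theta[:, j]
        z0 = bias_correction(ts, point[name])
        ahat = acceleration(loo[:, j])
        lo, hi = bca_interval(ts, z0, ahat, spec.ci_level)
        effects[name] = EffectEstimate(
            estimate=float(point[name]),
            se=float(ts.std(ddof=1)),
            ci_low=lo,
            ci_high=hi,
            p=_bca_p(ts, z0, ahat),
        )
    order = [spec.exposure, *spec.mediators, spec.outcome]
    data = rows[order].dropna().to_numpy(float)
    S = np.cov(data, rowvar=False, bias=True)
    fit = fit_indices(S, implied_covariance(est), n)
    return MediationFit(
        effects=effects,
        estimates=est,
        fit=fit,
        n_used=n,
        n_boot=B,
        ci_level=spec.ci_level,
        seed=spec.seed,
        n_degenerate_redraws=redraws,
    )
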