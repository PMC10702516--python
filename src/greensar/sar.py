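"""Maximum-likelihood spatial lag and spatial error regression.

The spatial lag model (SLM)

    y = rho * W y + X beta + eps,      eps ~ N(0, sigma2 I)

and the spatial error model (SEM)

    y = X beta + u,   u = lambda * W u + eps

are estimated by maximizing the log-likelihood concentrated in the spatial
coefficient: for each candidate rho (or lambda) the regression coefficients
and error variance have closed-form profiles, leaving a one-dimensional
bounded search over (-0.999, 0.999).  The Jacobian term log|I - rho W| is
computed exactly, either from the (complex) eigenvalues of W — precomputed
once and reused across evaluations — or by sparse LU factorization per
evaluation.  Standard errors come from the negative inverse Hessian of the
full log-likelihood, differentiated numerically at the optimum.

Spillover total effects beta1/(1 - rho) and percentage-difference-per-IQR
effect estimates (with delta-method / transformed CIs) are provided for
reporting associations the way environmental-epidemiology studies do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import optimize, stats

from greensar.weights import SpatialWeightMatrix

RHO_BOUNDS = (-0.999, 0.999)

# above this dimension a per-evaluation sparse LU beats a one-off dense
# eigendecomposition, unless the same W is reused across many fits
DENSE_EIG_MAX_N = 1500


class LogDeterminant:
    """Evaluator of log|I - rho W| for a fixed sparse W.

    mode "eig" precomputes the eigenvalues of W (dense, O(n^3) once, then
    O(n) per evaluation); mode "lu" factorizes I - rho W per call.  "auto"
    chooses eig for n <= 1500.  For a row-standardized W the determinant is
    positive throughout (-1, 1), so the magnitude is the determinant.
    """

    def __init__(self, W: sp.spmatrix, mode: str = "auto"):
        self.W = W.tocsc()
        n = W.shape[0]
        if mode == "auto":
            mode = "eig" if n <= DENSE_EIG_MAX_N else "lu"
        self.mode = mode
        self._eigs = None
        if mode == "eig":
            self._eigs = np.linalg.eigvals(W.toarray())
        self._I = sp.identity(n, format="csc")

    def __call__(self, rho: float) -> float:
        if self._eigs is not None:
            return float(np.log(np.abs(1.0 - rho * self._eigs)).sum())
        lu = spla.splu(self._I - rho * self.W)
        logdet = np.log(np.abs(lu.U.diagonal())).sum()
        return float(logdet)


@dataclass
class SARFit:
    """A fitted spatial lag or spatial error model.

    ``covariance`` is the joint covariance of (spatial coefficient,
    beta_0..beta_{p-1}, sigma2) in that order, on the original covariate
    scale.
    """

    model: str                     # "SLM" or "SEM"
    rho_or_lambda: float
    beta: np.ndarray
    sigma2: float
    loglik: float
    covariance: np.ndarray
    residuals: np.ndarray
    converged: bool
    n: int
    param_names: list = field(default_factory=list)
    message: str = ""

    @property
    def rho(self) -> float:
        return self.rho_or_lambda

    @property
    def se_spatial(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    def se_beta(self, j: int) -> float:
        return float(np.sqrt(self.covariance[1 + j, 1 + j]))

    def beta_ci(self, j: int, alpha: float = 0.05):
        zq = stats.norm.ppf(1 - alpha / 2)
        se = self.se_beta(j)
        return self.beta[j] - zq * se, self.beta[j] + zq * se

    def beta_pvalue(self, j: int) -> float:
        z = self.beta[j] / self.se_beta(j)
        return float(2 * stats.norm.sf(abs(z)))


def _prepare_design(X: np.ndarray):
    """Standardize non-intercept columns; return (Xs, means, sds, icol).

    Internal conditioning only — estimates and covariances are mapped back
    to the original covariate scale before being reported.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    const = [j for j in range(p) if np.ptp(X[:, j]) == 0]
    if len(const) != 1 or X[0, const[0]] == 0:
        raise ValueError("X must contain exactly one intercept (constant nonzero) column")
    icol = const[0]
    if np.linalg.matrix_rank(X) < p:
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(R).max())
        raise ValueError(f"X is rank deficient; collinear column indices: {bad.tolist()}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    means[icol], sds[icol] = 0.0, X[0, icol]  # intercept passes through unscaled
    Xs = (X - means) / sds
    Xs[:, icol] = 1.0
    return Xs, means, sds, icol


def _beta_backmap(means: np.ndarray, sds: np.ndarray, icol: int) -> np.ndarray:
    """Linear map A with beta_original = A @ beta_standardized."""
    p = means.size
    A = np.diag(1.0 / sds)
    # intercept absorbs the centering of every other column
    A[icol, :] = -means / sds
    A[icol, icol] = 1.0
    return A


def _numeric_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of scalar f at theta."""
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _covariance_from_hessian(negloglik, theta_hat, A_beta, message_sink):
    """Invert the numerical Hessian; map the beta block to original scale."""
    H = _numeric_hessian(negloglik, theta_hat)
    H = 0.5 * (H + H.T)
    try:
        cov_std = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        message_sink.append("Hessian singular; covariance unavailable")
        return np.full((theta_hat.size, theta_hat.size), np.nan), False
    k = theta_hat.size
    J = np.eye(k)
    J[1:k - 1, 1:k - 1] = A_beta
    cov = J @ cov_std @ J.T
    cov = 0.5 * (cov + cov.T)
    ok = bool(np.all(np.diag(cov)[:-1] > 0))
    if not ok:
        message_sink.append("non-positive variance from Hessian inversion")
    return cov, ok


def concentrated_loglik_slm(rho: float, y, Wy, Xs, logdet: LogDeterminant):
    """Profile log-likelihood of the SLM at rho (beta, sigma2 profiled out)."""
    n = y.size
    Ay = y - rho * Wy
    beta, *_ = np.linalg.lstsq(Xs, Ay, rcond=None)
    e = Ay - Xs @ beta
    sigma2 = float(e @ e) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet(rho)
    return ll, beta, sigma2, e


def fit_slm(y, X, swm: SpatialWeightMatrix, logdet: LogDeterminant | None = None,
            rho_bounds=RHO_BOUNDS, compute_se: bool = True) -> SARFit:
    """ML estimation of the spatial lag model y = rho W y + X beta + eps.

    Parameters
    ----------
    y : array
        Response (pollutant, typically log-concentration).
    X : array (n, p)
        Design matrix including an intercept column.
    swm : SpatialWeightMatrix
        Row-standardized weights.
    logdet : LogDeterminant, optional
        Precomputed log-determinant evaluator; pass one when fitting many
        models with the same W to amortize the eigendecomposition.
    """
    y = np.asarray(y, float)
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    swm.require_standardized()
    W = swm.W
    Xs, means, sds, icol = _prepare_design(X)
    n, p = Xs.shape
    if logdet is None:
        logdet = LogDeterminant(W)
    Wy = W @ y

    def neg_conc(rho):
        return -concentrated_loglik_slm(rho, y, Wy, Xs, logdet)[0]

    res = optimize.minimize_scalar(neg_conc, bounds=rho_bounds, method="bounded",
                                   options={"xatol": 1e-9})
    rho_hat = float(res.x)
    messages = []
    converged = bool(res.success)
    if not converged:
        messages.append(f"optimizer: {res.message}")
    if abs(rho_hat) > rho_bounds[1] - 1e-4:
        messages.append("rho estimate at search boundary")
        warnings.warn("spatial coefficient at the boundary of the search interval",
                      stacklevel=2)

    ll, beta_std, sigma2, e = concentrated_loglik_slm(rho_hat, y, Wy, Xs, logdet)
    A = _beta_backmap(means, sds, icol)
    beta = A @ beta_std

    cov = np.full((p + 2, p + 2), np.nan)
    if compute_se:
        def negloglik(theta):
            rho, b, s2 = theta[0], theta[1:1 + p], theta[-1]
            if s2 <= 0 or abs(rho) >= 1:
                return np.inf
            r = (y - rho * Wy) - Xs @ b
            return (0.5 * n * np.log(2 * np.pi * s2) - logdet(rho)
                    + 0.5 * float(r @ r) / s2)

        theta_hat = np.concatenate([[rho_hat], beta_std, [sigma2]])
        cov, ok = _covariance_from_hessian(negloglik, theta_hat, A, messages)
        converged = converged and ok

    names = ["rho"] + [f"beta{j}" for j in range(p)] + ["sigma2"]
    return SARFit(model="SLM", rho_or_lambda=rho_hat, beta=beta, sigma2=sigma2,
                  loglik=ll, covariance=cov, residuals=e, converged=converged,
                  n=n, param_names=names, message="; ".join(messages))


def concentrated_loglik_sem(lam: float, y, Wy, Xs, WXs, logdet: LogDeterminant):
    """Profile log-likelihood of the SEM at lambda (spatially filtered GLS)."""
    n = y.size
    yf = y - lam * Wy
    Xf = Xs - lam * WXs
    beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    e = yf - Xf @ beta
    sigma2 = float(e @ e) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet(lam)
    return ll, beta, sigma2, e


def fit_sem(y, X, swm: SpatialWeightMatrix, logdet: LogDeterminant | None = None,
            rho_bounds=RHO_BOUNDS, compute_se: bool = True) -> SARFit:
    """ML estimation of the spatial error model y = X beta + u, u = lambda W u + eps."""
    y = np.asarray(y, float)
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    swm.require_standardized()
    W = swm.W
    Xs, means, sds, icol = _prepare_design(X)
    n, p = Xs.shape
    if logdet is None:
        logdet = LogDeterminant(W)
    Wy = W @ y
    WXs = W @ Xs

    def neg_conc(lam):
        return -concentrated_loglik_sem(lam, y, Wy, Xs, WXs, logdet)[0]

    res = optimize.minimize_scalar(neg_conc, bounds=rho_bounds, method="bounded",
                                   options={"xatol": 1e-9})
    lam_hat = float(res.x)
    messages = []
    converged = bool(res.success)
    if not converged:
        messages.append(f"optimizer: {res.message}")
    if abs(lam_hat) > rho_bounds[1] - 1e-4:
        messages.append("lambda estimate at search boundary")
        warnings.warn("spatial coefficient at the boundary of the search interval",
                      stacklevel=2)

    ll, beta_std, sigma2, e = concentrated_loglik_sem(lam_hat, y, Wy, Xs, WXs, logdet)
    A = _beta_backmap(means, sds, icol)
    beta = A @ beta_std

    cov = np.full((p + 2, p + 2), np.nan)
    if compute_se:
        def negloglik(theta):
            lam, b, s2 = theta[0], theta[1:1 + p], theta[-1]
            if s2 <= 0 or abs(lam) >= 1:
                return np.inf
            r = (y - lam * Wy) - (Xs - lam * WXs) @ b
            return (0.5 * n * np.log(2 * np.pi * s2) - logdet(lam)
                    + 0.5 * float(r @ r) / s2)

        theta_hat = np.concatenate([[lam_hat], beta_std, [sigma2]])
        cov, ok = _covariance_from_hessian(negloglik, theta_hat, A, messages)
        converged = converged and ok

    names = ["lambda"] + [f"beta{j}" for j in range(p)] + ["sigma2"]
    # SEM residuals reported on the original (unfiltered) scale: u = y - X beta
    u = y - Xs @ beta_std
    return SARFit(model="SEM", rho_or_lambda=lam_hat, beta=beta, sigma2=sigma2,
                  loglik=ll, covariance=cov, residuals=u, converged=converged,
                  n=n, param_names=names, message="; ".join(messages))


@dataclass
class ModelSelection:
    """Outcome of residual-autocorrelation model choice between SLM and SEM."""

    choice: str
    moran_slm: "MoranResult"
    moran_sem: "MoranResult"
    rationale: str

    @property
    def selected(self):
        return self.choice


def select_model(slm: SARFit, sem: SARFit, swm: SpatialWeightMatrix,
                 alpha: float = 0.05) -> ModelSelection:
    """Choose SLM vs SEM by Moran's I of the model residuals.

    The model whose residual autocorrelation is non-significant (analytic
    p > alpha) wins; if both or neither qualify the smaller |z| wins, with
    exact ties broken toward the SLM.
    """
    from greensar.diagnostics import morans_i

    if not (slm.converged and sem.converged):
        bad = [f.model for f in (slm, sem) if not f.converged]
        raise RuntimeError(f"model selection aborted: unconverged fit(s) {bad}; "
                           f"messages: {[f.message for f in (slm, sem)]}")
    m_slm = morans_i(slm.residuals, swm, n_perm=0)
    m_sem = morans_i(sem.residuals, swm, n_perm=0)
    ok_slm = m_slm.p_analytic > alpha
    ok_sem = m_sem.p_analytic > alpha
    if ok_slm and not ok_sem:
        choice, why = "SLM", f"only SLM residuals pass (p={m_slm.p_analytic:.3g})"
    elif ok_sem and not ok_slm:
        choice, why = "SEM", f"only SEM residuals pass (p={m_sem.p_analytic:.3g})"
    else:
        if abs(m_slm.z) <= abs(m_sem.z):
            choice, why = "SLM", (f"both or neither pass; smaller |z| "
                                  f"({abs(m_slm.z):.3g} <= {abs(m_sem.z):.3g})")
        else:
            choice, why = "SEM", (f"both or neither pass; smaller |z| "
                                  f"({abs(m_sem.z):.3g} < {abs(m_slm.z):.3g})")
    return ModelSelection(choice=choice, moran_slm=m_slm, moran_sem=m_sem,
                          rationale=why)


@dataclass
class TotalEffect:
    """Spillover total effect beta1/(1 - rho) with a delta-method CI."""

    value: float
    se: float
    ci_low: float
    ci_high: float


def total_effect(fit: SARFit, beta_index: int = 1, alpha: float = 0.05) -> TotalEffect:
    """Total (direct + spillover) effect of covariate ``beta_index`` in an SLM.

    T_ef = beta1 / (1 - rho); its variance follows from the delta method
    applied to the joint covariance of (rho, beta1).
    """
    if fit.model != "SLM":
        raise ValueError("total effect is defined for the spatial lag model")
    rho = fit.rho_or_lambda
    if rho >= 1 - 1e-6:
        raise ValueError("total effect undefined: rho at or above 1")
    b1 = fit.beta[beta_index]
    T = b1 / (1.0 - rho)
    # gradient wrt (rho, beta1)
    g = np.array([b1 / (1.0 - rho) ** 2, 1.0 / (1.0 - rho)])
    idx = [0, 1 + beta_index]
    subcov = fit.covariance[np.ix_(idx, idx)]
    var = float(g @ subcov @ g)
    se = float(np.sqrt(var)) if var >= 0 else np.nan
    zq = stats.norm.ppf(1 - alpha / 2)
    return TotalEffect(value=float(T), se=se, ci_low=float(T - zq * se),
                       ci_high=float(T + zq * se))


@dataclass
class EffectEstimate:
    """Percentage difference in pollution per IQR increase in greenspace."""

    pollutant: str
    metric: str
    scale: str
    beta1: float
    se_beta1: float
    iqr: float
    pct_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    rho: float
    total_effect: float
    total_ci_low: float
    total_ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.pct_diff <= self.ci_high or
                np.isnan(self.ci_low) or np.isnan(self.ci_high)):
            raise ValueError("CI must bracket the point estimate")


def pct_per_iqr(fit: SARFit, iqr: float, beta_index: int = 1,
                use_total: bool = False, alpha: float = 0.05,
                scale: str = "log", ybar: float | None = None,
                pollutant: str = "", metric: str = "",
                scale_label: str = "") -> EffectEstimate:
    """Effect estimate expressed as % difference in pollution per IQR of greenspace.

    With the pollutant modeled on the natural-log scale (the default), a
    coefficient b gives pct = 100 * (exp(b * IQR) - 1) exactly, and the CI
    is the same monotone transform of b's Wald interval.  ``use_total``
    reports the spillover total effect beta1/(1-rho) instead of the direct
    coefficient.  ``scale="linear"`` gives the level-scale alternative
    pct = 100 * b * IQR / ybar.
    """
    if iqr <= 0:
        raise ValueError("iqr must be positive")
    if use_total:
        te = total_effect(fit, beta_index=beta_index, alpha=alpha)
        b, se = te.value, te.se
    else:
        b = float(fit.beta[beta_index])
        se = fit.se_beta(beta_index)
    zq = stats.norm.ppf(1 - alpha / 2)
    lo, hi = b - zq * se, b + zq * se
    if scale == "log":
        transform = lambda v: 100.0 * np.expm1(v * iqr)
    elif scale == "linear":
        if ybar is None or ybar == 0:
            raise ValueError("linear-scale percentages need a nonzero ybar")
        transform = lambda v: 100.0 * v * iqr / ybar
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    pct, ci_l, ci_h = transform(b), transform(lo), transform(hi)
    p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan

    te = total_effect(fit, beta_index=beta_index, alpha=alpha)
    return EffectEstimate(
        pollutant=pollutant, metric=metric, scale=scale_label,
        beta1=float(fit.beta[beta_index]), se_beta1=fit.se_beta(beta_index),
        iqr=float(iqr), pct_diff=float(pct), ci_low=float(ci_l),
        ci_high=float(ci_h), p_value=p, rho=float(fit.rho_or_lambda),
        total_effect=te.value, total_ci_low=te.ci_low, total_ci_high=te.ci_high,
    )
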