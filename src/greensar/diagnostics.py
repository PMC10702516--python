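"""Spatial autocorrelation and model-choice diagnostics.

Moran's I with analytic (randomization or normality assumption) and
permutation inference; the four Lagrange-multiplier score tests that
discriminate lag- from error-type spatial dependence in OLS residuals;
and multivariate outlier screening (z-score, Mahalanobis distance,
skewness/kurtosis report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from greensar.weights import SpatialWeightMatrix


@dataclass
class MoranResult:
    """Global Moran's I and its inference.

    ``interpretation`` applies the descriptive rule sometimes used in the
    applied literature (|I| > 0.3 read as strong autocorrelation); it is a
    label only — significance is judged from the p-values.
    """

    I: float
    expectation: float
    variance: float
    z: float
    p_analytic: float
    p_perm: float | None
    n_perm: int
    interpretation: str

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.p_perm if self.p_perm is not None else self.p_analytic
        return p < alpha


def _moran_statistic(z: np.ndarray, W: sp.spmatrix, s0: float) -> float:
    n = z.size
    return (n / s0) * float(z @ (W @ z)) / float(z @ z)


def morans_i(y, swm: SpatialWeightMatrix, n_perm: int = 999,
             assumption: str = "randomization", seed: int = 0) -> MoranResult:
    """Moran's I of y under the weight matrix, with analytic and permutation p.

    I = (n/S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2.

    Analytic moments use the randomization assumption by default (robust to
    non-Gaussian y); ``assumption="normality"`` is also available.  The
    permutation p-value comes from ``n_perm`` random relabelings with a fixed
    seed; pass ``n_perm=0`` to skip it.
    """
    y = np.asarray(y, float)
    W = swm.W
    n = y.size
    if W.shape[0] != n:
        raise ValueError("dimension mismatch between y and W")
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    z = y - y.mean()
    if np.allclose(z, 0):
        raise ValueError("y is constant; Moran's I is undefined")

    s0 = float(W.sum())
    I = _moran_statistic(z, W, s0)

    # Standard small-sample moments (Cliff & Ord).
    Wd = W
    S1 = 0.5 * float(((Wd + Wd.T).power(2)).sum())
    r = np.asarray(Wd.sum(axis=1)).ravel() + np.asarray(Wd.sum(axis=0)).ravel()
    S2 = float((r ** 2).sum())
    EI = -1.0 / (n - 1)
    if assumption == "randomization":
        b2 = n * float((z ** 4).sum()) / float((z ** 2).sum()) ** 2
        num = (n * ((n ** 2 - 3 * n + 3) * S1 - n * S2 + 3 * s0 ** 2)
               - b2 * ((n ** 2 - n) * S1 - 2 * n * S2 + 6 * s0 ** 2))
        den = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
        VI = num / den - EI ** 2
    elif assumption == "normality":
        VI = (n ** 2 * S1 - n * S2 + 3 * s0 ** 2) / (s0 ** 2 * (n ** 2 - 1)) - EI ** 2
    else:
        raise ValueError("assumption must be 'randomization' or 'normality'")

    zscore = (I - EI) / np.sqrt(VI)
    p_analytic = 2.0 * stats.norm.sf(abs(zscore))
    p_analytic = float(min(max(p_analytic, np.finfo(float).tiny), 1.0))

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        zz = float(z @ z)
        for _ in range(n_perm):
            zp = rng.permutation(z)
            Ip = (n / s0) * float(zp @ (W @ zp)) / zz
            if abs(Ip - EI) >= abs(I - EI):
                count += 1
        p_perm = (count + 1) / (n_perm + 1)

    if I > 0.3:
        label = "positive"
    elif I < -0.3:
        label = "negative"
    else:
        label = "weak"
    return MoranResult(I=I, expectation=EI, variance=VI, z=zscore,
                       p_analytic=p_analytic, p_perm=p_perm, n_perm=n_perm,
                       interpretation=label)


@dataclass
class LMTestResult:
    """Lagrange-multiplier diagnostics for spatial lag vs error dependence.

    All four statistics are asymptotically chi-square(1) under the null of
    no spatial dependence; the robust variants correct each test for local
    misspecification of the other alternative.
    """

    lm_lag: float
    lm_error: float
    rlm_lag: float
    rlm_error: float
    p_lm_lag: float
    p_lm_error: float
    p_rlm_lag: float
    p_rlm_error: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "lm_lag": self.lm_lag, "p_lm_lag": self.p_lm_lag,
            "lm_error": self.lm_error, "p_lm_error": self.p_lm_error,
            "rlm_lag": self.rlm_lag, "p_rlm_lag": self.p_rlm_lag,
            "rlm_error": self.rlm_error, "p_rlm_error": self.p_rlm_error,
        })


def lm_tests(y, X, swm: SpatialWeightMatrix) -> LMTestResult:
    """Anselin-form LM and robust-LM score tests from OLS residuals.

    With e the OLS residuals, sigma2 = e'e/n, T = tr(W'W + WW) and
    J = [(WXb)' M (WXb) + T sigma2] / sigma2 (M the OLS annihilator):

        LM_lag   = (e'Wy / sigma2)^2 / J
        LM_error = (e'We / sigma2)^2 / T
        RLM_lag  = (d_lag - d_err)^2 / (J - T)
        RLM_err  = (d_err - (T/J) d_lag)^2 / (T - T^2/J)
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the caller
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(R).max())
        raise ValueError(f"X is rank deficient; collinear column indices: {bad.tolist()}")
    W = swm.W

    import statsmodels.api as sm

    ols = sm.OLS(y, X).fit()
    e = ols.resid
    b = ols.params
    sigma2 = float(e @ e) / n

    T = float((W.T @ W).diagonal().sum() + (W @ W).diagonal().sum())
    d_lag = float(e @ (W @ y)) / sigma2
    d_err = float(e @ (W @ e)) / sigma2

    WXb = W @ (X @ b)
    # M WXb = residual of WXb on X
    M_WXb = WXb - X @ np.linalg.lstsq(X, WXb, rcond=None)[0]
    J = (float(WXb @ M_WXb) + T * sigma2) / sigma2

    lm_lag_stat = d_lag ** 2 / J
    lm_err_stat = d_err ** 2 / T
    rlm_lag_stat = (d_lag - d_err) ** 2 / (J - T) if J > T else 0.0
    rlm_err_stat = (d_err - (T / J) * d_lag) ** 2 / (T - T ** 2 / J) if J > T else 0.0

    chi2 = stats.chi2(df=1)
    return LMTestResult(
        lm_lag=lm_lag_stat, lm_error=lm_err_stat,
        rlm_lag=rlm_lag_stat, rlm_error=rlm_err_stat,
        p_lm_lag=float(chi2.sf(lm_lag_stat)), p_lm_error=float(chi2.sf(lm_err_stat)),
        p_rlm_lag=float(chi2.sf(rlm_lag_stat)), p_rlm_error=float(chi2.sf(rlm_err_stat)),
    )


@dataclass
class OutlierReport:
    """Per-row screening flags and per-variable distribution shape."""

    zscores: pd.DataFrame
    mahalanobis_sq: np.ndarray
    flagged: np.ndarray           # boolean per row
    flag_z: np.ndarray
    flag_maha: np.ndarray
    skewness: pd.Series
    excess_kurtosis: pd.Series
    z_thresh: float
    maha_quantile: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def screen_outliers(table: pd.DataFrame, columns=None, z_thresh: float = 3.0,
                    maha_quantile: float = 0.975):
    """Flag multivariate outliers; return (OutlierReport, filtered table).

    A row is flagged when any column z-score exceeds ``z_thresh`` in absolute
    value or its squared Mahalanobis distance exceeds the chi-square(p)
    quantile ``maha_quantile``.  Skewness and excess kurtosis per variable
    are reported but never used to transform the data.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    V = table[cols].to_numpy(float)
    n, p = V.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} rows for {p} columns")
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant column(s) {const}; remove before screening")
    Z = (V - mu) / sd
    cov = np.atleast_2d(np.cov(V, rowvar=False))
    if np.linalg.cond(cov) > 1e12:
        raise ValueError("singular covariance matrix; consider removing a "
                         "collinear variable")
    cov_inv = np.linalg.inv(cov)
    diff = V - mu
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    flag_z = (np.abs(Z) > z_thresh).any(axis=1)
    cutoff = stats.chi2(df=p).ppf(maha_quantile)
    flag_maha = d2 > cutoff
    flagged = flag_z | flag_maha

    report = OutlierReport(
        zscores=pd.DataFrame(Z, columns=cols, index=table.index),
        mahalanobis_sq=d2, flagged=flagged, flag_z=flag_z, flag_maha=flag_maha,
        skewness=pd.Series(stats.skew(V, axis=0), index=cols),
        excess_kurtosis=pd.Series(stats.kurtosis(V, axis=0), index=cols),
        z_thresh=z_thresh, maha_quantile=maha_quantile,
    )
    return report, table.loc[~flagged]
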