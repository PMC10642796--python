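"""Simple (single-mediator) mediation with percentile-bootstrap inference.

The model is the classic three-regression decomposition (PROCESS Model 4):

    M = i1 + a*X
    Y = i2 + c*X                 (total effect)
    Y = i3 + c'*X + b*M          (direct effect and mediator path)

The indirect effect is a*b, and on any single OLS-fitted sample the identity
c = c' + a*b holds exactly.  Significance of the indirect effect comes from a
nonparametric bootstrap over subjects: a*b is recomputed on each resample and
the effect is called significant when zero falls outside the percentile
confidence interval.

In the connectome pipeline X is the social-rejection score, M the summed FC
over the consensus negative prediction network, and Y the rumination score.
Variables are z-scored before fitting by default, so paths are standardized
coefficients; raw-scale fitting is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["MediationResult", "fit_mediation", "bootstrap_indirect"]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int
    standardized: bool
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    level: float | None = None
    significant: bool | None = None
    ci_method: str | None = None


def _validate_xyz(x, m, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be 1-D arrays of equal length")
    if x.size < 10:
        raise ValueError(f"need at least 10 subjects, got {x.size}")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.var(v) == 0.0:
            raise ValueError(f"{name} has zero variance")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} contains non-finite values")
    return x, m, y


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and two-tailed p of y ~ 1 + x."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return slope, 0.0 if slope != 0.0 else 1.0
    t = slope / se
    return slope, float(2.0 * stats.t.sf(abs(t), df))


def _bivariate_ols(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Coefficients (c', b) and their p values for y ~ 1 + x + m.

    When x and m are perfectly collinear the direct and mediator paths are
    not separately identified; by convention the shared effect is attributed
    entirely to the mediator (c' = 0, b from y ~ 1 + m), so a perfect chain
    x -> m -> y yields b = 1, c' = 0 on standardized data.
    """
    n = x.size
    xc, mc, yc = x - x.mean(), m - m.mean(), y - y.mean()
    sxx, smm, sxm = float(xc @ xc), float(mc @ mc), float(xc @ mc)
    sxy, smy = float(xc @ yc), float(mc @ yc)
    det = sxx * smm - sxm**2
    if det <= 1e-12 * sxx * smm:
        b, p_b = _simple_ols(m, y)
        return 0.0, b, 1.0, p_b
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    resid = yc - c_prime * xc - b * mc
    df = n - 3
    sigma2 = float(resid @ resid) / df
    var_cp = sigma2 * smm / det
    var_b = sigma2 * sxx / det
    ps = []
    for coef, var in ((c_prime, var_cp), (b, var_b)):
        if var <= 0.0:
            ps.append(0.0 if coef != 0.0 else 1.0)
        else:
            ps.append(float(2.0 * stats.t.sf(abs(coef) / np.sqrt(var), df)))
    return c_prime, b, ps[0], ps[1]


def fit_mediation(x, m, y, standardize: bool = True) -> MediationResult:
    """Fit the three mediation regressions and return all paths.

    With ``standardize=True`` (default) x, m and y are z-scored first, so the
    returned paths are standardized coefficients.
    """
    x, m, y = _validate_xyz(x, m, y)
    if standardize:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
    a, p_a = _simple_ols(x, m)
    c, p_c = _simple_ols(x, y)
    c_prime, b, p_cp, p_b = _bivariate_ols(x, m, y)
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
        p_a=p_a, p_b=p_b, p_c=p_c, p_c_prime=p_cp,
        n=x.size, standardized=standardize,
    )


def _indirect_batch(X: np.ndarray, M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Indirect effect a*b per row of (B, n) resample matrices."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    sxm = np.einsum("ij,ij->i", Xc, Mc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    det = sxx * smm - sxm**2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        ab = a * b
    # degenerate resamples (constant x or collinear x,m) carry no information
    return np.where((sxx > 0) & (det > 0), ab, np.nan)


def bootstrap_indirect(
    x,
    m,
    y,
    n_boot: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
    standardize: bool = True,
    method: Literal["percentile", "bca"] = "percentile",
) -> MediationResult:
    """Bootstrap confidence interval for the indirect effect a*b.

    Subjects are resampled with replacement ``n_boot`` times and a*b is
    recomputed on each resample; the CI is the percentile interval at the
    requested level (default 95%, i.e. the 2.5th and 97.5th percentiles).
    The effect is significant when zero lies outside the CI.  A
    bias-corrected-and-accelerated (BCa) variant is available.

    Standardization, when requested, is applied once to the original sample;
    resamples are drawn from the standardized data.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if n_boot < 100:
        import warnings

        warnings.warn(
            f"n_boot={n_boot} is very small for a percentile CI", stacklevel=2
        )
    x, m, y = _validate_xyz(x, m, y)
    result = fit_mediation(x, m, y, standardize=standardize)
    if standardize:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
    n = x.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab = _indirect_batch(x[idx], m[idx], y[idx])
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    if method == "bca":
        lo_q, hi_q = _bca_quantiles(x, m, y, ab, result.indirect, level)
    ci_low, ci_high = np.nanpercentile(ab, [lo_q, hi_q])
    result.ci_low = float(ci_low)
    result.ci_high = float(ci_high)
    result.n_boot = n_boot
    result.level = level
    result.significant = bool(not (ci_low <= 0.0 <= ci_high))
    result.ci_method = method
    return result


def _bca_quantiles(x, m, y, ab_boot, ab_hat, level) -> tuple[float, float]:
    """Adjusted percentile positions for the BCa interval."""
    ab_boot = ab_boot[np.isfinite(ab_boot)]
    prop = np.mean(ab_boot < ab_hat)
    prop = min(max(prop, 1.0 / (ab_boot.size + 1)), 1.0 - 1.0 / (ab_boot.size + 1))
    z0 = stats.norm.ppf(prop)
    n = x.size
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        jack[i] = _indirect_batch(
            x[keep][None, :], m[keep][None, :], y[keep][None, :]
        )[0]
        keep[i] = True
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    accel = 0.0 if den == 0.0 else num / den
    z_lo = stats.norm.ppf((1 - level) / 2)
    z_hi = stats.norm.ppf((1 + level) / 2)
    q = []
    for z in (z_lo, z_hi):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        q.append(100.0 * stats.norm.cdf(adj))
    return q[0], q[1]
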