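"""Curve estimation, rank correlation and two-sample contrasts.

The curve-estimation helper fits the three classical families of the
centrality-response analysis — linear ``y = a*x + b``, exponential
``y = a*exp(b*x)`` and logarithmic ``y = a*ln(x) + b`` — by ordinary
least squares on the appropriately transformed scale (log-transformed
response for the exponential family, log-transformed predictor for the
logarithmic one), reporting R², the regression F statistic with
``(1, n-2)`` degrees of freedom and its p-value.  Rank correlation and
the two-sample contrast wrap the tie-corrected scipy implementations,
with the Mann-Whitney z score computed from the tie-corrected normal
approximation (appropriate at the 10,000-replicate batch sizes used
here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CurveFitResult",
    "curve_estimation",
    "best_family",
    "spearman_rho",
    "mann_whitney",
]

FAMILIES = ("linear", "exponential", "logarithmic")

#: F statistic sentinel for exactly collinear data (R² = 1)
F_CAP = 1e15


@dataclass(frozen=True)
class CurveFitResult:
    """One fitted family with its goodness-of-fit statistics."""

    family: str
    a: float
    b: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "linear":
            return self.a * x + self.b
        if self.family == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a * np.log(x) + self.b

    def equation(self) -> str:
        if self.family == "linear":
            return f"y = {self.a:.6g}x + {self.b:.6g}"
        if self.family == "exponential":
            return f"y = {self.a:.6g}e^({self.b:.6g}x)"
        return f"y = {self.a:.6g}ln(x) + {self.b:.6g}"


def curve_estimation(
    x: Sequence[float], y: Sequence[float], family: str
) -> CurveFitResult:
    """Least-squares fit of one family on its transformed scale.

    R² is computed on the fitted (transformed) scale, as in classical
    curve-estimation procedures, and ``F = R²(n-2)/(1-R²)`` with
    ``df = (1, n-2)``.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"curve estimation needs at least 3 points, got {n}")
    if family == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential family requires all y > 0")
        xt, yt = x, np.log(y)
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic family requires all x > 0")
        xt, yt = np.log(x), y
    else:
        xt, yt = x, y
    if np.ptp(xt) == 0.0:
        raise ValueError("predictor has zero variance on the fitted scale")
    fit = sps.linregress(xt, yt)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        f_stat, p = F_CAP, np.finfo(float).tiny
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p = float(sps.f.sf(f_stat, 1, n - 2))
        p = max(p, np.finfo(float).tiny)
    if family == "linear":
        a, b = float(fit.slope), float(fit.intercept)
    elif family == "exponential":
        a, b = float(np.exp(fit.intercept)), float(fit.slope)
    else:
        a, b = float(fit.slope), float(fit.intercept)
    return CurveFitResult(
        family=family,
        a=a,
        b=b,
        r_squared=r2,
        f_stat=float(f_stat),
        df=(1, n - 2),
        p_value=float(min(p, 1.0)),
        n=n,
    )


def best_family(
    x: Sequence[float], y: Sequence[float], families: Sequence[str] = FAMILIES
) -> CurveFitResult:
    """Fit every applicable family and return the one with maximal R²."""
    fits = []
    for fam in families:
        try:
            fits.append(curve_estimation(x, y, fam))
        except ValueError:
            continue  # family not applicable to this data (sign constraints)
    if not fits:
        raise ValueError("no family is applicable to the data")
    return max(fits, key=lambda f: f.r_squared)


def spearman_rho(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined for a constant sequence")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns ``(U, z, p)`` where ``U`` counts, over all cross pairs, how
    often an ``a`` value exceeds a ``b`` value (ties count one half).  The
    z score is negative when ``a``'s ranks are lower than ``b``'s; the
    p-value is two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if sigma2 <= 0.0:  # all values identical
        return u, 0.0, 1.0
    z = (u - mu) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return u, float(z), p
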