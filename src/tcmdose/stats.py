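"""Statistical layer: summaries, R-squared, covariate-adjusted OLS, normal
tolerance intervals via the non-central t distribution, and one-sample
proportion z-tests.

The tolerance interval covers a population fraction ``p`` with confidence
``gamma`` for a normal sample: the one-sided factor is

    k = t'_{gamma, n-1}(delta = z_p * sqrt(n)) / sqrt(n)

where t' is the non-central t quantile, and the reported two-limit interval
is (mean - k*sd, mean + k*sd).  The proportion test uses the plain normal
approximation z = (k/n - p0) / sqrt(p0 (1-p0) / n) without continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ToleranceInterval",
    "RegressionResult",
    "summarize",
    "r_squared",
    "fit_linear_model",
    "tolerance_interval",
    "proportion_test",
    "count_outside",
]

SIGNIFICANCE_LEVEL = 0.05
TRENDING_LEVEL = 0.10


@dataclass(frozen=True)
class ToleranceInterval:
    sample_mean: float
    sample_sd: float
    n: int
    coverage: float
    confidence: float
    k_factor: float
    lower: float
    upper: float


@dataclass(frozen=True)
class RegressionResult:
    names: tuple
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    r_squared: float


def summarize(values) -> tuple:
    """(mean, median, sample SD) of a sample; SD uses the n-1 denominator."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return float(x.mean()), float(np.median(x)), float(x.std(ddof=1))


def r_squared(x, y) -> float:
    """Squared Pearson correlation (coefficient of determination)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def fit_linear_model(response, scanner_indicator, dw) -> RegressionResult:
    """OLS of a dose contrast on a scanner indicator and patient size.

    The intercept's p-value is the covariate-adjusted test of the mean
    contrast differing from zero.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    design = np.column_stack([np.asarray(scanner_indicator, float), np.asarray(dw, float)])
    x = sm.add_constant(design)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, x).fit()
    return RegressionResult(
        names=("intercept", "scanner", "dw"),
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        t_statistics=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
    )


def tolerance_k(n: int, p: float = 0.90, gamma: float = 0.95) -> float:
    """One-sided normal tolerance factor via the non-central t quantile."""
    if not 0.0 < p < 1.0 or not 0.0 < gamma < 1.0:
        raise ValueError("coverage and confidence must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    delta = sps.norm.ppf(p) * np.sqrt(n)
    return float(sps.nct.ppf(gamma, df=n - 1, nc=delta) / np.sqrt(n))


def tolerance_interval(sample, p: float = 0.90, gamma: float = 0.95) -> ToleranceInterval:
    """Normal tolerance interval covering fraction ``p`` of the population
    with confidence ``gamma`` (one-sided k factors on both sides)."""
    x = np.asarray(sample, float)
    mean, _, sd = (float(x.mean()), None, float(x.std(ddof=1)))
    k = tolerance_k(x.size, p, gamma)
    return ToleranceInterval(
        sample_mean=mean,
        sample_sd=sd,
        n=int(x.size),
        coverage=p,
        confidence=gamma,
        k_factor=k,
        lower=mean - k * sd,
        upper=mean + k * sd,
    )


def proportion_test(k_successes: int, n: int, p0: float = 0.5) -> tuple:
    """One-sample proportion z-test (normal approximation, no continuity
    correction).  Returns (z, two-sided p)."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k_successes <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    z = (k_successes / n - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * (1.0 - sps.norm.cdf(abs(z)))
    return float(z), float(p)


def count_outside(deltas, interval, convention: str = "magnitude") -> tuple:
    """(n_within, n_outside) of values relative to (lower, upper).

    ``magnitude`` classifies |delta| against the interval (the interval
    bounds the expected reproducibility magnitude); ``signed`` classifies the
    signed value.
    """
    lower, upper = interval
    if lower > upper:
        raise ValueError("lower must not exceed upper")
    x = np.asarray(deltas, float)
    if convention == "magnitude":
        x = np.abs(x)
    elif convention != "signed":
        raise ValueError("convention must be 'magnitude' or 'signed'")
    within = int(np.sum((x >= lower) & (x <= upper)))
    return within, int(x.size) - within
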