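"""Accuracy, precision and combined agreement statistics for paired observed/simulated data.

All statistics use population moments (divide by n). That is the only
convention under which the mean-square-prediction-error partition

    MSPE = (mean_s - mean_o)^2 + sd_s^2 (1 - b)^2 + (1 - r^2) sd_o^2,
    b = cov / sd_s^2,

is an exact identity, so the three components always sum to 100% of MSPE.
Sample-convention (divide by n-1) moments are available for cross-checks via
``moments(..., ddof=1)`` but are not used by the evaluators.

Sign convention: mean bias is 100 * (mean_s - mean_o) / mean_o, so a model
that underestimates reports a negative bias.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .dataset import PairedSeries
from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "Moments",
    "MetricSet",
    "moments",
    "mean_so_ratio",
    "mean_bias_pct",
    "regression_fit",
    "model_efficiency",
    "mspe_partition",
    "concordance",
    "ccc_from_components",
    "evaluate",
]


@dataclass(frozen=True)
class Moments:
    """First and second moments of a paired series (population convention by default)."""

    n: int
    mean_o: float
    mean_s: float
    sd_o: float
    sd_s: float
    cov_os: float
    r: float


@dataclass
class MetricSet:
    """One full evaluation column: every accuracy/precision/combined descriptor."""

    n: int
    msor: float
    slope: float
    slope_se: float
    mb_pct: float
    cv_so_pct: float
    r2: float
    me: float
    mspe: float
    bias_pct: float
    slope_pct: float
    random_pct: float
    ccc: float
    ca: float
    r: float
    p_bias: float
    p_slope_vs_1: float
    p_slope_vs_0: float
    perfect_fit: bool = False
    mode: str = "moment"

    def to_dict(self) -> dict:
        return asdict(self)


def moments(p: PairedSeries, ddof: int = 0) -> Moments:
    """Means, standard deviations, covariance and Pearson correlation.

    ``ddof=0`` (default) gives population moments; ``ddof=1`` the sample
    convention, provided for cross-checking against other software.
    """
    n = len(p)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    o, s = p.o, p.s
    mean_o, mean_s = float(o.mean()), float(s.mean())
    sd_o = float(o.std(ddof=ddof))
    sd_s = float(s.std(ddof=ddof))
    cov_os = float(((o - mean_o) * (s - mean_s)).sum() / (n - ddof))
    if sd_o > 0 and sd_s > 0:
        r = cov_os / (sd_o * sd_s)
        r = float(np.clip(r, -1.0, 1.0))
    else:
        r = float("nan")
    return Moments(n=n, mean_o=mean_o, mean_s=mean_s, sd_o=sd_o, sd_s=sd_s,
                   cov_os=cov_os, r=r)


def mean_so_ratio(p: PairedSeries) -> tuple[float, float]:
    """Mean of elementwise S/O ratios and their coefficient of variation (%).

    CV uses the population SD of the ratios divided by their mean.
    """
    ratios = p.s / p.o
    msor = float(ratios.mean())
    if msor == 0:
        raise DegenerateInputError("mean S/O ratio is zero; CV undefined")
    cv = 100.0 * float(ratios.std(ddof=0)) / msor
    return msor, cv


def mean_bias_pct(p: PairedSeries) -> float:
    """Signed mean bias as % of the observed mean; negative = underestimation."""
    mean_o = float(p.o.mean())
    mean_s = float(p.s.mean())
    if mean_o == 0:
        raise DegenerateInputError("observed mean is zero; mean bias undefined")
    return 100.0 * (mean_s - mean_o) / mean_o


def _two_sided_p(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def _slope_tests(slope: float, se: float, df: int) -> tuple[float, float]:
    """Two-sided t-test p-values for slope=1 and slope=0, robust to se=0."""
    if se == 0.0:
        p1 = 1.0 if abs(slope - 1.0) < 1e-12 else 0.0
        p0 = 1.0 if abs(slope) < 1e-12 else 0.0
        return p1, p0
    return _two_sided_p((slope - 1.0) / se, df), _two_sided_p(slope / se, df)


def _denoise_sse(sse: float, o: np.ndarray) -> float:
    """Treat a residual sum of squares at machine-noise level as an exact fit."""
    return 0.0 if sse <= 1e-24 * float((o**2).sum()) else sse


def regression_fit(
    p: PairedSeries, mode: str = "moment"
) -> tuple[float, float, float, float, float]:
    """Regression of observed on simulated values.

    ``mode='moment'``: ordinary least squares with intercept; the reported
    slope is cov/sd_s^2 and tests use n-2 degrees of freedom.
    ``mode='origin'``: least squares through the origin, slope = sum(O*S)/sum(S^2),
    tests on n-1 degrees of freedom.

    Returns (slope, slope_se, r2, p_slope_vs_1, p_slope_vs_0) where r2 is the
    squared Pearson correlation between O and S.
    """
    n = len(p)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs for regression, got {n}")
    o, s = p.o, p.s
    m = moments(p)
    if mode == "moment":
        if m.sd_s == 0:
            raise DegenerateInputError("simulated series is constant; slope undefined")
        slope = m.cov_os / m.sd_s**2
        intercept = m.mean_o - slope * m.mean_s
        resid = o - (intercept + slope * s)
        df = n - 2
        sse = _denoise_sse(float((resid**2).sum()), o)
        se = float(np.sqrt((sse / df) / (n * m.sd_s**2))) if df > 0 else float("nan")
    elif mode == "origin":
        ss2 = float((s**2).sum())
        if ss2 == 0:
            raise DegenerateInputError("sum of squared simulated values is zero")
        slope = float((o * s).sum() / ss2)
        resid = o - slope * s
        df = n - 1
        sse = _denoise_sse(float((resid**2).sum()), o)
        se = float(np.sqrt((sse / df) / ss2)) if df > 0 else float("nan")
    else:
        raise ValueError(f"mode must be 'moment' or 'origin', got {mode!r}")
    if m.sd_o == 0 or m.sd_s == 0:
        raise DegenerateInputError("zero variance; R^2 undefined")
    r2 = m.r**2
    p1, p0 = _slope_tests(slope, se, df)
    return slope, se, r2, p1, p0


def model_efficiency(p: PairedSeries) -> float:
    """1 - sum((S-O)^2) / sum((O-mean_o)^2); 1 is perfect, negative is worse
    than predicting the observed mean."""
    o, s = p.o, p.s
    ss_o = float(((o - o.mean()) ** 2).sum())
    if ss_o == 0:
        raise DegenerateInputError("observed series is constant; ME undefined")
    return 1.0 - float(((s - o) ** 2).sum()) / ss_o


def mspe_partition(
    p: PairedSeries,
) -> tuple[float, float, float, float, float, bool]:
    """MSPE and its exact partition into overall-bias, slope and random components.

    Returns (mspe, bias_pct, slope_pct, random_pct, p_bias, perfect_fit).
    The three percentages sum to 100 for every non-degenerate input. ``p_bias``
    is the two-sided paired t-test of the mean observed-simulated difference.
    A perfect fit (MSPE = 0) reports percentages (0, 0, 0) with the flag set.
    """
    n = len(p)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    o, s = p.o, p.s
    mspe = float(((s - o) ** 2).mean())
    if mspe == 0.0:
        return 0.0, 0.0, 0.0, 0.0, 1.0, True
    m = moments(p)
    bias_term = (m.mean_s - m.mean_o) ** 2
    if m.sd_s == 0:
        slope_term = 0.0  # b undefined; whole non-bias error is "random"
        random_term = mspe - bias_term
    else:
        b = m.cov_os / m.sd_s**2
        slope_term = m.sd_s**2 * (1.0 - b) ** 2
        random_term = (1.0 - m.r**2) * m.sd_o**2 if m.sd_o > 0 else mspe - bias_term - slope_term
    diff = o - s
    if np.allclose(diff, diff[0]):
        # constant difference: t-test is degenerate unless the constant is 0
        p_bias = 1.0 if diff[0] == 0 else 0.0
    else:
        p_bias = float(stats.ttest_rel(o, s).pvalue)
    scale = 100.0 / mspe
    return (
        mspe,
        bias_term * scale,
        slope_term * scale,
        random_term * scale,
        p_bias,
        False,
    )


def concordance(p: PairedSeries) -> tuple[float, float, float]:
    """Concordance correlation coefficient with its accuracy/precision factors.

    Returns (ccc, ca, r) where ccc = 2*cov / (sd_o^2 + sd_s^2 + (mean_s-mean_o)^2),
    ca = 2*sd_o*sd_s / same denominator, r = Pearson correlation, and
    ccc = ca * r holds to machine precision.
    """
    m = moments(p)
    if m.sd_o == 0 or m.sd_s == 0:
        raise DegenerateInputError("zero variance; concordance undefined")
    denom = m.sd_o**2 + m.sd_s**2 + (m.mean_s - m.mean_o) ** 2
    ccc = 2.0 * m.cov_os / denom
    ca = 2.0 * m.sd_o * m.sd_s / denom
    return ccc, ca, m.r


def ccc_from_components(ca: float, r: float) -> float:
    """Concordance coefficient from its accuracy and precision factors (ccc = ca * r)."""
    if not 0 < ca <= 1:
        raise ValueError(f"accuracy component must be in (0, 1], got {ca}")
    if not -1 <= r <= 1:
        raise ValueError(f"precision component must be in [-1, 1], got {r}")
    return ca * r


def evaluate(p: PairedSeries, mode: str = "moment") -> MetricSet:
    """Compute the full descriptor set for one paired series."""
    n = len(p)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs to evaluate, got {n}")
    msor, cv = mean_so_ratio(p)
    mb = mean_bias_pct(p)
    slope, slope_se, r2, p1, p0 = regression_fit(p, mode=mode)
    me = model_efficiency(p)
    mspe, bias_pct, slope_pct, random_pct, p_bias, perfect = mspe_partition(p)
    ccc, ca, r = concordance(p)
    return MetricSet(
        n=n, msor=msor, slope=slope, slope_se=slope_se, mb_pct=mb, cv_so_pct=cv,
        r2=r2, me=me, mspe=mspe, bias_pct=bias_pct, slope_pct=slope_pct,
        random_pct=random_pct, ccc=ccc, ca=ca, r=r, p_bias=p_bias,
        p_slope_vs_1=p1, p_slope_vs_0=p0, perfect_fit=perfect, mode=mode,
    )
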