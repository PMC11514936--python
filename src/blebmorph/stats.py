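"""Group summaries and inferential procedures for bleb morphometry.

Implements, from their defining formulas, the tests used to compare bleb
propagation between injection-site groups:

* Welch's unequal-variance two-sided t-test, both from raw values and from
  printed summary statistics (n, mean, SEM) — the latter reconstructs a
  published test when only the summaries are available;
* the uncorrected Pearson chi-square test on a 2x2 contingency table
  (away vs. not-away by injection site);
* the D'Agostino–Pearson K² omnibus normality test;
* maximum-likelihood lognormal fitting and lognormal moment matching
  (used to calibrate the synthetic-data generator to published
  mean ± SEM group summaries).

Only tail probabilities come from :mod:`scipy.stats` distributions; the
statistics themselves are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import t as _t_dist

from .geometry import ValidationError, BlebMorphError

__all__ = [
    "GroupSummary",
    "TestResult",
    "ContingencyTable2x2",
    "LognormalParams",
    "UnsupportedSampleSizeError",
    "summarize",
    "welch_t",
    "welch_t_from_summary",
    "student_t_from_summary",
    "pearson_chi2",
    "dagostino_pearson",
    "fit_lognormal",
    "lognormal_from_moments",
]


class UnsupportedSampleSizeError(BlebMorphError):
    """Sample too small (or too degenerate) for the requested statistic."""


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group: mean ± SEM and median ± IQR.

    ``sd``/``sem`` are ``None`` for a single observation.  Percentiles use
    linear interpolation.
    """

    n: int
    mean: float
    sd: float | None
    sem: float | None
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    method: str
    statistic: float
    df: float
    p_value: float
    note: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }
        if self.note:
            d["note"] = self.note
        return d


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts indexed (site: inferior, superior) x (class: away, not_away)."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        flat = [c for row in self.counts for c in row]
        if any(c < 0 or c != int(c) for c in flat):
            raise ValidationError("contingency counts must be non-negative integers")
        if sum(flat) < 1:
            raise ValidationError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal distribution parameters (mu, sigma of log-values)."""

    mu: float
    sigma: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0 or (self.sigma == 0 and not self.degenerate):
            raise ValidationError("sigma must be > 0 (or flagged degenerate)")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def sd(self) -> float:
        s2 = self.sigma**2
        return math.exp(self.mu + 0.5 * s2) * math.sqrt(math.expm1(s2))


def _as_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


def summarize(values: Sequence[float]) -> GroupSummary:
    """Descriptive statistics with the sample (n−1) variance convention."""
    arr = _as_1d(values, "summarize")
    n = arr.size
    mean = float(np.mean(arr))
    if n >= 2:
        sd = float(np.std(arr, ddof=1))
        sem = sd / math.sqrt(n)
    else:
        sd = sem = None
    q25, q50, q75 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return GroupSummary(
        n=n, mean=mean, sd=sd, sem=sem, median=q50, iqr_low=q25, iqr_high=q75
    )


# --- t-tests ---------------------------------------------------------------

def _welch_from_moments(
    n1: int, mean1: float, sq1: float, n2: int, mean2: float, sq2: float
) -> TestResult:
    """Welch test from per-group squared standard errors sq_i = s_i²/n_i."""
    se2 = sq1 + sq2
    if se2 == 0.0:
        if mean1 == mean2:
            return TestResult("welch_t", 0.0, float(n1 + n2 - 2), 1.0,
                              note="zero variance in both groups, equal means")
        return TestResult("welch_t", math.inf if mean1 > mean2 else -math.inf,
                          float(n1 + n2 - 2), 0.0,
                          note="zero variance with unequal means")
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (sq1**2 / (n1 - 1) + sq2**2 / (n2 - 1))
    p = 2.0 * float(_t_dist.sf(abs(t), df))
    return TestResult("welch_t", t, df, min(p, 1.0))


def welch_t(raw_a: Sequence[float], raw_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sided t-test on raw values.

    t = (m̄₁ − m̄₂) / sqrt(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite
    degrees of freedom.  Zero variance in both groups falls back to the
    p = 1 (equal means) / p = 0 (unequal means) convention.
    """
    a = _as_1d(raw_a, "welch_t group a")
    b = _as_1d(raw_b, "welch_t group b")
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t requires n >= 2 per group")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    return _welch_from_moments(
        a.size, float(np.mean(a)), va / a.size,
        b.size, float(np.mean(b)), vb / b.size,
    )


def welch_t_from_summary(
    n1: int, mean1: float, sem1: float,
    n2: int, mean2: float, sem2: float,
) -> TestResult:
    """Welch test reconstructed from printed group summaries (n, mean, SEM).

    Identical formulas to :func:`welch_t` with s_i²/n_i = SEM_i²; feeding
    the summaries of raw groups reproduces :func:`welch_t` exactly.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("summary t-test requires n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValidationError("SEMs must be positive")
    return _welch_from_moments(n1, mean1, sem1**2, n2, mean2, sem2**2)


def student_t_from_summary(
    n1: int, mean1: float, sem1: float,
    n2: int, mean2: float, sem2: float,
) -> TestResult:
    """Pooled-variance Student t-test from summaries (offered as an option)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("summary t-test requires n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValidationError("SEMs must be positive")
    s1sq, s2sq = sem1**2 * n1, sem2**2 * n2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / df
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(_t_dist.sf(abs(t), df))
    return TestResult("student_t", t, float(df), min(p, 1.0))


# --- chi-square ------------------------------------------------------------

def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square test of independence on a 2x2 table.

    χ² = Σ (O − E)² / E with expected counts from the margins, df = 1, no
    continuity correction; two-sided p from the χ²₁ survival function.
    """
    obs = table.as_array()
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValidationError("chi-square undefined: zero row or column margin")
    expected = np.outer(rows, cols) / total
    stat = float(np.sum((obs - expected) ** 2 / expected))
    p = float(_chi2_dist.sf(stat, 1))
    return TestResult("pearson_chi2", stat, 1.0, p)


# --- normality -------------------------------------------------------------

def _skewness_z(g1: float, n: int) -> float:
    # D'Agostino (1970) transformation of sample skewness to normality
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n * n + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    y = y / alpha
    return delta * math.log(y + math.sqrt(y * y + 1.0))


def _kurtosis_z(b2: float, n: int) -> float:
    # Anscombe & Glynn (1983) transformation of sample kurtosis
    e = 3.0 * (n - 1.0) / (n + 1.0)
    var = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    x = (b2 - e) / math.sqrt(var)
    beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7.0) * (n + 9.0))
        * math.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + 8.0 / beta1 * (2.0 / beta1 + math.sqrt(1.0 + 4.0 / beta1**2))
    term = (1.0 - 2.0 / a) / (1.0 + x * math.sqrt(2.0 / (a - 4.0)))
    return (
        (1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(term) ** (1.0 / 3.0), term)
    ) * math.sqrt(4.5 * a)


def dagostino_pearson(values: Sequence[float]) -> TestResult:
    """D'Agostino–Pearson K² omnibus normality test.

    K² = z_skew² + z_kurt² with the standard normalizing transformations of
    sample skewness and kurtosis; p from the χ²₂ survival function.
    Requires n >= 8 and non-zero variance.
    """
    arr = _as_1d(values, "dagostino_pearson")
    n = arr.size
    if n < 8:
        raise UnsupportedSampleSizeError(
            f"D'Agostino-Pearson requires n >= 8, got {n}"
        )
    m = arr.mean()
    dev = arr - m
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        raise UnsupportedSampleSizeError("zero variance: normality test undefined")
    g1 = float(np.mean(dev**3)) / m2**1.5
    b2 = float(np.mean(dev**4)) / m2**2
    z1, z2 = _skewness_z(g1, n), _kurtosis_z(b2, n)
    k2 = z1 * z1 + z2 * z2
    return TestResult("dagostino_pearson", k2, 2.0, float(_chi2_dist.sf(k2, 2)))


# --- lognormal -------------------------------------------------------------

def fit_lognormal(values: Sequence[float]) -> LognormalParams:
    """Maximum-likelihood lognormal fit (mu, sigma of logs, ML divisor n)."""
    arr = _as_1d(values, "fit_lognormal")
    if arr.size < 2:
        raise ValidationError("lognormal fit requires n >= 2")
    if np.any(arr <= 0):
        raise ValidationError("lognormal fit requires strictly positive values")
    logs = np.log(arr)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    return LognormalParams(mu=mu, sigma=sigma, degenerate=(sigma == 0.0))


def lognormal_from_moments(mean: float, sd: float) -> LognormalParams:
    """Lognormal parameters whose distribution has exactly this mean and SD.

    sigma² = ln(1 + sd²/mean²), mu = ln(mean) − sigma²/2.  Used to
    calibrate synthetic A_V distributions to published mean ± SEM·√n
    summaries.
    """
    if mean <= 0 or sd <= 0:
        raise ValidationError("moment matching requires mean > 0 and sd > 0")
    s2 = math.log1p((sd / mean) ** 2)
    return LognormalParams(mu=math.log(mean) - 0.5 * s2, sigma=math.sqrt(s2))
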