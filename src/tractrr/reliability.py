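"""Test–retest reliability statistics: ICC(A,1), SEM, MDC95 and companions.

The reliability model is the two-way ANOVA decomposition of an n-subject by
k-session measurement matrix X.  With subject means m_i, session means m_j and
grand mean m:

    MSR = k * sum_i (m_i - m)^2 / (n - 1)          (between subjects)
    MSC = n * sum_j (m_j - m)^2 / (k - 1)          (between sessions)
    MSE = sum_ij (x_ij - m_i - m_j + m)^2 / ((n-1)(k-1))

The intraclass correlation for absolute agreement, single measurement —
identical for the two-way random and two-way mixed formulations — is

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the McGraw–Wong confidence interval built on a Satterthwaite
approximation for the combined MSC/MSE degrees of freedom, and the
significance test F = MSR/MSE on (n-1, (n-1)(k-1)) df.

Downstream psychometrics follow the standard definitions:

    SEM   = SD_day1 * sqrt(1 - ICC)
    MDC95 = z_0.975 * SEM * sqrt(2)      (z_0.975 = 1.959964)

where SD_day1 is the first-session sample SD (n-1 denominator).  Ratings use
the conventional bands: ICC < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
> 0.9 excellent (intervals closed on the left, so 0.5 -> moderate, 0.75 and
0.9 -> good).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import StatisticsError

logger = logging.getLogger("tractrr.reliability")

RATINGS = ("poor", "moderate", "good", "excellent")


@dataclass
class PairedMeasurements:
    """An n x k subjects-by-sessions matrix for a single metric."""

    values: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatisticsError("values must be a 2D subjects x sessions matrix")
        n, k = self.values.shape
        if n < 2:
            raise StatisticsError("need at least 2 subjects")
        if k < 2:
            raise StatisticsError("need at least 2 sessions (k=1 has no retest)")
        if not np.isfinite(self.values).all():
            raise StatisticsError("missing or non-finite cells are not allowed")


@dataclass
class ReliabilityResult:
    """ICC point estimate with CI/F-test, rating and SEM/MDC in metric units."""

    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    f_p: float
    rating: str
    sem: float = float("nan")
    mdc: float = float("nan")
    confidence: float = 0.95
    sd_day1: float = float("nan")
    msr: float = float("nan")
    msc: float = float("nan")
    mse: float = float("nan")


def anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way single-observation ANOVA mean squares (MSR, MSC, MSE)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    mi = x.mean(axis=1)
    mj = x.mean(axis=0)
    m = x.mean()
    msr = k * np.sum((mi - m) ** 2) / (n - 1)
    msc = n * np.sum((mj - m) ** 2) / (k - 1)
    mse = np.sum((x - mi[:, None] - mj[None, :] + m) ** 2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(
    data, confidence: float = 0.95
) -> ReliabilityResult:
    """ICC(A,1): two-way model, single measurement, absolute agreement.

    ``data`` is a :class:`PairedMeasurements` or a plain n x k array.  Returns
    the point estimate, the McGraw–Wong confidence interval at ``confidence``
    and the F test of MSR against MSE.  SEM/MDC fields are filled by
    :func:`reliability_summary`.
    """
    if not isinstance(data, PairedMeasurements):
        data = PairedMeasurements(values=data)
    if not 0.0 < confidence < 1.0:
        raise StatisticsError("confidence must lie in (0, 1)")
    x = data.values
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom) or np.ptp(x) == 0:
        raise StatisticsError("total variance is zero: ICC undefined")
    icc = (msr - mse) / denom

    # significance test of the subject variance component
    if mse > 0:
        f_stat = msr / mse
        f_p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        f_stat = float("inf")
        f_p = 0.0

    alpha = 1.0 - confidence
    if 1.0 - icc < 1e-12 or mse == 0.0:
        ci_low = ci_high = icc  # degenerate: perfect agreement
    else:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        nu = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, nu)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, nu, n - 1)
        ci_low = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
        ci_low = min(float(ci_low), icc)
        ci_high = max(float(ci_high), icc)
    return ReliabilityResult(
        icc=float(icc),
        ci_low=float(max(ci_low, -1.0)),
        ci_high=float(min(ci_high, 1.0)),
        f_stat=float(f_stat),
        f_p=f_p,
        rating=classify_icc(icc),
        confidence=confidence,
        msr=msr,
        msc=msc,
        mse=mse,
    )


def sem_mdc(sd_day1: float, icc: float, confidence: float = 0.95) -> tuple[float, float]:
    """Standard error of measurement and minimal detectable change.

    SEM = SD_day1 * sqrt(1 - ICC); MDC = z * SEM * sqrt(2) with z the
    two-sided normal quantile for ``confidence`` (1.959964 at 0.95).
    Negative ICC estimates are clamped to 0 with a warning; ICC > 1 is an
    error.
    """
    if not 0.0 < confidence < 1.0:
        raise StatisticsError("confidence must lie in (0, 1)")
    if sd_day1 < 0:
        raise StatisticsError("sd_day1 must be non-negative")
    if icc > 1.0 + 1e-12:
        raise StatisticsError("ICC cannot exceed 1")
    if icc < 0.0:
        warnings.warn(
            f"negative ICC estimate {icc:.3f} clamped to 0 inside SEM",
            stacklevel=2,
        )
        icc = 0.0
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    sem = sd_day1 * np.sqrt(1.0 - min(icc, 1.0))
    mdc = z * sem * np.sqrt(2.0)
    return float(sem), float(mdc)


def classify_icc(icc: float) -> str:
    """Conventional reliability bands (closed on the left)."""
    if not np.isfinite(icc):
        raise StatisticsError("ICC must be finite to be rated")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def reliability_summary(
    data, confidence: float = 0.95
) -> ReliabilityResult:
    """ICC + SEM/MDC computed from the same measurement matrix.

    The SEM uses the first-session (day-1) sample SD, not the pooled SD.
    """
    if not isinstance(data, PairedMeasurements):
        data = PairedMeasurements(values=data)
    res = icc_absolute_agreement(data, confidence=confidence)
    sd1 = float(np.std(data.values[:, 0], ddof=1))
    sem, mdc = sem_mdc(sd1, res.icc, confidence=confidence)
    res.sd_day1 = sd1
    res.sem = sem
    res.mdc = mdc
    return res


# ---------------------------------------------------------------------------
# Hemisphere contrasts
# ---------------------------------------------------------------------------

def fa_ratio(ipsi: float, contra: float) -> float:
    """FA of the lesioned tract normalised by the non-lesioned tract (1 = symmetric)."""
    if contra <= 0:
        raise StatisticsError("contralesional FA must be positive")
    return float(ipsi) / float(contra)


def fa_asymmetry(ipsi: float, contra: float) -> float:
    """(contra - ipsi) / (contra + ipsi); 0 = symmetric tract integrity."""
    s = float(ipsi) + float(contra)
    if s <= 0:
        raise StatisticsError("FA sum must be positive")
    return (float(contra) - float(ipsi)) / s


def paired_t(a, b) -> tuple[float, float, int]:
    """Two-sided paired t test; returns (t, p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise StatisticsError("paired_t needs two equal-length vectors, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            raise StatisticsError("paired t undefined: all differences are zero")
        t = float(np.sign(mean) * np.inf)  # limit of a degenerate difference
        return t, 0.0, n - 1
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), p, n - 1


def correlate_with_behavior(
    metric, behavior, n_approaches: int = 3
) -> dict:
    """Pearson correlation with a multiple-approach-corrected alpha.

    alpha_corrected = 0.05 / n_approaches (0.0167 for three approaches);
    the returned ``significant`` flag is p < alpha_corrected.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatisticsError("correlation needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatisticsError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    alpha = 0.05 / n_approaches
    return {
        "r": float(r),
        "p": float(p),
        "alpha_corrected": alpha,
        "significant": bool(p < alpha),
        "n": int(x.size),
    }
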