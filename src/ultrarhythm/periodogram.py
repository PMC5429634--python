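"""Rhythm detection by Fourier power spectrum and the Enright chi-square periodogram.

Two complementary period-detection tools:

* the one-sided FFT power spectrum, with pointwise significance against an
  exponential (white-noise) null and a log-log spectral-slope estimate
  (``S(f) ~ f**-beta``, with ``beta = 2*alpha - 1`` linking it to the DFA
  exponent);
* the Enright periodogram: fold the series at every trial period ``P`` and
  measure how much variance the column means of the folded block capture,
  normalised so that the statistic ``Q_P`` is chi-square distributed with
  ``P - 1`` degrees of freedom under white noise (the Sokolove-Bushell
  normalisation), followed by the peak-sorting and harmonic-removal rules
  used in circadian work (keep local maxima above 10 % of the global
  maximum, ascending by period, and drop integer multiples of retained
  shorter periods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_timeseries import Actogram

__all__ = [
    "PeriodogramResult",
    "power_spectrum",
    "peak_significance",
    "dominant_period",
    "spectral_slope",
    "enright_periodogram",
    "enright_select_peaks",
]


@dataclass
class PeriodogramResult:
    """Scores per trial period, from either method.

    ``periods_h`` are in hours, ascending in frequency for the Fourier
    method (so descending in period) and ascending in period for Enright.
    ``scores`` are one-sided power ordinates (Fourier, summing to the
    series variance) or ``Q_P`` values (Enright).  ``significant`` is per
    period, None until a significance rule has been applied.
    """

    periods_h: np.ndarray
    scores: np.ndarray
    method: str
    significant: np.ndarray | None = None
    alpha_level: float | None = None
    degenerate: bool = False
    #: Enright only: trial periods in actogram bins.
    period_bins: np.ndarray | None = None
    bin_seconds: float | None = None

    def __post_init__(self) -> None:
        self.periods_h = np.asarray(self.periods_h, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.periods_h.shape != self.scores.shape:
            raise ValueError("periods and scores must align")
        if self.scores.size and self.scores.min() < -1e-12:
            raise ValueError("scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"period_hours": self.periods_h, "score": self.scores}
        )
        if self.significant is not None:
            df["significant"] = self.significant
        return df


# ---------------------------------------------------------------------------
# Fourier

def power_spectrum(series, dt: float) -> PeriodogramResult:
    """One-sided power spectrum of a real (or binary) series.

    The series is mean-subtracted first; ordinates are scaled so that their
    sum equals the series variance (Parseval).  The DC ordinate is dropped.
    A constant series returns an all-zero spectrum flagged ``degenerate``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise ValueError("series too short for a spectrum")
    n = x.size
    x = x - x.mean()
    degenerate = not np.any(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    power = 2.0 * spec / n**2
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist ordinate is not duplicated
    freqs = np.fft.rfftfreq(n, d=dt)
    periods_h = np.empty_like(freqs)
    periods_h[1:] = 1.0 / freqs[1:] / 3600.0
    return PeriodogramResult(
        periods_h=periods_h[1:],
        scores=power[1:],
        method="fourier",
        degenerate=degenerate,
    )


def peak_significance(
    result: PeriodogramResult,
    alpha_level: float = 0.001,
    correction: str | None = None,
) -> PeriodogramResult:
    """Flag spectral ordinates against the white-noise null.

    Under Gaussian white noise the normalised periodogram ordinates are
    exponentially distributed; an ordinate is significant when its
    exponential tail probability falls below ``alpha_level``.  With
    ``correction="sidak"`` the level is tightened to control the
    family-wise error over all frequencies instead of per frequency.
    """
    if result.method != "fourier":
        raise ValueError("peak_significance applies to Fourier results")
    scores = result.scores
    if result.degenerate or scores.sum() == 0:
        result.significant = np.zeros(scores.size, dtype=bool)
        result.alpha_level = alpha_level
        return result
    level = alpha_level
    if correction == "sidak":
        level = 1.0 - (1.0 - alpha_level) ** (1.0 / scores.size)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    norm = scores / scores.mean()
    pvals = np.exp(-norm)
    result.significant = pvals < level
    result.alpha_level = alpha_level
    return result


def dominant_period(result: PeriodogramResult) -> float:
    """Period (hours) of the largest ordinate, refined by parabolic interpolation.

    Interpolates log-power over the three ordinates around the maximum on
    the frequency axis, which recovers tone periods falling between the
    discrete Fourier frequencies of a finite record.
    """
    scores = result.scores
    k = int(np.argmax(scores))
    if result.method != "fourier" or k == 0 or k == scores.size - 1:
        return float(result.periods_h[k])
    freqs = 1.0 / result.periods_h
    with np.errstate(divide="ignore"):
        y = np.log(scores[k - 1 : k + 2] + 1e-300)
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0:
        return float(result.periods_h[k])
    shift = 0.5 * (y[0] - y[2]) / denom
    f = freqs[k] + shift * (freqs[k + 1] - freqs[k])
    return float(1.0 / f)


def spectral_slope(
    result: PeriodogramResult, fit_range: tuple[float, float]
) -> tuple[float, float]:
    """Spectral decay exponent beta over a period range.

    Least-squares slope of ``log S(f)`` vs ``log f`` restricted to periods
    in ``fit_range = (min_hours, max_hours)``, sign-flipped so that
    ``S(f) ~ f**-beta``.  Returns ``(beta, r_squared)``.
    """
    lo, hi = fit_range
    sel = (result.periods_h >= lo) & (result.periods_h <= hi) & (result.scores > 0)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 resolved frequencies in fit range")
    logf = np.log10(1.0 / (result.periods_h[sel] * 3600.0))
    logs = np.log10(result.scores[sel])
    fit = stats.linregress(logf, logs)
    return -float(fit.slope), float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# Enright chi-square periodogram

from functools import lru_cache


@lru_cache(maxsize=100_000)
def _beta_critical(p: int, k: int, alpha_level: float) -> float:
    """Upper quantile of the exact variance-fraction null for a P-fold."""
    return float(
        stats.beta.ppf(1.0 - alpha_level, (p - 1) / 2.0, p * (k - 1) / 2.0)
    )


def enright_periodogram(
    actogram,
    period_range: tuple[int, int] | None = None,
    alpha_level: float = 0.001,
    bin_seconds: float | None = None,
    null: str = "beta",
) -> PeriodogramResult:
    """Chi-square (Enright) periodogram of a binned activity series.

    For each trial period ``P`` (in bins) the series is folded into ``K``
    rows of length ``P`` and ``Q_P = N * var(column means) / var(series)``
    is computed over the ``N = K*P`` folded samples.  ``Q_P / N`` is the
    fraction of variance explained by the fold, which under Gaussian white
    noise follows a Beta((P-1)/2, P(K-1)/2) law exactly; that is the
    default significance null.  ``null="chi2"`` uses the classical
    chi-square approximation with ``P - 1`` degrees of freedom instead,
    which is accurate when many cycles are folded (large ``K``) but
    conservative for trial periods near ``N/2``.

    ``actogram`` may be an :class:`Actogram` or a plain array (then
    ``bin_seconds`` must be given).  Trial periods default to 2 .. N//2
    bins; the degenerate single-bin fold is skipped.
    """
    if isinstance(actogram, Actogram):
        x = actogram.percents
        bin_seconds = actogram.bin_seconds
    else:
        x = np.asarray(actogram, dtype=float)
        if bin_seconds is None:
            raise ValueError("bin_seconds required for a plain array")
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x), x)  # neutral fill for gaps
    n = x.size
    if period_range is None:
        period_range = (2, n // 2)
    p_lo, p_hi = period_range
    p_lo = max(2, int(p_lo))
    p_hi = min(n // 2, int(p_hi))
    if p_hi < p_lo:
        raise ValueError("actogram too short for the requested periods")
    if x.var() == 0:
        raise ValueError("constant actogram: Q_P undefined")
    if null not in ("beta", "chi2"):
        raise ValueError("null must be 'beta' or 'chi2'")
    periods = np.arange(p_lo, p_hi + 1)
    qp = np.empty(periods.size)
    significant = np.empty(periods.size, dtype=bool)
    for i, p in enumerate(periods):
        k = n // p
        folded = x[: k * p].reshape(k, p)
        col_means = folded.mean(axis=0)
        n_fold = k * p
        total_var = folded.var()
        qp[i] = n_fold * col_means.var() / total_var
        if null == "beta":
            crit = n_fold * _beta_critical(p, k, alpha_level)
        else:
            crit = stats.chi2.ppf(1.0 - alpha_level, p - 1)
        significant[i] = qp[i] > crit
    return PeriodogramResult(
        periods_h=periods * bin_seconds / 3600.0,
        scores=qp,
        method="enright",
        significant=significant,
        alpha_level=alpha_level,
        period_bins=periods,
        bin_seconds=float(bin_seconds),
    )


def enright_select_peaks(
    result: PeriodogramResult, rel_threshold: float = 0.10
) -> pd.DataFrame:
    """Apply the peak-sorting and harmonic-removal rules to a Q_P periodogram.

    Local maxima with ``Q_P`` above ``rel_threshold`` of the global maximum
    are sorted ascending by period; then every period that is an integer
    multiple (within half a bin) of a retained shorter period is removed,
    since the fold statistic cannot distinguish a rhythm from its
    harmonics.  Returns the surviving periods with their scores and
    significance flags.
    """
    if result.method != "enright":
        raise ValueError("enright_select_peaks applies to Enright results")
    qp = result.scores
    periods = result.period_bins
    if periods is None:
        raise ValueError("result lacks trial periods in bins")
    interior = np.arange(1, qp.size - 1)
    is_max = (qp[interior] > qp[interior - 1]) & (qp[interior] >= qp[interior + 1])
    cand = interior[is_max]
    cand = cand[qp[cand] > rel_threshold * qp.max()]
    order = np.argsort(periods[cand])
    kept: list[int] = []
    for idx in cand[order]:
        p = periods[idx]
        harmonic = False
        for j in kept:
            p0 = periods[j]
            m = round(p / p0)
            if m >= 2 and abs(p - m * p0) <= 0.5:
                harmonic = True
                break
        if not harmonic:
            kept.append(idx)
    kept_arr = np.asarray(kept, dtype=int)
    return pd.DataFrame(
        {
            "period_bins": periods[kept_arr],
            "period_hours": result.periods_h[kept_arr],
            "Q_P": qp[kept_arr],
            "significant": (
                result.significant[kept_arr]
                if result.significant is not None
                else np.zeros(kept_arr.size, dtype=bool)
            ),
        }
    )
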