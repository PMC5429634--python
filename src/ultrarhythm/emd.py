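"""Empirical mode decomposition by classic sifting.

EMD splits a signal into intrinsic mode functions (IMFs): oscillatory
components, ordered fast to slow, whose extrema and zero-crossing counts
differ by at most one.  Each sifting pass interpolates the local maxima and
minima with natural cubic splines and subtracts the envelope mean,
iterating until the envelope mean is locally negligible (Rilling's
amplitude criterion, the default of the classic open-source EMD tooling)
or until Huang's SD criterion is met.  Decomposition stops when the
residual retains fewer than three extrema.

Extrema are extended past both ends by symmetry before spline fitting
(mirrored about the terminal extremum, or about the boundary sample when
the signal protrudes beyond the would-be envelope); without this the
envelopes of a week-long record swing wildly at the boundaries and corrupt
the slow IMFs.  The signal is deliberately used as-is - no detrending or
denoising - since EMD is itself the adaptive filter bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .periodogram import PeriodogramResult, dominant_period, power_spectrum

__all__ = [
    "IMFSet",
    "emd_decompose",
    "imf_spectra",
    "principal_peaks",
    "peak_period_histogram",
]

#: Per-IMF sifting iteration cap.
MAX_SIFT_ITERS = 200
#: Envelope-amplitude stopping thresholds (Rilling): sifting stops when the
#: envelope mean is below ``theta1`` of the local envelope amplitude on all
#: but a ``tol`` fraction of samples and below ``theta2`` everywhere.
RILLING_THETA1 = 0.05
RILLING_THETA2 = 0.5
RILLING_TOL = 0.05
#: Huang SD threshold, used when ``stop="sd"``.
SD_THRESHOLD = 0.2


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) plus the monotonic-ish residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sift_iters: list[int]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {f"imf_{i + 1}": imf for i, imf in enumerate(self.imfs)}
        data["residual"] = self.residual
        return pd.DataFrame(data)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    dx = np.diff(x)
    # collapse flat segments so plateaus register a single extremum
    nonzero = np.flatnonzero(dx != 0)
    if nonzero.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    signs = np.sign(dx[nonzero])
    turn = np.flatnonzero(signs[:-1] != signs[1:])
    # plateau midpoint between the end of one run and start of the next
    idx = (nonzero[turn] + 1 + nonzero[turn + 1]) // 2
    maxima = idx[signs[turn] > 0]
    minima = idx[signs[turn] < 0]
    return maxima, minima


def _mirror_ends(
    x: np.ndarray, tmax: np.ndarray, tmin: np.ndarray, nbsym: int = 2
):
    """Extrema extended by symmetry beyond both ends (Rilling's rule).

    Extrema are mirrored about the first/last extremum, unless the signal
    at the boundary protrudes beyond the would-be envelope, in which case
    the boundary sample itself becomes the symmetry point (and, on the
    protruding side, an extremum).  Returns extended (t, v) knot arrays
    for the upper and lower envelope splines.
    """
    n = x.size
    end = n - 1
    if tmax.size < 2 or tmin.size < 2:
        # last, extrema-poor modes: plain reflection about both endpoints
        t_up = np.r_[-tmax[::-1], tmax, 2 * end - tmax[::-1]]
        t_lo = np.r_[-tmin[::-1], tmin, 2 * end - tmin[::-1]]
        v_up = np.r_[x[tmax[::-1]], x[tmax], x[tmax[::-1]]]
        v_lo = np.r_[x[tmin[::-1]], x[tmin], x[tmin[::-1]]]
        return (t_up, v_up), (t_lo, v_lo)
    # -- left
    if tmax[0] < tmin[0]:
        if x[0] > x[tmin[0]]:
            lmax, lmin, lsym = tmax[1 : nbsym + 1], tmin[:nbsym], tmax[0]
        else:
            lmax, lmin, lsym = tmax[:nbsym], np.r_[tmin[: nbsym - 1], 0], 0
    else:
        if x[0] < x[tmax[0]]:
            lmax, lmin, lsym = tmax[:nbsym], tmin[1 : nbsym + 1], tmin[0]
        else:
            lmax, lmin, lsym = np.r_[tmax[: nbsym - 1], 0], tmin[:nbsym], 0
    if (2 * lsym - lmax[::-1])[0] > 0 or (2 * lsym - lmin[::-1])[0] > 0:
        # mirrored knots do not reach past the start; mirror about it
        if lsym == tmax[0]:
            lmax = tmax[:nbsym]
        else:
            lmin = tmin[:nbsym]
        lsym = 0
    # -- right
    if tmax[-1] < tmin[-1]:
        if x[-1] < x[tmax[-1]]:
            rmax, rmin, rsym = tmax[-nbsym:], tmin[-nbsym - 1 : -1], tmin[-1]
        else:
            rmax, rmin, rsym = np.r_[end, tmax[-(nbsym - 1) :]][-nbsym:], tmin[-nbsym:], end
    else:
        if x[-1] > x[tmin[-1]]:
            rmax, rmin, rsym = tmax[-nbsym - 1 : -1], tmin[-nbsym:], tmax[-1]
        else:
            rmax, rmin, rsym = tmax[-nbsym:], np.r_[end, tmin[-(nbsym - 1) :]][-nbsym:], end
    if (2 * rsym - rmax[::-1])[-1] < end or (2 * rsym - rmin[::-1])[-1] < end:
        if rsym == tmax[-1]:
            rmax = tmax[-nbsym:]
        else:
            rmin = tmin[-nbsym:]
        rsym = end
    t_up = np.r_[2 * lsym - lmax[::-1], tmax, 2 * rsym - rmax[::-1]]
    t_lo = np.r_[2 * lsym - lmin[::-1], tmin, 2 * rsym - rmin[::-1]]
    v_up = np.r_[x[lmax[::-1]], x[tmax], x[rmax[::-1]]]
    v_lo = np.r_[x[lmin[::-1]], x[tmin], x[rmin[::-1]]]
    return (t_up, v_up), (t_lo, v_lo)


def _envelopes(
    x: np.ndarray, tmax: np.ndarray, tmin: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower natural-cubic-spline envelopes over the full record."""
    (t_up, v_up), (t_lo, v_lo) = _mirror_ends(x, tmax, tmin)
    grid = np.arange(x.size, dtype=float)
    upper = CubicSpline(*_dedupe(t_up, v_up), bc_type="natural")(grid)
    lower = CubicSpline(*_dedupe(t_lo, v_lo), bc_type="natural")(grid)
    return upper, lower


def _dedupe(t: np.ndarray, v: np.ndarray):
    order = np.argsort(t, kind="stable")
    t, v = t[order].astype(float), v[order]
    keep = np.r_[True, np.diff(t) > 0]
    return t[keep], v[keep]


def _sift(x: np.ndarray, stop: str, max_iters: int) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``x`` by repeated envelope-mean subtraction."""
    h = x.copy()
    n = x.size
    count = 0
    for count in range(1, max_iters + 1):
        maxima, minima = _local_extrema(h)
        if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 3:
            break
        upper, lower = _envelopes(h, maxima, minima)
        mean_env = 0.5 * (upper + lower)
        if stop == "rilling":
            amp = 0.5 * np.abs(upper - lower)
            sigma = np.abs(mean_env) / np.maximum(amp, 1e-12)
            if (
                count > 1
                and np.mean(sigma > RILLING_THETA1) < RILLING_TOL
                and sigma.max() < RILLING_THETA2
            ):
                break
            h = h - mean_env
        else:  # Huang SD criterion
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum(mean_env**2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < SD_THRESHOLD:
                break
    return h, count


def emd_decompose(
    series,
    stop: str = "rilling",
    max_iters: int = MAX_SIFT_ITERS,
    max_imfs: int | None = None,
) -> IMFSet:
    """Decompose a real series into IMFs by iterated sifting.

    ``stop`` selects the sifting-stop rule: ``"rilling"`` (default), which
    iterates until the envelope mean is locally negligible relative to the
    envelope amplitude, or ``"sd"``, Huang's global SD criterion at 0.2.
    The envelope-amplitude rule sifts considerably harder and resolves the
    full dyadic bank of modes in intermittent locomotion actograms.

    Returns an empty IMF list with ``residual == series`` for monotonic
    input.  Reconstruction (sum of IMFs plus residual) is exact to floating
    round-off because every operation is a subtraction.
    """
    if stop not in ("rilling", "sd"):
        raise ValueError("stop must be 'rilling' or 'sd'")
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for EMD")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    iters: list[int] = []
    while max_imfs is None or len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 3:
            break
        h, count = _sift(residual, stop, max_iters)
        imfs.append(h)
        iters.append(count)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, n_sift_iters=iters)


def imf_spectra(imfset: IMFSet, dt: float) -> list[PeriodogramResult]:
    """Power spectrum of each IMF (same scaling as :func:`power_spectrum`)."""
    if imfset.n_imfs == 0:
        raise ValueError("no IMFs to analyse")
    return [power_spectrum(imf, dt) for imf in imfset.imfs]


def mean_zero_crossing_period(imf: np.ndarray, dt: float) -> float:
    """Mean oscillation period (seconds) from the zero-crossing count."""
    crossings = np.count_nonzero(np.diff(np.signbit(imf)))
    if crossings == 0:
        return float("inf")
    return 2.0 * imf.size * dt / crossings


def _spectrum_peaks(result: PeriodogramResult, rel_threshold: float):
    """(period, power) of local spectral maxima above the relative threshold."""
    s = result.scores
    if s.size < 3 or s.max() == 0:
        return []
    interior = np.arange(1, s.size - 1)
    is_max = (s[interior] > s[interior - 1]) & (s[interior] >= s[interior + 1])
    idx = interior[is_max]
    idx = idx[s[idx] > rel_threshold * s.max()]
    return [(float(result.periods_h[i]), float(s[i])) for i in idx]


def principal_peaks(
    spectra: list[PeriodogramResult],
    subgroup_size: int = 4,
    subgroup_start: int | None = None,
    rel_threshold: float = 0.30,
    top_n: int = 10,
) -> list[float]:
    """Principal spectral peaks of a contiguous subgroup of IMFs.

    Within the chosen window of ``subgroup_size`` contiguous IMF spectra,
    peaks higher than ``rel_threshold`` of that spectrum's own maximum are
    pooled and the ``top_n`` largest retained; their periods (hours) are
    returned.  When ``subgroup_start`` is None the window is placed so that
    its last IMF is the one whose dominant period is closest to 24 h,
    i.e. the window spans the circadian-to-ultradian band.
    """
    if len(spectra) < subgroup_size:
        raise ValueError(f"need at least {subgroup_size} IMF spectra")
    if subgroup_start is None:
        dom = np.array([dominant_period(r) for r in spectra])
        last = int(np.argmin(np.abs(np.log(dom / 24.0))))
        subgroup_start = max(0, last - subgroup_size + 1)
    window = spectra[subgroup_start : subgroup_start + subgroup_size]
    if len(window) < subgroup_size:
        raise ValueError("subgroup window extends past the last IMF")
    pooled: list[tuple[float, float]] = []
    for result in window:
        pooled.extend(_spectrum_peaks(result, rel_threshold))
    pooled.sort(key=lambda pk: -pk[1])
    return [period for period, _ in pooled[:top_n]]


def peak_period_histogram(
    period_lists: list[list[float]],
    bin_centers: tuple[float, ...] = (24.0, 12.0, 8.0, 6.0, 4.8, 4.0, 3.0, 2.4, 2.0, 1.0),
    rel_tol: float = 0.15,
) -> dict[float, int]:
    """Aggregate principal peaks across animals into a period histogram.

    Each detected period is snapped to the nearest canonical rhythm period
    within ``rel_tol`` relative distance; periods matching none of the
    centers are ignored.  Returns ``{center: count}``.
    """
    counts = {c: 0 for c in bin_centers}
    centers = np.asarray(bin_centers)
    for periods in period_lists:
        for p in periods:
            rel = np.abs(centers - p) / centers
            j = int(np.argmin(rel))
            if rel[j] <= rel_tol:
                counts[bin_centers[j]] += 1
    return counts
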