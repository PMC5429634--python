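"""Reading, writing and binning of binary locomotion time series.

A locomotion record is a uniformly sampled sequence of 0/1 values: 1 means
the animal was ambulating at some point during the sampling interval, 0 that
it remained immobile.  Records are typically long (a week at 0.5 s
resolution is above 10**6 samples) and may contain short housekeeping gaps
that must be excluded from every downstream statistic.

The module provides the two central containers (:class:`LocomotionSeries`
and :class:`Actogram`), plain-text/CSV readers and writers in the one-sample
-per-row dialect used by public locomotion deposits, and the standard
chronobiology summaries: hourly percent ambulation, binned actograms and the
median (folded) actogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LocomotionSeries",
    "Actogram",
    "read_series",
    "write_series",
    "percent_ambulating_hourly",
    "bin_to_actogram",
    "median_actogram",
    "actogram_to_csv",
    "hourly_to_csv",
]

#: Largest tolerated fraction of excluded samples.  Above this bound the
#: scaling analyses downstream are no longer trustworthy (global DFA
#: exponents are robust to data loss only up to roughly 65 %).
MAX_EXCLUDED_FRACTION = 0.65


@dataclass
class LocomotionSeries:
    """Uniformly sampled binary (0/1) activity record.

    Parameters
    ----------
    values:
        One value per sampling interval, 1 = ambulating, 0 = immobile.
    dt:
        Sampling interval in seconds (0.5 s for the home-cage setup).
    start_clock:
        Clock time of the first sample, in hours after midnight
        (13.0 means recording started at 1:00 PM).
    photoperiod:
        Optional ``(lights_on, lights_off)`` clock times in hours.
    excluded_mask:
        Optional boolean array marking samples that fall inside
        housekeeping gaps; masked samples are removed from every statistic.
    animal_id:
        Free-form label.
    """

    values: np.ndarray
    dt: float = 0.5
    start_clock: float = 13.0
    photoperiod: tuple[float, float] | None = None
    excluded_mask: np.ndarray | None = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size == 0:
            raise ValueError("empty series")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary value {self.values[bad]!r} at sample {bad + 1}"
            )
        self.values = self.values.astype(np.uint8)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.excluded_mask is not None:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
            if self.excluded_mask.shape != self.values.shape:
                raise ValueError("excluded_mask must match values in length")
            frac = float(self.excluded_mask.mean())
            if frac >= MAX_EXCLUDED_FRACTION:
                raise ValueError(
                    f"excluded fraction {frac:.2f} exceeds the "
                    f"{MAX_EXCLUDED_FRACTION:.0%} validity bound"
                )

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_seconds(self) -> float:
        return self.n_samples * self.dt

    @property
    def duration_days(self) -> float:
        return self.duration_seconds / 86400.0

    @property
    def mask(self) -> np.ndarray:
        """Boolean exclusion mask (all False when no gaps were recorded)."""
        if self.excluded_mask is None:
            return np.zeros(self.n_samples, dtype=bool)
        return self.excluded_mask

    def concatenated(self) -> "LocomotionSeries":
        """Drop excluded samples and splice the remainder end to end.

        Housekeeping gaps are short (< 2 % of the record), so downstream
        stages treat the record as if the gap intervals never happened.
        """
        if self.excluded_mask is None or not self.excluded_mask.any():
            return self
        return replace(
            self, values=self.values[~self.excluded_mask], excluded_mask=None
        )


@dataclass
class Actogram:
    """Percent-time-ambulating per fixed-width bin.

    ``percents`` lie in [0, 100]; a bin whose samples were all excluded is
    stored as NaN (missing), never as zero activity.
    """

    percents: np.ndarray
    bin_seconds: float = 360.0
    start_clock: float = 13.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.percents = np.asarray(self.percents, dtype=float)
        finite = self.percents[np.isfinite(self.percents)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("percents must lie in [0, 100]")

    @property
    def n_bins(self) -> int:
        return int(self.percents.size)

    @property
    def day_length_bins(self) -> int:
        """Number of bins per 24 h day."""
        n = 86400.0 / self.bin_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_seconds does not divide 24 h evenly")
        return int(round(n))

    @property
    def times_hours(self) -> np.ndarray:
        """Elapsed time of each bin's left edge, hours since record start."""
        return np.arange(self.n_bins) * self.bin_seconds / 3600.0


# ---------------------------------------------------------------------------
# file I/O

def read_series(
    path,
    dt: float = 0.5,
    column: int = 0,
    metadata: dict | None = None,
) -> LocomotionSeries:
    """Read a binary locomotion series from a plain-text or CSV file.

    The expected dialect is one sample per row; multi-column CSV files are
    supported through ``column`` (deposits sometimes carry a leading time
    column).  Lines starting with ``#`` are ignored, as is a single
    non-numeric header row.

    Raises
    ------
    ValueError
        If the file is empty or a token is not 0/1 (the error names the
        offending line).
    FileNotFoundError
        If ``path`` does not exist.
    """
    values: list[int] = []
    meta = dict(metadata or {})
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if column >= len(tokens):
                raise ValueError(
                    f"{path}: line {lineno} has no column {column}"
                )
            tok = tokens[column]
            try:
                val = float(tok)
            except ValueError:
                if lineno == 1:  # tolerate one header row
                    continue
                raise ValueError(
                    f"{path}: non-numeric token {tok!r} at line {lineno}"
                ) from None
            if val not in (0.0, 1.0):
                raise ValueError(
                    f"{path}: non-binary value {tok!r} at line {lineno}"
                )
            values.append(int(val))
    if not values:
        raise ValueError(f"{path}: no samples found")
    return LocomotionSeries(
        values=np.asarray(values, dtype=np.uint8),
        dt=dt,
        start_clock=float(meta.get("start_clock", 13.0)),
        photoperiod=meta.get("photoperiod"),
        animal_id=str(meta.get("animal_id", "")),
    )


def write_series(series: LocomotionSeries, path) -> None:
    """Write one sample per line, the same dialect :func:`read_series` reads."""
    np.savetxt(path, series.values, fmt="%d")


# ---------------------------------------------------------------------------
# summaries

def percent_ambulating_hourly(series: LocomotionSeries) -> np.ndarray:
    """Percent of time spent ambulating per whole hour.

    Amb% = 100 * (number of ambulating samples) / (number of retained
    samples) per hour; excluded samples are removed from both numerator and
    denominator.  Trailing partial hours are dropped.
    """
    per_hour = int(round(3600.0 / series.dt))
    n_hours = series.n_samples // per_hour
    if n_hours < 1:
        raise ValueError("series shorter than one hour")
    vals = series.values[: n_hours * per_hour].reshape(n_hours, per_hour)
    keep = ~series.mask[: n_hours * per_hour].reshape(n_hours, per_hour)
    counts = (vals * keep).sum(axis=1).astype(float)
    denom = keep.sum(axis=1).astype(float)
    out = np.full(n_hours, np.nan)
    ok = denom > 0
    out[ok] = 100.0 * counts[ok] / denom[ok]
    return out


def bin_to_actogram(
    series: LocomotionSeries, bin_seconds: float = 360.0
) -> Actogram:
    """Bin a locomotion series into percent-time-ambulating bins.

    ``bin_seconds`` must be an integer multiple of the sampling interval.
    The trailing partial bin is dropped; a bin whose samples are all
    excluded becomes NaN.
    """
    ratio = bin_seconds / series.dt
    if bin_seconds < series.dt or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("bin_seconds must be an integer multiple of dt")
    per_bin = int(round(ratio))
    n_bins = series.n_samples // per_bin
    if n_bins == 0:
        raise ValueError("series shorter than one bin")
    vals = series.values[: n_bins * per_bin].reshape(n_bins, per_bin)
    keep = ~series.mask[: n_bins * per_bin].reshape(n_bins, per_bin)
    counts = (vals * keep).sum(axis=1).astype(float)
    denom = keep.sum(axis=1).astype(float)
    percents = np.full(n_bins, np.nan)
    ok = denom > 0
    percents[ok] = 100.0 * counts[ok] / denom[ok]
    return Actogram(
        percents=percents,
        bin_seconds=float(bin_seconds),
        start_clock=series.start_clock,
        animal_id=series.animal_id,
    )


def median_actogram(actogram: Actogram) -> np.ndarray:
    """Median percent ambulation per within-day bin position.

    Folds the actogram at the 24 h day (day boundary at midnight, bins
    addressed by their left edge) and takes the median across days at each
    position, ignoring missing bins.  Requires at least two full days.
    """
    day_bins = actogram.day_length_bins
    if actogram.n_bins < 2 * day_bins:
        raise ValueError("median actogram needs at least two full days")
    offset = int(round(actogram.start_clock * 3600.0 / actogram.bin_seconds))
    positions = (offset + np.arange(actogram.n_bins)) % day_bins
    out = np.full(day_bins, np.nan)
    for pos in range(day_bins):
        vals = actogram.percents[positions == pos]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[pos] = np.median(vals)
    return out


# ---------------------------------------------------------------------------
# CSV export

def actogram_to_csv(actogram: Actogram, path) -> None:
    clock = (actogram.start_clock + actogram.times_hours) % 24.0
    pd.DataFrame(
        {"bin_start_clock": clock, "percent": actogram.percents}
    ).to_csv(path, index=False)


def hourly_to_csv(percents: np.ndarray, path) -> None:
    pd.DataFrame(
        {"hour": np.arange(len(percents)), "percent": percents}
    ).to_csv(path, index=False)
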