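"""Statistical characterisation of sound-level distributions.

Averages of decibel series are not interchangeable.  The RMS (power-mean)
level — the L_eq of terrestrial noise assessment — averages squared
pressure before the dB conversion, so intermittent high-amplitude events
dominate it: it can exceed the 95th percentile of the underlying levels.
The median (L_50) and the mode (the level of maximum probability density)
are more representative of typical conditions.  Percentiles double as
exceedance levels with reversed order: L_95, the level exceeded 95% of the
time, is the 5th percentile.  The full picture is the spectral probability
density (SPD): the empirical probability density of levels in each
frequency band, which exposes multimodality and instrument limits (a
self-noise floor appears as the lowest level bins converging onto the
mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .spectral import BandSeries, PsdGrid

__all__ = [
    "SummaryStats",
    "LevelDistribution",
    "ModeResult",
    "rms_average",
    "percentile_levels",
    "exceedance_levels",
    "mode_level",
    "summary_stats",
    "spd",
    "temporal_aggregate",
]


def _clean(levels) -> np.ndarray:
    x = np.asarray(levels, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite levels supplied")
    return x


def rms_average(levels: Iterable[float]) -> float:
    """Power-domain (RMS / L_eq) average of dB levels.

    10·log10( mean(10^(L/10)) ): the mean squared pressure is formed before
    the dB conversion.  Always ≥ the arithmetic mean of the dB values
    (Jensen's inequality) and strongly influenced by the loudest windows.
    """
    x = _clean(levels)
    return float(10.0 * np.log10(np.mean(10.0 ** (x / 10.0))))


def percentile_levels(levels: Iterable[float], q) -> np.ndarray:
    """Empirical dB quantiles with linear interpolation of order statistics."""
    x = _clean(levels)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    return np.percentile(x, q)


def exceedance_levels(levels: Iterable[float], x) -> np.ndarray:
    """Exceedance level L_x: the level exceeded x% of the time.

    L_x is the (100 − x)th percentile; L_95 equals the 5th percentile.
    """
    x = np.asarray(x, dtype=float)
    return percentile_levels(levels, 100.0 - x)


@dataclass
class ModeResult:
    """Histogram mode of a level distribution."""

    level: float  #: center of the bin with maximum probability density, dB
    multimodal: bool  #: a second peak lies within 3 dB density of the maximum
    bin_width: float

    def __float__(self) -> float:
        return self.level


def mode_level(levels: Iterable[float], bin_width: float = 1.0) -> ModeResult:
    """Modal level: center of the histogram bin of maximum density.

    Ties break toward the lower level.  ``multimodal`` is set when a second
    local maximum of the histogram has density within 3 dB of the global
    maximum — a warning that a single mode may be misleading.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = _clean(levels)
    edges = _level_bin_edges(x, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    imax = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
    centers = (edges[:-1] + edges[1:]) / 2

    # local maxima: bins strictly above both neighbours (ends compare one side)
    c = counts.astype(float)
    left = np.r_[-1.0, c[:-1]]
    right = np.r_[c[1:], -1.0]
    peaks = np.flatnonzero((c >= left) & (c >= right) & (c > 0))
    # drop plateau duplicates adjacent to the global max
    others = peaks[(np.abs(peaks - imax) > 1)]
    multimodal = bool(
        len(others) and np.any(10 * np.log10(c[imax] / c[others]) <= 3.0)
    )
    return ModeResult(level=float(centers[imax]), multimodal=multimodal, bin_width=bin_width)


@dataclass
class SummaryStats:
    """Summary of one level distribution (all values dB re p_ref)."""

    rms_level: float
    median: float
    mode: float
    percentiles: dict[float, float]
    minimum: float
    q1: float
    q3: float
    maximum: float
    n: int

    def boxplot(self) -> dict[str, float]:
        """Five-number summary {min, Q1, median, Q3, max}."""
        return {
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.maximum,
        }


def summary_stats(
    levels: Iterable[float],
    percentiles: Sequence[float] = (1, 5, 50, 95, 99),
    mode_bin_width: float = 1.0,
) -> SummaryStats:
    """All standard level statistics of one dB sample in one pass."""
    x = _clean(levels)
    q = percentile_levels(x, percentiles)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return SummaryStats(
        rms_level=rms_average(x),
        median=float(med),
        mode=mode_level(x, mode_bin_width).level,
        percentiles={float(p): float(v) for p, v in zip(percentiles, q)},
        minimum=float(x.min()),
        q1=float(q1),
        q3=float(q3),
        maximum=float(x.max()),
        n=len(x),
    )


# -- spectral probability density -------------------------------------------

@dataclass
class LevelDistribution:
    """Empirical probability density of levels per frequency (the SPD).

    ``density[i, j]`` is probability per dB for frequency ``frequencies[i]``
    and level bin ``j``; each frequency row integrates to exactly 1.
    """

    frequencies: np.ndarray
    level_bin_edges: np.ndarray
    density: np.ndarray  # (n_frequencies, n_level_bins), units 1/dB
    n_samples: np.ndarray

    @property
    def level_bin_centers(self) -> np.ndarray:
        return (self.level_bin_edges[:-1] + self.level_bin_edges[1:]) / 2

    @property
    def bin_width(self) -> float:
        return float(self.level_bin_edges[1] - self.level_bin_edges[0])

    def mode_per_frequency(self) -> np.ndarray:
        """Level of maximum probability density at each frequency."""
        return self.level_bin_centers[np.argmax(self.density, axis=1)]

    def to_dataframe(self) -> pd.DataFrame:
        f, lv = np.meshgrid(self.frequencies, self.level_bin_centers, indexing="ij")
        return pd.DataFrame(
            {
                "frequency_hz": f.ravel(),
                "level_db": lv.ravel(),
                "density_per_db": self.density.ravel(),
            }
        )

    def to_csv(self, path, float_format: str = "%.6g") -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=float_format)


def _level_bin_edges(x: np.ndarray, bin_width: float) -> np.ndarray:
    """Uniform dB bin edges aligned to multiples of bin_width, padded to cover x."""
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def spd(grid: PsdGrid, bin_width: float = 1.0) -> LevelDistribution:
    """Spectral probability density of a PSD grid.

    Per-frequency normalized histogram of dB levels (units 1/dB) over
    uniform level bins spanning the observed range.  Requires at least two
    time steps; a single column has no distribution to estimate.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if grid.levels.shape[1] < 2:
        raise ValueError("SPD needs at least 2 time steps")
    finite = grid.levels[np.isfinite(grid.levels)]
    if len(finite) == 0:
        raise ValueError("no finite levels in grid")
    edges = _level_bin_edges(finite, bin_width)
    n_f = len(grid.frequencies)
    density = np.zeros((n_f, len(edges) - 1))
    n_samples = np.zeros(n_f, dtype=int)
    for i in range(n_f):
        row = grid.levels[i]
        row = row[np.isfinite(row)]
        n_samples[i] = len(row)
        if len(row):
            counts, _ = np.histogram(row, bins=edges)
            density[i] = counts / (len(row) * bin_width)
    return LevelDistribution(
        frequencies=grid.frequencies,
        level_bin_edges=edges,
        density=density,
        n_samples=n_samples,
    )


# -- temporal aggregation ----------------------------------------------------

_KEYS = ("hour-of-day", "day", "month")
_STATS = ("median", "rms", "percentiles", "boxplot")


def temporal_aggregate(
    series: Union[BandSeries, PsdGrid],
    key: str = "hour-of-day",
    stat: str = "median",
    percentiles: Sequence[float] = (5, 50, 95),
) -> pd.DataFrame:
    """Group levels by a calendar key and summarise per band/frequency.

    Recordings must carry absolute timestamps (a datetime ``start_time``).
    Grouping uses the recording's local clock as parsed from filenames; no
    daylight-saving adjustment is applied.

    Returns a long-form table with one row per (group, band) and columns
    for the requested statistic: ``level_db`` for median/rms, one column
    per percentage for ``percentiles``, or the five-number summary for
    ``boxplot`` (min ≤ Q1 ≤ median ≤ Q3 ≤ max).
    """
    if key not in _KEYS:
        raise ValueError(f"key must be one of {_KEYS}")
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {_STATS}")

    stamps = pd.DatetimeIndex(series.timestamps())
    if isinstance(series, PsdGrid):
        band_ids = [f"{f:g}" for f in series.frequencies]
    else:
        band_ids = list(series.labels)
    levels = series.levels  # (n_bands, n_times)

    group = {
        "hour-of-day": stamps.hour,
        "day": stamps.normalize(),
        "month": stamps.to_period("M"),
    }[key]

    frames = []
    for i, band in enumerate(band_ids):
        df = pd.DataFrame({"group": group, "level": levels[i]})
        df = df[np.isfinite(df["level"])]
        g = df.groupby("group")["level"]
        if stat == "median":
            out = g.median().rename("level_db").reset_index()
        elif stat == "rms":
            out = g.apply(rms_average).rename("level_db").reset_index()
        elif stat == "percentiles":
            out = g.apply(
                lambda s: pd.Series(
                    dict(zip([f"p{p:g}" for p in percentiles],
                             np.percentile(s, percentiles)))
                )
            ).unstack().reset_index()
        else:  # boxplot
            out = g.apply(
                lambda s: pd.Series(
                    {
                        "min": s.min(),
                        "q1": s.quantile(0.25),
                        "median": s.median(),
                        "q3": s.quantile(0.75),
                        "max": s.max(),
                    }
                )
            ).unstack().reset_index()
        out.insert(1, "band", band)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
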