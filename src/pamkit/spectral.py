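"""Calibrated spectral analysis: Welch PSD, spectrograms, band levels, SEL.

All levels are decibels relative to the reference pressure carried by the
input :class:`~pamkit.calibration.PressureSeries` (20 µPa in air, 1 µPa
underwater).  PSD levels are dB re p_ref²/Hz — power in the equivalent of
1-Hz bands — while band levels (broadband SPL, 1/3-octave levels) are
dB re p_ref.  Spectra with differing bandwidths (PSD versus 1/3-octave)
are therefore on different scales and cannot be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal as sps

from .calibration import PressureSeries

__all__ = [
    "SpectralConfig",
    "PsdGrid",
    "BandSeries",
    "window_coefficients",
    "psd_welch",
    "spectrogram",
    "broadband_spl",
    "third_octave_levels",
    "third_octave_center",
    "third_octave_nominal",
    "sel",
]

_WINDOWS = ("hann", "hamming", "rectangular")

# Renard preferred numbers for nominal 1/3-octave band labels (ratio 10^(1/10))
_RENARD = (1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0)


@dataclass
class SpectralConfig:
    """STFT/Welch analysis parameters.

    Parameters
    ----------
    segment_length : int
        DFT segment length N in samples (frequency resolution fs/N).
    window : {"hann", "hamming", "rectangular"}
        Taper applied to each segment.  Hann is the default; it trades a
        wider main lobe for strong sidelobe suppression.
    overlap : float
        Fractional overlap between successive segments, in [0, 1).
        0.5 is standard Welch practice; dense overlaps (e.g. 0.99) smooth
        impulsive events at proportionate cost.
    average_seconds : float, optional
        When set, periodograms are averaged into output columns of this
        duration (Welch's method with a time-resolved output).  Must be at
        least one segment long.  None → no averaging beyond the segment.
    scaling : {"density", "band"}
        "density" yields PSD in p_ref²/Hz; "band" yields power per DFT bin.
    """

    segment_length: int = 1024
    window: str = "hann"
    overlap: float = 0.5
    average_seconds: Optional[float] = None
    scaling: str = "density"

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.window not in _WINDOWS:
            raise ValueError(f"unknown window {self.window!r}; choose from {_WINDOWS}")
        if self.scaling not in ("density", "band"):
            raise ValueError("scaling must be 'density' or 'band'")

    def hop(self) -> int:
        """Hop size in samples between successive segments."""
        return self.segment_length - int(np.floor(self.overlap * self.segment_length))

    @classmethod
    def from_seconds(
        cls, segment_seconds: float, sample_rate: float, **kw
    ) -> "SpectralConfig":
        return cls(segment_length=int(round(segment_seconds * sample_rate)), **kw)


@dataclass
class PsdGrid:
    """Time × frequency matrix of calibrated spectral levels (a spectrogram).

    Attributes
    ----------
    times : ndarray
        Segment-center times in seconds relative to ``start_time``.
    frequencies : ndarray
        Hz, 0 to Nyquist, spacing sample_rate / segment_length.
    levels : ndarray, shape (n_frequencies, n_times)
        dB re p_ref²/Hz (density scaling) or dB re p_ref² (band scaling).
    n_averaged : ndarray
        Number of periodograms averaged into each column.
    """

    times: np.ndarray
    frequencies: np.ndarray
    levels: np.ndarray
    config: SpectralConfig
    p_ref: float = 1.0
    start_time: Union[float, datetime] = 0.0
    sample_rate: float = 0.0
    n_averaged: np.ndarray = field(default=None)
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("levels must be (n_frequencies, n_times)")
        if self.n_averaged is None:
            self.n_averaged = np.ones(len(self.times), dtype=int)

    @property
    def power(self) -> np.ndarray:
        """Linear power (p_ref² or p_ref²/Hz units removed): 10**(levels/10) * p_ref²."""
        return 10.0 ** (self.levels / 10.0) * self.p_ref**2

    def timestamps(self) -> np.ndarray:
        """Absolute timestamps per column; requires a datetime start_time."""
        if not isinstance(self.start_time, datetime):
            raise ValueError("PsdGrid has no absolute start_time")
        return np.array([self.start_time + timedelta(seconds=float(t)) for t in self.times])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table (time_s, frequency_hz, level_db)."""
        t, f = np.meshgrid(self.times, self.frequencies)
        return pd.DataFrame(
            {
                "time_s": t.ravel(),
                "frequency_hz": f.ravel(),
                "level_db": self.levels.ravel(),
            }
        )

    def to_csv(self, path, float_format: str = "%.6f") -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=float_format)

    def to_netcdf(self, path) -> None:
        """Gridded export (NetCDF3 container via the scipy backend)."""
        import xarray as xr

        da = xr.DataArray(
            self.levels,
            coords={"frequency_hz": self.frequencies, "time_s": self.times},
            dims=("frequency_hz", "time_s"),
            name="level_db",
            attrs={"p_ref_upa": self.p_ref, "scaling": self.config.scaling},
        )
        da.to_netcdf(path, engine="scipy")


@dataclass
class BandSeries:
    """Time series of levels in named frequency bands, dB re p_ref."""

    times: np.ndarray
    band_centers: np.ndarray
    band_edges: np.ndarray  # (n_bands, 2) lower/upper Hz
    levels: np.ndarray  # (n_bands, n_times)
    labels: Sequence[str] = ()
    p_ref: float = 1.0
    start_time: Union[float, datetime] = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        self.levels = np.atleast_2d(np.asarray(self.levels, dtype=float))
        if self.levels.shape != (len(self.band_centers), len(self.times)):
            raise ValueError("levels must be (n_bands, n_times)")
        if not len(self.labels):
            self.labels = [f"{c:g}" for c in self.band_centers]

    def timestamps(self) -> np.ndarray:
        if not isinstance(self.start_time, datetime):
            raise ValueError("BandSeries has no absolute start_time")
        return np.array([self.start_time + timedelta(seconds=float(t)) for t in self.times])

    def band(self, label: str) -> np.ndarray:
        """Level time series for one band by its nominal label."""
        try:
            i = list(self.labels).index(label)
        except ValueError:
            raise KeyError(f"no band labelled {label!r}; have {list(self.labels)}")
        return self.levels[i]

    def to_dataframe(self) -> pd.DataFrame:
        t, c = np.meshgrid(self.times, self.band_centers)
        lab = np.repeat(np.asarray(self.labels, dtype=object), len(self.times))
        return pd.DataFrame(
            {
                "time_s": t.ravel(),
                "band_center_hz": c.ravel(),
                "band": lab,
                "level_db": self.levels.ravel(),
            }
        )

    def to_csv(self, path, float_format: str = "%.6f") -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=float_format)


# -- windows ----------------------------------------------------------------

def window_coefficients(window: str, n: int) -> tuple[np.ndarray, float, float]:
    """Taper coefficients and their normalization constants.

    Returns
    -------
    w : ndarray
        Periodic taper of length ``n``.
    coherent_gain : float
        Σw / n — amplitude scaling of an in-bin tone (0.5 for Hann).
    noise_bandwidth : float
        Equivalent noise power bandwidth B = n·Σw² / (Σw)² in bins
        (1.0 rectangular, 1.5 Hann in the large-n limit).
    """
    if n < 2:
        raise ValueError("window length must be >= 2")
    if window == "rectangular":
        w = np.ones(n)
    elif window in ("hann", "hamming"):
        w = sps.get_window(window, n, fftbins=True)
    else:
        raise ValueError(f"unknown window {window!r}; choose from {_WINDOWS}")
    s1 = w.sum()
    s2 = (w**2).sum()
    return w, float(s1 / n), float(n * s2 / s1**2)


# -- PSD estimation ----------------------------------------------------------

def _segment_psds(
    p: PressureSeries, cfg: SpectralConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-sided window-compensated periodograms, one column per segment.

    Returns (frequencies, segment-center times, psd matrix in µPa²/Hz or
    µPa² per bin depending on scaling).
    """
    n = cfg.segment_length
    x = p.pressure
    if len(x) < n:
        raise ValueError(
            f"series of {len(x)} samples shorter than one segment ({n} samples)"
        )
    w, _cg, _nbw = window_coefficients(cfg.window, n)
    hop = cfg.hop()
    freqs, times, psd = sps.spectrogram(
        x,
        fs=p.sample_rate,
        window=w,
        nperseg=n,
        noverlap=n - hop,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    if cfg.scaling == "band":
        psd = psd * (p.sample_rate / n)  # per-bin power instead of per Hz
    return freqs, times, psd


def spectrogram(p: PressureSeries, cfg: SpectralConfig) -> PsdGrid:
    """Calibrated spectrogram: one PSD column per analysis segment.

    Each column is the single-sided, window-compensated periodogram of one
    segment, in dB re p_ref²/Hz.  Overlapping segments (``cfg.overlap``)
    smooth the time dimension and keep sounds spanning segment boundaries
    represented.
    """
    freqs, times, psd = _segment_psds(p, cfg)
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(psd / p.p_ref**2)
    return PsdGrid(
        times=times,
        frequencies=freqs,
        levels=levels,
        config=cfg,
        p_ref=p.p_ref,
        start_time=p.start_time,
        sample_rate=p.sample_rate,
        clipped_fraction=p.clipped_fraction,
    )


def psd_welch(p: PressureSeries, cfg: SpectralConfig) -> PsdGrid:
    """Welch PSD estimate, optionally resolved in time.

    Periodograms of successive segments are averaged arithmetically (in
    power) within each ``average_seconds`` interval; with
    ``average_seconds=None`` a single column averages the whole series.
    Averaging K segments reduces estimator variance by ~1/K without
    changing the expectation.
    """
    freqs, seg_times, psd = _segment_psds(p, cfg)
    seg_dur = cfg.segment_length / p.sample_rate
    if cfg.average_seconds is None:
        bins = np.zeros(len(seg_times), dtype=int)
        n_bins = 1
    else:
        if cfg.average_seconds < seg_dur:
            raise ValueError("average_seconds must be at least one segment long")
        # group by segment start time so a 60 s file with 1 s segments and
        # average_seconds=60 forms exactly one column
        seg_starts = seg_times - seg_dur / 2
        bins = np.floor(seg_starts / cfg.average_seconds + 1e-9).astype(int)
        n_bins = bins.max() + 1

    mean_psd = np.empty((len(freqs), n_bins))
    n_avg = np.empty(n_bins, dtype=int)
    out_times = np.empty(n_bins)
    for b in range(n_bins):
        m = bins == b
        n_avg[b] = np.count_nonzero(m)
        if n_avg[b] == 0:
            mean_psd[:, b] = np.nan
            out_times[b] = (b + 0.5) * (cfg.average_seconds or 0)
            continue
        mean_psd[:, b] = psd[:, m].mean(axis=1)
        out_times[b] = seg_times[m].mean()

    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(mean_psd / p.p_ref**2)
    return PsdGrid(
        times=out_times,
        frequencies=freqs,
        levels=levels,
        config=cfg,
        p_ref=p.p_ref,
        start_time=p.start_time,
        sample_rate=p.sample_rate,
        n_averaged=n_avg,
        clipped_fraction=p.clipped_fraction,
    )


# -- band levels -------------------------------------------------------------

def band_power(grid: PsdGrid, f_lo: float, f_hi: float) -> np.ndarray:
    """Integrated power per time step over [f_lo, f_hi], in µPa².

    A PSD bin belongs to the band containing its center frequency (no bin
    splitting); the assignment error is bounded by one bin width.
    """
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    df = grid.sample_rate / grid.config.segment_length
    mask = (grid.frequencies >= f_lo) & (grid.frequencies <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no PSD bins inside band ({f_lo}, {f_hi}) Hz")
    power = grid.power
    if grid.config.scaling == "density":
        return power[mask].sum(axis=0) * df
    return power[mask].sum(axis=0)


def broadband_spl(
    p: PressureSeries,
    f_lo: float = 0.0,
    f_hi: Optional[float] = None,
    cfg: Optional[SpectralConfig] = None,
) -> BandSeries:
    """Broadband SPL time series: RMS level over a frequency range.

    PSD power is integrated over [f_lo, f_hi] in each averaging interval
    and converted to dB re p_ref.  With the full band (0 to Nyquist) this
    equals the time-domain RMS level.
    """
    nyq = p.sample_rate / 2
    if f_hi is None:
        f_hi = nyq
    if not 0 <= f_lo < f_hi <= nyq + 1e-9:
        raise ValueError(f"band ({f_lo}, {f_hi}) outside [0, {nyq}] Hz")
    if cfg is None:
        cfg = SpectralConfig(segment_length=min(1024, len(p.pressure)))
    grid = psd_welch(p, cfg)
    power = band_power(grid, f_lo, f_hi)
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(power / p.p_ref**2)
    return BandSeries(
        times=grid.times,
        band_centers=[np.sqrt(max(f_lo, grid.frequencies[1]) * f_hi)],
        band_edges=[(f_lo, f_hi)],
        levels=levels[np.newaxis, :],
        labels=["broadband"],
        p_ref=p.p_ref,
        start_time=p.start_time,
    )


def third_octave_center(n: int) -> float:
    """Exact base-ten 1/3-octave center frequency 10**(n/10) Hz."""
    return 10.0 ** (n / 10.0)


def third_octave_nominal(n: int) -> float:
    """Nominal (preferred-number) center for band ``n`` (e.g. 18 → 63 Hz)."""
    decade, pos = divmod(n, 10)
    return _RENARD[pos] * 10.0**decade


def third_octave_levels(
    grid: PsdGrid, f_lo: float = 0.0, f_hi: Optional[float] = None
) -> BandSeries:
    """1/3-octave band levels from a PSD grid, dB re p_ref.

    Bands follow the base-ten ladder: exact centers fc(n) = 10**(n/10) Hz
    with edges fc·10**(±1/20), so successive bandwidths grow by the ratio
    10**(1/10) (constant Q).  Bands narrower than one PSD bin (unresolvable
    at the grid's frequency resolution) and bands whose upper edge exceeds
    Nyquist (or ``f_hi``) are excluded, leaving a contiguous ladder;
    nominal preferred-number labels (…, 63, 125, …) are attached.
    """
    if grid.config.scaling != "density":
        raise ValueError("third_octave_levels requires density scaling")
    nyq = grid.sample_rate / 2
    if f_hi is None:
        f_hi = nyq
    f_hi = min(f_hi, nyq)
    df = grid.sample_rate / grid.config.segment_length
    edge = 10.0 ** (1.0 / 20.0)

    # narrowest resolvable band: bandwidth fc*(edge - 1/edge) >= one bin
    fc_min = max(f_lo, df / (edge - 1 / edge))
    n_min = int(np.ceil(10 * np.log10(max(fc_min, 0.1))))
    n_max = int(np.floor(10 * np.log10(f_hi / edge)))
    power = grid.power

    centers, edges, labels, rows = [], [], [], []
    for n in range(n_min, n_max + 1):
        fc = third_octave_center(n)
        lo, hi = fc / edge, fc * edge
        if hi > f_hi + 1e-9:
            continue
        mask = (grid.frequencies >= lo) & (grid.frequencies < hi)
        if not np.any(mask):
            continue
        band = power[mask].sum(axis=0) * df
        centers.append(fc)
        edges.append((lo, hi))
        labels.append(f"{third_octave_nominal(n):g}")
        with np.errstate(divide="ignore"):
            rows.append(10.0 * np.log10(band / grid.p_ref**2))
    if not rows:
        raise ValueError("grid does not cover one complete 1/3-octave band")
    return BandSeries(
        times=grid.times,
        band_centers=centers,
        band_edges=edges,
        levels=np.vstack(rows),
        labels=labels,
        p_ref=grid.p_ref,
        start_time=grid.start_time,
    )


# -- sound exposure level ----------------------------------------------------

def sel(p: PressureSeries, t0: float = 0.0, t1: Optional[float] = None) -> float:
    """Sound exposure level over [t0, t1], dB re p_ref²·s.

    SEL = 10·log10( Σ p²·Δt / (p_ref² · 1 s) ): the time integral of
    squared pressure referenced to one second.  For a stationary signal of
    SPL L over T seconds, SEL = L + 10·log10(T).
    """
    if t1 is None:
        t1 = p.duration
    if not 0 <= t0 < t1 <= p.duration + 1e-9:
        raise ValueError(f"interval ({t0}, {t1}) invalid for a {p.duration} s series")
    seg = p.slice_seconds(t0, t1)
    energy = np.sum(seg.pressure**2) / p.sample_rate
    if energy <= 0:
        raise ValueError("zero energy in interval; SEL undefined")
    return float(10.0 * np.log10(energy / p.p_ref**2))
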