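"""Waveform-domain metrics for impulsive sounds.

Impulses (airgun shots, pile strikes, echolocation clicks, gunshots) are
too brief for frequency spectra to represent their amplitude faithfully;
they are measured on the calibrated pressure waveform instead.  The peak
is described by the zero-to-peak level SPL_0p = 20·log10(max|p|/p_ref) or
peak-to-peak level SPL_pp = 20·log10((max p − min p)/p_ref); the energy by
the pulse SEL; and the duration by the 90% energy envelope — the window
between 5% and 95% of cumulative energy.  A pulse measurement is
considered valid when its signal-to-noise ratio is at least 10 dB and the
recording chain is flat over the pulse's peak frequency range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import CalibrationSpec, PressureSeries
from .spectral import sel as _sel

__all__ = [
    "PulseMetrics",
    "peak_levels",
    "energy_envelope",
    "pulse_sel",
    "snr_check",
    "analyze_pulse",
    "SNR_THRESHOLD_DB",
]

#: Minimum pulse signal-to-noise ratio for a valid amplitude measurement.
SNR_THRESHOLD_DB = 10.0


@dataclass
class PulseMetrics:
    """Descriptors of one impulsive event (dB re p_ref / p_ref²·s)."""

    spl_zero_to_peak: float
    spl_peak_to_peak: float
    sel_pulse: float  #: SEL over the full analysis window
    sel_envelope: float  #: SEL restricted to the 90% energy envelope
    t5: float  #: seconds, 5% cumulative-energy crossing (series-relative)
    t95: float  #: seconds, 95% crossing
    tau90: float  #: t95 − t5, the 90%-energy pulse duration
    snr: Optional[float] = None
    valid: Optional[bool] = None


def _window_slice(p: PressureSeries, t0: float, t1: float) -> np.ndarray:
    if not 0 <= t0 < t1 <= p.duration + 1e-9:
        raise ValueError(f"window ({t0}, {t1}) outside series of {p.duration} s")
    i0 = int(round(t0 * p.sample_rate))
    i1 = int(round(t1 * p.sample_rate))
    return p.pressure[i0:i1]


def peak_levels(
    p: PressureSeries, window: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """Zero-to-peak and peak-to-peak levels of a pulse window, dB re p_ref.

    Returns ``(spl_zero_to_peak, spl_peak_to_peak)``.  For a symmetric
    waveform SPL_pp exceeds SPL_0p by 20·log10(2) ≈ 6.02 dB; for a one-
    sided spike the two coincide.
    """
    x = _window_slice(p, *(window or (0.0, p.duration)))
    if len(x) == 0 or np.all(x == 0):
        raise ValueError("all-zero window: peak level undefined")
    zero_to_peak = np.max(np.abs(x))
    peak_to_peak = np.max(x) - np.min(x)
    return (
        float(20.0 * np.log10(zero_to_peak / p.p_ref)),
        float(20.0 * np.log10(peak_to_peak / p.p_ref)),
    )


def energy_envelope(
    p: PressureSeries,
    window: Optional[tuple[float, float]] = None,
    lo: float = 0.05,
    hi: float = 0.95,
) -> tuple[float, float, float, float]:
    """Cumulative-energy envelope of a pulse.

    The cumulative energy E(t) = Σ p²·Δt from the window start defines
    t5 (first sample with E ≥ lo·E_total) and t95 (first with E ≥ hi·E_total);
    tau90 = t95 − t5 is the standard pulse-duration measure.  Crossings use
    the first sample at-or-above threshold, so the bias is below one sample
    period and the energy fraction inside [t5, t95] is ≥ hi − lo by
    construction.

    Returns ``(t5, t95, tau90, sel_in_envelope)`` with times relative to
    the series start.
    """
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    t0, t1 = window or (0.0, p.duration)
    x = _window_slice(p, t0, t1)
    energy = np.cumsum(x**2) / p.sample_rate
    total = energy[-1] if len(energy) else 0.0
    if total <= 0:
        raise ValueError("zero total energy in window: envelope undefined")
    i5 = int(np.searchsorted(energy, lo * total))
    i95 = int(np.searchsorted(energy, hi * total))
    t5 = t0 + i5 / p.sample_rate
    t95 = t0 + (i95 + 1) / p.sample_rate  # crossing sample included
    sel_env = _sel(p, t5, t95)
    return t5, t95, t95 - t5, sel_env


def pulse_sel(
    p: PressureSeries, window: Optional[tuple[float, float]] = None
) -> float:
    """Sound exposure level of the pulse window, dB re p_ref²·s."""
    t0, t1 = window or (0.0, p.duration)
    return _sel(p, t0, t1)


def snr_check(
    p: PressureSeries,
    pulse_window: tuple[float, float],
    noise_window: tuple[float, float],
    threshold: float = SNR_THRESHOLD_DB,
) -> tuple[float, bool]:
    """Signal-to-noise ratio of a pulse against an adjacent noise window.

    SNR = RMS level of the pulse window − RMS level of the noise window,
    in dB.  The measurement is flagged valid when SNR ≥ ``threshold``
    (default 10 dB).  Windows must not overlap.
    """
    (p0, p1), (n0, n1) = pulse_window, noise_window
    if max(p0, n0) < min(p1, n1):
        raise ValueError(
            f"pulse window {pulse_window} overlaps noise window {noise_window}"
        )
    xs = _window_slice(p, p0, p1)
    xn = _window_slice(p, n0, n1)
    if len(xs) == 0 or len(xn) == 0:
        raise ValueError("degenerate pulse or noise window")
    ms_s = np.mean(xs**2)
    ms_n = np.mean(xn**2)
    if ms_n <= 0:
        raise ValueError("silent noise window: SNR undefined")
    snr = float(10.0 * np.log10(ms_s / ms_n))
    return snr, snr >= threshold


def _response_flatness_warning(
    p: PressureSeries, window: tuple[float, float], spec: CalibrationSpec
) -> None:
    """Warn when the chain response varies > 3 dB over the pulse's
    −10 dB spectral extent (peak amplitude would then be distorted)."""
    if spec is None or spec.frequency_response is None:
        return
    x = _window_slice(p, *window)
    spec_amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / p.sample_rate)
    peak = spec_amp.max()
    if peak <= 0:
        return
    extent = freqs[spec_amp >= peak * 10 ** (-10 / 20)]
    fr = np.asarray(spec.frequency_response, dtype=float)
    safe = np.clip(extent, fr[0, 0], fr[-1, 0])
    resp = np.interp(np.log10(np.maximum(safe, 1e-12)), np.log10(fr[:, 0]), fr[:, 1])
    if resp.max() - resp.min() > 3.0:
        warnings.warn(
            "recording-chain response varies by "
            f"{resp.max() - resp.min():.1f} dB across the pulse's -10 dB "
            "spectral extent; peak metrics may be distorted",
            stacklevel=3,
        )


def analyze_pulse(
    p: PressureSeries,
    pulse_window: tuple[float, float],
    noise_window: Optional[tuple[float, float]] = None,
    threshold: float = SNR_THRESHOLD_DB,
    calibration: Optional[CalibrationSpec] = None,
) -> PulseMetrics:
    """All pulse metrics for one event in a single call.

    SNR and validity are reported only when a ``noise_window`` is given.
    When a calibration spec with a frequency-response curve is supplied,
    a warning is issued if the chain is not flat (within 3 dB) over the
    pulse's peak frequency range.
    """
    spl_0p, spl_pp = peak_levels(p, pulse_window)
    t5, t95, tau90, sel_env = energy_envelope(p, pulse_window)
    metrics = PulseMetrics(
        spl_zero_to_peak=spl_0p,
        spl_peak_to_peak=spl_pp,
        sel_pulse=pulse_sel(p, pulse_window),
        sel_envelope=sel_env,
        t5=t5,
        t95=t95,
        tau90=tau90,
    )
    if noise_window is not None:
        metrics.snr, metrics.valid = snr_check(p, pulse_window, noise_window, threshold)
    if calibration is not None:
        _response_flatness_warning(p, pulse_window, calibration)
    return metrics
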