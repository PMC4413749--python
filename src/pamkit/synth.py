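"""Synthetic pressure signals and a recorder-chain simulator.

Every analysis operation in this package can be tested without field data:
this module generates pressure waveforms with exactly known ground truth
(tones of a requested SPL, noise of a requested spectral density, impulses
of a requested peak level, diel cycles) and simulates the forward
acquisition chain — sensitivity and gain scaling, additive self-noise,
clipping at full scale, quantization to a chosen bit depth — producing the
normalized audio that the calibration module then inverts.

Generation is deterministic: identical (parameters, seed) give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta
from typing import Any, Optional, Union

import numpy as np

from .audio_io import AudioSegment, CLIP_THRESHOLD
from .calibration import (
    REFERENCE_PRESSURE,
    CalibrationSpec,
    PressureSeries,
    combined_sensitivity,
)

__all__ = ["SynthSpec", "SyntheticSeries", "generate", "simulate_recorder"]

_KINDS = ("tone", "white_noise", "pink_noise", "impulse", "mixture", "diel_cycle")


@dataclass
class SynthSpec:
    """Recipe for one synthetic pressure signal.

    Parameters
    ----------
    kind : {"tone", "white_noise", "pink_noise", "impulse", "mixture", "diel_cycle"}
    duration : float, seconds
    sample_rate : float, Hz
    seed : int
        Seeds all randomness; same (parameters, seed) → identical output.
    domain : {"air", "water"}
        Sets the reference pressure the dB parameters refer to.
    parameters : dict, per kind
        tone: ``frequency`` Hz, ``spl`` dB re p_ref (RMS), ``phase`` rad.
        white_noise: ``psd_level`` dB re p_ref²/Hz (flat to Nyquist).
        pink_noise: ``psd_level`` dB re p_ref²/Hz at ``reference_hz``
        (default 1000); density falls 3 dB per octave (∝ 1/f).
        impulse: ``peak`` dB re p_ref zero-to-peak, ``decay_s`` envelope
        time constant, ``carrier_hz``, ``interval_s`` between pulse starts,
        ``first_s`` offset of the first pulse.
        diel_cycle: ``baseline`` dB re p_ref²/Hz white-noise density,
        ``day_offset`` dB added during ``day_hours`` (default (6, 18));
        requires ``start_time`` to be a datetime.
        mixture: ``components``: list of SynthSpec whose pressures sum.
    """

    kind: str
    duration: float
    sample_rate: float
    seed: int = 0
    domain: str = "water"
    parameters: dict[str, Any] = dc_field(default_factory=dict)
    start_time: Union[float, datetime] = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; choose from {_KINDS}")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.domain not in REFERENCE_PRESSURE:
            raise ValueError("domain must be 'air' or 'water'")

    @property
    def p_ref(self) -> float:
        return REFERENCE_PRESSURE[self.domain]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class SyntheticSeries(PressureSeries):
    """A generated pressure waveform carrying its ground truth.

    ``truth`` holds the machine-readable true values of the generated
    signal (SPL, PSD density level, peak level, …) for use as oracles.
    """

    truth: dict[str, Any] = dc_field(default_factory=dict)


def _tone(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    f = spec.parameters["frequency"]
    spl = spec.parameters["spl"]
    phase = spec.parameters.get("phase", 0.0)
    if not 0 < f < spec.sample_rate / 2:
        raise ValueError(f"tone frequency {f} Hz outside (0, Nyquist)")
    amp = np.sqrt(2.0) * spec.p_ref * 10.0 ** (spl / 20.0)
    t = np.arange(spec.n_samples) / spec.sample_rate
    return amp * np.sin(2 * np.pi * f * t + phase), {
        "spl_db": spl,
        "frequency_hz": f,
        "amplitude_upa": amp,
    }


def _white_noise(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    level = spec.parameters["psd_level"]
    # flat density D over [0, fs/2] → variance = 10^(D/10) p_ref² · fs/2
    var = 10.0 ** (level / 10.0) * spec.p_ref**2 * spec.sample_rate / 2.0
    x = rng.normal(0.0, np.sqrt(var), spec.n_samples)
    return x, {"psd_level_db": level, "variance_upa2": var}


def _pink_noise(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    level = spec.parameters["psd_level"]
    f_ref = spec.parameters.get("reference_hz", 1000.0)
    white, _ = _white_noise(
        SynthSpec(
            kind="white_noise",
            duration=spec.duration,
            sample_rate=spec.sample_rate,
            domain=spec.domain,
            parameters={"psd_level": level},
        ),
        rng,
    )
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(len(white), 1.0 / spec.sample_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = np.sqrt(f_ref / freqs[1:])  # PSD ∝ 1/f: −3 dB/octave
    x = np.fft.irfft(spectrum * shape, n=len(white))
    return x, {"psd_level_db_at_ref": level, "reference_hz": f_ref}


def _impulse(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    peak = spec.parameters["peak"]
    decay = spec.parameters.get("decay_s", 0.01)
    carrier = spec.parameters.get("carrier_hz", spec.sample_rate / 8)
    interval = spec.parameters.get("interval_s", spec.duration + 1)
    first = spec.parameters.get("first_s", 0.0)
    peak_upa = spec.p_ref * 10.0 ** (peak / 20.0)

    n = spec.n_samples
    x = np.zeros(n)
    # one pulse template: decaying sinusoid, scaled to the exact peak
    t_len = min(n, int(round(8 * decay * spec.sample_rate)) + 1)
    tt = np.arange(t_len) / spec.sample_rate
    template = np.exp(-tt / decay) * np.sin(2 * np.pi * carrier * tt)
    m = np.max(np.abs(template))
    if m <= 0:
        raise ValueError("degenerate impulse template (carrier or decay too small)")
    template = template * (peak_upa / m)

    start = first
    starts = []
    while start < spec.duration:
        i0 = int(round(start * spec.sample_rate))
        seg = template[: n - i0]
        x[i0 : i0 + len(seg)] += seg
        starts.append(start)
        start += interval
    return x, {
        "peak_db": peak,
        "peak_upa": peak_upa,
        "decay_s": decay,
        "carrier_hz": carrier,
        "pulse_starts_s": starts,
    }


def _diel_cycle(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    baseline = spec.parameters["baseline"]
    offset = spec.parameters["day_offset"]
    h0, h1 = spec.parameters.get("day_hours", (6, 18))
    if not isinstance(spec.start_time, datetime):
        raise ValueError("diel_cycle requires a datetime start_time")
    x, _ = _white_noise(
        SynthSpec(
            kind="white_noise",
            duration=spec.duration,
            sample_rate=spec.sample_rate,
            domain=spec.domain,
            parameters={"psd_level": baseline},
        ),
        rng,
    )
    secs = np.arange(spec.n_samples) / spec.sample_rate
    start_hour = (
        spec.start_time.hour
        + spec.start_time.minute / 60
        + spec.start_time.second / 3600
    )
    hours = (start_hour + secs / 3600.0) % 24.0
    day = (hours >= h0) & (hours < h1)
    x[day] *= 10.0 ** (offset / 20.0)
    return x, {
        "baseline_db": baseline,
        "day_offset_db": offset,
        "day_hours": (h0, h1),
    }


def generate(spec: SynthSpec) -> SyntheticSeries:
    """Generate a calibrated pressure waveform with known ground truth."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "tone":
        x, truth = _tone(spec)
    elif spec.kind == "white_noise":
        x, truth = _white_noise(spec, rng)
    elif spec.kind == "pink_noise":
        x, truth = _pink_noise(spec, rng)
    elif spec.kind == "impulse":
        x, truth = _impulse(spec)
    elif spec.kind == "diel_cycle":
        x, truth = _diel_cycle(spec, rng)
    elif spec.kind == "mixture":
        components = spec.parameters["components"]
        x = np.zeros(spec.n_samples)
        truth = {"components": []}
        for comp in components:
            if (comp.sample_rate, comp.n_samples) != (spec.sample_rate, spec.n_samples):
                raise ValueError("mixture components must share duration and rate")
            series = generate(comp)
            x = x + series.pressure
            truth["components"].append(series.truth)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.kind)
    return SyntheticSeries(
        pressure=x,
        sample_rate=spec.sample_rate,
        start_time=spec.start_time,
        p_ref=spec.p_ref,
        truth=truth,
    )


def simulate_recorder(
    p: PressureSeries,
    spec: CalibrationSpec,
    bit_depth: Union[int, str] = 16,
    self_noise_density: Optional[float] = None,
    seed: int = 0,
) -> AudioSegment:
    """Forward acquisition chain: pressure → normalized, quantized audio.

    Applies the chain sensitivity (``x = p · 10^(S/20)`` full-scale units),
    adds optional flat Gaussian self-noise of the given pressure-equivalent
    density (dB re p_ref²/Hz), clips at full scale, and quantizes to the
    requested bit depth.  The returned segment reports the clipped
    fraction.  ``apply_calibration`` with the same spec inverts the chain
    up to quantization and clipping.
    """
    s = combined_sensitivity(spec)
    scale = 10.0 ** (s / 20.0)
    pressure = p.pressure
    if self_noise_density is not None:
        rng = np.random.default_rng(seed)
        var = 10.0 ** (self_noise_density / 10.0) * spec.p_ref**2 * p.sample_rate / 2.0
        pressure = pressure + rng.normal(0.0, np.sqrt(var), len(pressure))
    x = pressure * scale

    if bit_depth == "float":
        clipped = x  # float recorders are assumed unclipped within range
        samples = np.asarray(clipped, dtype=np.float64)
    elif bit_depth in (16, 24, 32):
        full = 2.0 ** (bit_depth - 1)
        codes = np.clip(np.round(x * full), -full, full - 1)
        samples = codes / full
    else:
        raise ValueError(f"unsupported bit depth {bit_depth!r}")

    clipped_fraction = float(
        np.count_nonzero(np.abs(samples) >= CLIP_THRESHOLD) / max(len(samples), 1)
    )
    return AudioSegment(
        samples=samples,
        sample_rate=p.sample_rate,
        start_time=p.start_time,
        bit_depth=bit_depth,
        clipped_fraction=clipped_fraction,
    )
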