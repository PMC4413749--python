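"""Acquisition-chain calibration: normalized samples to absolute pressure.

A PAM system converts sound pressure to stored samples through three
stages: the transducer (microphone or hydrophone) turns pressure into
voltage with sensitivity *M* (dB re 1 V/µPa), a pre-amplifier adds gain
*G* (dB), and the ADC maps its full-scale input voltage onto the audio
file's full-scale code.  Calibration reverses that chain.  The combined
(end-to-end) sensitivity in dB re full-scale-per-µPa is

    S = M + G - 20*log10(V_adc_peak)

and the pressure waveform is ``p[n] = x[n] * 10**(-S/20)`` µPa for
normalized samples ``x``.  Alternatively *S* can be measured directly by
injecting a known reference signal at the transducer (e.g. a pistonphone
tone) and supplied as ``end_to_end_sensitivity``.

Real transducers produce far less than a volt per µPa, so *M* is a large
negative number.  Worked example: a hydrophone with M = -165 dB re 1 V/µPa,
G = 20 dB and a ±1 V ADC gives S = -145 dB re full-scale/µPa; a full-scale
sample then corresponds to 10**(145/20) ≈ 1.78e7 µPa ≈ 17.8 Pa.

Both domains use µPa as the pressure unit; only the reference pressure for
dB conversion differs (air: 20 µPa, water: 1 µPa).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .audio_io import AudioSegment, StartTime

__all__ = [
    "REFERENCE_PRESSURE",
    "CalibrationSpec",
    "PressureSeries",
    "combined_sensitivity",
    "apply_calibration",
    "apply_frequency_response",
    "load_calibration",
    "save_calibration",
    "load_frequency_response",
]

#: Reference pressures in µPa: nominal human hearing threshold at 1 kHz in
#: air; the conventional 1 µPa underwater.
REFERENCE_PRESSURE = {"air": 20.0, "water": 1.0}


@dataclass
class CalibrationSpec:
    """Parameters mapping dimensionless samples to sound pressure.

    Exactly one parameterization must be given: either the component chain
    (``transducer_sensitivity``, ``gain``, ``adc_peak_voltage``) or a
    measured ``end_to_end_sensitivity`` that overrides the components.

    Parameters
    ----------
    domain : {"air", "water"}
        Selects the reference pressure (air: 20 µPa, water: 1 µPa).
    transducer_sensitivity : float, optional
        M, dB re 1 V/µPa.  Negative for real transducers.
    gain : float, optional
        G, pre-amplifier gain in dB.
    adc_peak_voltage : float, optional
        Zero-to-peak ADC input voltage corresponding to full scale, volts.
    end_to_end_sensitivity : float, optional
        S, dB re full-scale-per-µPa, measured by injecting a known signal.
    frequency_response : sequence of (Hz, dB) pairs, optional
        Relative response of the chain versus frequency; frequencies must
        be strictly increasing.
    """

    domain: str = "water"
    transducer_sensitivity: Optional[float] = None
    gain: Optional[float] = None
    adc_peak_voltage: Optional[float] = None
    end_to_end_sensitivity: Optional[float] = None
    frequency_response: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.domain not in REFERENCE_PRESSURE:
            raise ValueError(f"domain must be 'air' or 'water', got {self.domain!r}")
        components = (
            self.transducer_sensitivity is not None
            and self.gain is not None
            and self.adc_peak_voltage is not None
        )
        any_component = any(
            v is not None
            for v in (self.transducer_sensitivity, self.gain, self.adc_peak_voltage)
        )
        if self.end_to_end_sensitivity is not None and any_component:
            raise ValueError(
                "give either end_to_end_sensitivity or the component chain "
                "(transducer_sensitivity, gain, adc_peak_voltage), not both"
            )
        if self.end_to_end_sensitivity is None and not components:
            missing = [
                name
                for name, v in (
                    ("transducer_sensitivity", self.transducer_sensitivity),
                    ("gain", self.gain),
                    ("adc_peak_voltage", self.adc_peak_voltage),
                )
                if v is None
            ]
            raise ValueError(
                "calibration requires end_to_end_sensitivity or all of the "
                f"component chain; missing: {', '.join(missing)}"
            )
        if components and self.adc_peak_voltage <= 0:
            raise ValueError("adc_peak_voltage must be positive")
        if self.frequency_response is not None:
            fr = np.asarray(self.frequency_response, dtype=float)
            if fr.ndim != 2 or fr.shape[1] != 2 or len(fr) < 1:
                raise ValueError("frequency_response must be (Hz, dB) pairs")
            if np.any(np.diff(fr[:, 0]) <= 0):
                raise ValueError("frequency_response frequencies must be strictly increasing")
            self.frequency_response = [tuple(row) for row in fr]

    @property
    def p_ref(self) -> float:
        """Reference pressure in µPa for this domain."""
        return REFERENCE_PRESSURE[self.domain]


@dataclass
class PressureSeries:
    """A calibrated pressure waveform.

    Attributes
    ----------
    pressure : ndarray
        Instantaneous sound pressure in µPa.
    sample_rate : float
        Hz.
    start_time : float or datetime
        Offset seconds or absolute timestamp.
    p_ref : float
        Reference pressure in µPa used for dB conversion downstream.
    clipped_fraction : float
        Carried over from the source audio.
    """

    pressure: np.ndarray
    sample_rate: float
    start_time: StartTime = 0.0
    p_ref: float = 1.0
    clipped_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure must be finite everywhere")

    @property
    def duration(self) -> float:
        return len(self.pressure) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to start_time."""
        return np.arange(len(self.pressure)) / self.sample_rate

    def slice_seconds(self, t0: float, t1: float) -> "PressureSeries":
        """Sub-series covering [t0, t1) seconds relative to the start."""
        if not 0 <= t0 < t1 <= self.duration + 1e-12:
            raise ValueError(f"window ({t0}, {t1}) outside series of {self.duration} s")
        i0 = int(round(t0 * self.sample_rate))
        i1 = int(round(t1 * self.sample_rate))
        return replace(self, pressure=self.pressure[i0:i1])


def combined_sensitivity(spec: CalibrationSpec) -> float:
    """End-to-end sensitivity S in dB re full-scale-per-µPa.

    Returns ``M + G - 20*log10(adc_peak_voltage)`` from the component
    chain, or ``end_to_end_sensitivity`` verbatim when supplied.
    """
    if spec.end_to_end_sensitivity is not None:
        return float(spec.end_to_end_sensitivity)
    return float(
        spec.transducer_sensitivity
        + spec.gain
        - 20.0 * np.log10(spec.adc_peak_voltage)
    )


def apply_calibration(seg: AudioSegment, spec: CalibrationSpec) -> PressureSeries:
    """Convert a normalized audio segment to absolute pressure (flat case).

    ``pressure[n] = (samples[n] - mean) * 10**(-S/20)`` µPa.  The segment
    mean is removed first: a DC offset is an acquisition artefact that would
    otherwise corrupt the lowest PSD bins.
    """
    s = combined_sensitivity(spec)
    x = seg.samples
    if len(x):
        x = x - x.mean()
    return PressureSeries(
        pressure=x * 10.0 ** (-s / 20.0),
        sample_rate=seg.sample_rate,
        start_time=seg.start_time,
        p_ref=spec.p_ref,
        clipped_fraction=seg.clipped_fraction,
    )


def apply_frequency_response(
    levels: np.ndarray,
    frequencies: np.ndarray,
    spec: CalibrationSpec,
    out_of_range: str = "clamp",
) -> np.ndarray:
    """Apply frequency-dependent corrections to spectrum levels (dB).

    The chain's relative response curve is interpolated linearly in dB
    versus log-frequency (matching how response curves are tabulated on
    log-frequency datasheets) and subtracted bin by bin from ``levels``.

    Parameters
    ----------
    levels : array of dB values at ``frequencies``
    frequencies : array of Hz, positive where corrected
    spec : CalibrationSpec with ``frequency_response`` set
    out_of_range : {"clamp", "error"}
        Frequencies outside the curve's range use the end values (with a
        warning), or raise.
    """
    if spec.frequency_response is None:
        raise ValueError("CalibrationSpec has no frequency_response curve")
    fr = np.asarray(spec.frequency_response, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    levels = np.asarray(levels, dtype=float)

    outside = (freqs < fr[0, 0]) | (freqs > fr[-1, 0])
    if np.any(outside):
        if out_of_range == "error":
            raise ValueError(
                f"{np.count_nonzero(outside)} analysis frequencies outside the "
                f"response curve range [{fr[0, 0]}, {fr[-1, 0]}] Hz"
            )
        warnings.warn(
            f"{np.count_nonzero(outside)} analysis frequencies outside the "
            "frequency-response curve; clamping to end values",
            stacklevel=2,
        )
    # log-f interpolation; zero/negative frequencies clamp to the first point
    safe = np.where(freqs > 0, freqs, fr[0, 0])
    correction = np.interp(np.log10(safe), np.log10(fr[:, 0]), fr[:, 1])
    return levels - correction


# -- serialisation ----------------------------------------------------------

def save_calibration(spec: CalibrationSpec, path) -> None:
    """Write a CalibrationSpec as a flat JSON config."""
    d = {
        "domain": spec.domain,
        "transducer_sensitivity": spec.transducer_sensitivity,
        "gain": spec.gain,
        "adc_peak_voltage": spec.adc_peak_voltage,
        "end_to_end_sensitivity": spec.end_to_end_sensitivity,
        "frequency_response": spec.frequency_response,
    }
    Path(path).write_text(json.dumps({k: v for k, v in d.items() if v is not None}, indent=2))


def load_calibration(path) -> CalibrationSpec:
    """Read a CalibrationSpec from a flat JSON config.

    ``frequency_response`` may be inline pairs or the name of a two-column
    CSV (Hz, dB) resolved relative to the config file.
    """
    path = Path(path)
    d = json.loads(path.read_text())
    fr = d.get("frequency_response")
    if isinstance(fr, str):
        d["frequency_response"] = load_frequency_response(path.parent / fr)
    elif fr is not None:
        d["frequency_response"] = [tuple(p) for p in fr]
    return CalibrationSpec(**d)


def load_frequency_response(path) -> list[tuple[float, float]]:
    """Read a two-column (Hz, dB) CSV response curve; a header row is skipped."""
    pairs: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                pairs.append((float(row[0]), float(row[1])))
            except ValueError:
                if pairs:
                    raise
                continue  # header
    if not pairs:
        raise ValueError(f"{path}: no (Hz, dB) rows found")
    return pairs
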