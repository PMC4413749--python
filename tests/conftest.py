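import numpy as np
import pytest

from pamkit import CalibrationSpec, PressureSeries


@pytest.fixture
def water_spec():
    """Hydrophone chain: M = -165 dB re 1 V/µPa, G = 20 dB, ±1 V ADC (S = -145)."""
    return CalibrationSpec(
        domain="water",
        transducer_sensitivity=-165.0,
        gain=20.0,
        adc_peak_voltage=1.0,
    )


@pytest.fixture
def air_spec():
    """Microphone chain specified end-to-end: S = -40 dB re FS/µPa."""
    return CalibrationSpec(domain="air", end_to_end_sensitivity=-40.0)


def make_series(pressure, sample_rate=1000.0, p_ref=1.0, **kw):
    return PressureSeries(
        pressure=np.asarray(pressure, dtype=float),
        sample_rate=sample_rate,
        p_ref=p_ref,
        **kw,
    )


@pytest.fixture
def sine_series():
    """2 s, 1 kHz sine at 94 dB re 1 µPa RMS, fs = 8 kHz."""
    fs = 8000.0
    amp = np.sqrt(2.0) * 10 ** (94.0 / 20.0)
    t = np.arange(int(2 * fs)) / fs
    return make_series(amp * np.sin(2 * np.pi * 1000.0 * t), sample_rate=fs)
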