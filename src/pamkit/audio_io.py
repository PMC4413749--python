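"""Reading WAV recordings into normalized sample streams.

Autonomous recorders package digitised sound as RIFF/WAVE audio with a
standardised amplitude range (a 16-bit recording holds integers between
-32768 and 32767).  This module normalises those integer codes to
dimensionless full-scale units in [-1, 1], flags saturated (clipped)
samples, chunks long recordings into segments, and recovers absolute
recording start times from filename conventions.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterator, Union

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "read_wav",
    "write_wav",
    "stream_segments",
    "parse_timestamp",
    "format_timestamp",
    "CLIP_THRESHOLD",
]

#: |normalized sample| at or above this value counts as saturated.  Recorders
#: with analogue limiters rarely produce codes at exact full scale, so the
#: threshold sits slightly below 1.0.
CLIP_THRESHOLD = 0.99

# WAVE format tags we accept
_WAVE_FORMAT_PCM = 0x0001
_WAVE_FORMAT_IEEE_FLOAT = 0x0003
_WAVE_FORMAT_EXTENSIBLE = 0xFFFE

StartTime = Union[float, datetime]


@dataclass
class AudioSegment:
    """A block of normalized audio samples with acquisition metadata.

    Attributes
    ----------
    samples : ndarray
        Dimensionless full-scale samples in [-1, 1] (float64).
    sample_rate : float
        Sampling rate in Hz.
    start_time : float or datetime
        Offset in seconds from the start of the file, or an absolute
        timestamp when one is known.
    bit_depth : int or "float"
        Bits per sample of the source encoding (16, 24, 32) or the string
        ``"float"`` for IEEE float data.
    clipped_fraction : float
        Fraction of samples with magnitude at or above ``CLIP_THRESHOLD``.
    partial : bool
        True when this is a final segment shorter than the requested
        segment length.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: StartTime = 0.0
    bit_depth: Union[int, str] = "float"
    clipped_fraction: float = field(default=0.0)
    partial: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.bit_depth not in (16, 24, 32, "float"):
            raise ValueError(f"unsupported bit depth {self.bit_depth!r}")

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self.samples) / self.sample_rate

    def with_time(self, start_time: StartTime) -> "AudioSegment":
        return replace(self, start_time=start_time)


def _clipped_fraction(x: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    return float(np.count_nonzero(np.abs(x) >= CLIP_THRESHOLD) / len(x))


def _peek_format(path) -> tuple[int, int, int]:
    """Return (format_tag, bits_per_sample, n_channels) from the fmt chunk.

    scipy decodes the sample data; this peek only recovers the declared bit
    depth, which scipy's dtype alone cannot distinguish (24-bit PCM is
    delivered left-justified in int32).
    """
    with open(path, "rb") as fh:
        riff = fh.read(12)
        if len(riff) < 12 or riff[:4] != b"RIFF" or riff[8:12] != b"WAVE":
            raise ValueError(f"{path}: not a RIFF/WAVE file")
        while True:
            header = fh.read(8)
            if len(header) < 8:
                raise ValueError(f"{path}: no fmt chunk found")
            chunk_id, size = header[:4], struct.unpack("<I", header[4:])[0]
            if chunk_id == b"fmt ":
                data = fh.read(size)
                tag, n_ch, _rate, _bps, _align, bits = struct.unpack(
                    "<HHIIHH", data[:16]
                )
                if tag == _WAVE_FORMAT_EXTENSIBLE and size >= 26:
                    # actual format lives in the extension's SubFormat GUID
                    tag = struct.unpack("<H", data[24:26])[0]
                return tag, bits, n_ch
            fh.seek(size + (size & 1), 1)  # chunks are word-aligned


def read_wav(path, channel: int = 0) -> AudioSegment:
    """Read a WAV file into a normalized mono :class:`AudioSegment`.

    Integer codes are divided by the positive full-scale code of the
    declared bit depth, ``2**(bits-1)``, so the most negative code maps to
    exactly -1.0 (a 16-bit code of -32768 becomes -1.0).  IEEE-float data
    is passed through unchanged.

    Parameters
    ----------
    path : path-like
        RIFF/WAVE file with PCM 16/24/32-bit or IEEE float-32 encoding.
    channel : int
        Channel to extract from multi-channel files (default 0).
    """
    path = Path(path)
    tag, bits, n_ch = _peek_format(path)
    if tag == _WAVE_FORMAT_PCM and bits in (16, 24, 32):
        bit_depth: Union[int, str] = bits
    elif tag == _WAVE_FORMAT_IEEE_FLOAT and bits in (32, 64):
        bit_depth = "float"
    else:
        raise ValueError(
            f"{path}: unsupported WAV encoding (format tag 0x{tag:04x}, "
            f"{bits} bits per sample); supported: PCM 16/24/32-bit, IEEE float"
        )

    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel >= data.shape[1]:
            raise ValueError(
                f"{path}: channel {channel} requested but file has "
                f"{data.shape[1]} channels"
            )
        data = data[:, channel]
    elif channel != 0:
        raise ValueError(f"{path}: channel {channel} requested from a mono file")

    if bit_depth == "float":
        samples = np.asarray(data, dtype=np.float64)
    elif data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        # scipy left-justifies 24-bit codes into int32, so a single divisor
        # of 2**31 normalises both 24- and 32-bit PCM to code / 2**(bits-1)
        samples = data / 2.0**31
    else:  # pragma: no cover - guarded by _peek_format
        raise ValueError(f"{path}: unexpected sample dtype {data.dtype}")

    return AudioSegment(
        samples=samples,
        sample_rate=float(rate),
        start_time=0.0,
        bit_depth=bit_depth,
        clipped_fraction=_clipped_fraction(samples),
    )


def write_wav(path, seg: AudioSegment, bit_depth: Union[int, str, None] = None) -> None:
    """Write an :class:`AudioSegment` to a WAV file.

    Supported encodings: 16-bit PCM and IEEE float-32.  Integer output
    quantizes ``round(sample * 2**(bits-1))`` clipped to the code range, the
    inverse of the :func:`read_wav` normalization.
    """
    if bit_depth is None:
        bit_depth = seg.bit_depth if seg.bit_depth in (16, "float") else 16
    if bit_depth == 16:
        codes = np.clip(np.round(seg.samples * 2.0**15), -(2**15), 2**15 - 1)
        wavfile.write(str(path), int(seg.sample_rate), codes.astype(np.int16))
    elif bit_depth == "float":
        wavfile.write(str(path), int(seg.sample_rate), seg.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported output bit depth {bit_depth!r}")


def stream_segments(
    path, segment_seconds: float, channel: int = 0
) -> Iterator[AudioSegment]:
    """Yield contiguous, non-overlapping segments covering a WAV file.

    Segments are ``segment_seconds`` long; the final segment is emitted even
    when shorter and is marked ``partial``.  ``start_time`` advances by
    exactly one segment length per segment.  Concatenating the yielded
    samples reproduces :func:`read_wav` exactly.
    """
    if segment_seconds <= 0:
        raise ValueError(f"segment_seconds must be positive, got {segment_seconds}")
    whole = read_wav(path, channel=channel)
    n_seg = int(np.ceil(len(whole.samples) / (segment_seconds * whole.sample_rate)))
    step = int(round(segment_seconds * whole.sample_rate))
    for i in range(n_seg):
        chunk = whole.samples[i * step : (i + 1) * step]
        yield AudioSegment(
            samples=chunk,
            sample_rate=whole.sample_rate,
            start_time=i * segment_seconds,
            bit_depth=whole.bit_depth,
            clipped_fraction=_clipped_fraction(chunk),
            partial=len(chunk) < step,
        )


# -- filename timestamps ----------------------------------------------------

def parse_timestamp(filename: str, pattern: str) -> datetime:
    """Recover a recording start time from its filename.

    ``pattern`` is a ``strftime``-style descriptor of the whole base name,
    e.g. ``"REC_%Y%m%d_%H%M%S.wav"`` matches ``"REC_20131019_120000.wav"``
    and yields 2013-10-19 12:00:00.

    Raises
    ------
    ValueError
        If the filename does not match the pattern; the message names both.
    """
    name = Path(filename).name
    try:
        return datetime.strptime(name, pattern)
    except ValueError as exc:
        raise ValueError(
            f"filename {name!r} does not match timestamp pattern {pattern!r}: {exc}"
        ) from None


def format_timestamp(t: datetime, pattern: str) -> str:
    """Inverse of :func:`parse_timestamp`: render a start time as a filename."""
    return t.strftime(pattern)
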