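"""Minimal European Data Format (EDF) writer/reader for continuous signals.

Implements the plain EDF variant: one ASCII header (256 bytes plus 256 per
signal) followed by fixed-duration data records of little-endian 16-bit
integers, scaled per channel between the declared physical and digital
ranges.  One-second records are used; the signal is zero-padded to a whole
number of records on write and the true sample count is stored in the
header's reserved field so reads round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["EDFError", "write_edf", "read_edf", "quantization_step"]


class EDFError(ValueError):
    """Malformed or truncated EDF content."""


_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    data = value.encode("ascii")
    if len(data) > width:
        raise EDFError(f"header field {value!r} exceeds {width} bytes")
    return data.ljust(width)


def _num(value: float, width: int) -> bytes:
    # prefer plain decimal notation; fall back to exponent form for extreme
    # magnitudes (readable by any float parser)
    for allow_exp in (False, True):
        for precision in range(width, -1, -1):
            text = f"{value:.{precision}g}"
            if len(text) <= width and (allow_exp or "e" not in text.lower()):
                return _ascii(text, width)
    raise EDFError(f"cannot format {value} in {width} bytes")


def quantization_step(physical_min: float, physical_max: float) -> float:
    return (physical_max - physical_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    labels: list[str],
) -> None:
    """Write channels x samples to an EDF file with one-second data records."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_channels, n_samples = signals.shape
    if len(labels) != n_channels:
        raise ValueError(f"{len(labels)} labels for {n_channels} channels")
    if fs <= 0 or fs != int(fs):
        raise ValueError(f"fs must be a positive integer sample rate, got {fs}")
    spr = int(fs)  # samples per 1 s record
    n_records = max(1, -(-n_samples // spr))
    padded = np.zeros((n_channels, n_records * spr))
    padded[:, :n_samples] = signals

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min == 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    # Widen slightly, then quantize against the ranges as they survive the
    # 8-character ASCII header fields, so the reader's reconstruction matches
    # the writer's and no sample falls outside the declared range.
    span = phys_max - phys_min
    phys_min = phys_min - 1e-4 * span
    phys_max = phys_max + 1e-4 * span
    phys_min = np.array([float(_num(v, 8).decode()) for v in phys_min])
    phys_max = np.array([float(_num(v, 8).decode()) for v in phys_max])

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),  # patient id (synthetic data)
            _ascii("X", 80),  # recording id
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + n_channels)), 8),
            _ascii(f"NSAMP={n_samples}", 44),  # reserved: true sample count
            _ascii(str(n_records), 8),
            _num(1.0, 8),  # record duration s
            _ascii(str(n_channels), 4),
        ]
    )
    header += b"".join(_ascii(label, 16) for label in labels)
    header += b"".join(_ascii("", 80) for _ in labels)  # transducer
    header += b"".join(_ascii("uV", 8) for _ in labels)  # physical dimension
    header += b"".join(_num(v, 8) for v in phys_min)
    header += b"".join(_num(v, 8) for v in phys_max)
    header += b"".join(_ascii(str(_DIG_MIN), 8) for _ in labels)
    header += b"".join(_ascii(str(_DIG_MAX), 8) for _ in labels)
    header += b"".join(_ascii("", 80) for _ in labels)  # prefiltering
    header += b"".join(_ascii(str(spr), 8) for _ in labels)
    header += b"".join(_ascii("", 32) for _ in labels)  # per-signal reserved

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as handle:
        handle.write(header)
        for record in range(n_records):
            chunk = digital[:, record * spr : (record + 1) * spr]
            handle.write(chunk.tobytes())  # channel-major within each record


def _field(raw: bytes, offset: int, width: int) -> str:
    return raw[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples, fs, labels)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EDFError(f"{path}: file shorter than the 256-byte EDF header")
    try:
        header_bytes = int(_field(raw, 184, 8))
        n_records = int(_field(raw, 236, 8))
        record_duration = float(_field(raw, 244, 8))
        n_channels = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EDFError(f"{path}: malformed EDF header ({exc})") from None
    if len(raw) < header_bytes:
        raise EDFError(f"{path}: truncated header ({len(raw)} < {header_bytes} bytes)")

    def signal_field(base: int, width: int, conv):
        out = []
        for ch in range(n_channels):
            text = _field(raw, base + ch * width, width)
            try:
                out.append(conv(text))
            except ValueError as exc:
                raise EDFError(
                    f"{path}: malformed header for channel {ch} ({text!r}: {exc})"
                ) from None
        return out

    base = 256
    labels = signal_field(base, 16, str)
    base += n_channels * (16 + 80 + 8)
    phys_min = np.array(signal_field(base, 8, float))
    base += n_channels * 8
    phys_max = np.array(signal_field(base, 8, float))
    base += n_channels * 8
    dig_min = np.array(signal_field(base, 8, float))
    base += n_channels * 8
    dig_max = np.array(signal_field(base, 8, float))
    base += n_channels * (8 + 80)
    spr_list = signal_field(base, 8, int)
    if len(set(spr_list)) != 1:
        raise EDFError(f"{path}: mixed sampling rates not supported: {spr_list}")
    spr = spr_list[0]

    expected = header_bytes + n_records * n_channels * spr * 2
    if len(raw) < expected:
        raise EDFError(
            f"{path}: truncated data section ({len(raw)} bytes, expected {expected}; "
            f"{n_channels} channels x {n_records} records x {spr} samples)"
        )

    body = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    body = body.reshape(n_records, n_channels, spr)
    digital = body.transpose(1, 0, 2).reshape(n_channels, n_records * spr).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    signals = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    reserved = _field(raw, 192, 44)
    if reserved.startswith("NSAMP="):
        n_samples = int(reserved[6:])
        signals = signals[:, :n_samples]
    fs = spr / record_duration
    return signals, fs, labels
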