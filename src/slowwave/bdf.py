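"""BioSemi BDF file support.

BDF is the 24-bit variant of the European Data Format used by the BioSemi
ActiveTwo acquisition system: an 8-byte magic (0xFF then ``BIOSEMI``), a
256-byte main header, 256 header bytes per channel, then fixed-duration data
records of 24-bit little-endian two's-complement samples, channel-major
within each record.

Only the BioSemi dialect is accepted; other EDF variants are rejected rather
than guessed.  Physical units are taken to be microvolts.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .core import Recording, SlowWaveError

BDF_MAGIC = b"\xffBIOSEMI"
DIG_MIN = -8388608
DIG_MAX = 8388607
#: default physical range (uV) giving the native BioSemi LSB of ~0.03125 uV
PHYS_MIN = -262144.0
PHYS_MAX = 262143.0


def _decode_24bit(raw: bytes) -> np.ndarray:
    """24-bit little-endian two's complement -> int32 array."""
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    val = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    return val - ((val & 0x800000) << 1)


def _encode_24bit(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int64)
    if v.min(initial=0) < DIG_MIN or v.max(initial=0) > DIG_MAX:
        raise SlowWaveError("digital value outside 24-bit range")
    u = (v & 0xFFFFFF).astype(np.uint32)
    out = np.empty((u.size, 3), dtype=np.uint8)
    out[:, 0] = u & 0xFF
    out[:, 1] = (u >> 8) & 0xFF
    out[:, 2] = (u >> 16) & 0xFF
    return out.tobytes()


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise SlowWaveError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _num_field(x: float, width: int) -> bytes:
    if float(x) == int(x):
        s = str(int(x))
    else:
        s = repr(float(x))
        if len(s) > width:
            s = f"{x:.{max(1, width - 6)}g}"
    return _field(s, width)


def write_bdf(recording: Recording, path: str | Path) -> None:
    """Write a recording as a BioSemi BDF file.

    Records are 1 s long when the sample count divides evenly into whole
    seconds; otherwise a single record spanning the whole recording is
    written.  Values outside the representable physical range raise an
    error naming the offending channel and sample.
    """
    fs = recording.fs
    n = recording.n_samples
    bad = np.argwhere(
        (recording.samples < PHYS_MIN) | (recording.samples > PHYS_MAX)
        | ~np.isfinite(recording.samples)
    )
    if bad.size:
        ch_i, s_i = bad[0]
        raise SlowWaveError(
            f"sample out of physical range [{PHYS_MIN}, {PHYS_MAX}] uV on channel "
            f"{recording.channel_ids[ch_i]!r} at sample index {s_i}"
        )
    if fs == int(fs) and n % int(fs) == 0:
        record_dur = 1.0
        spr = int(fs)
    else:
        record_dur = n / fs
        spr = n
    n_records = n // spr
    nch = recording.n_channels

    gain = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)
    digital = np.rint((recording.samples - PHYS_MIN) / gain).astype(np.int64) + DIG_MIN

    header = bytearray()
    header += BDF_MAGIC
    header += _field("", 80)                      # local subject id
    header += _field("", 80)                      # local recording id
    header += _field("01.01.00", 8)               # start date
    header += _field("00.00.00", 8)               # start time
    header += _num_field(256 * (nch + 1), 8)      # header byte count
    header += _field("24BIT", 44)                 # BioSemi data-format version
    header += _num_field(n_records, 8)
    header += _num_field(record_dur, 8)
    header += _num_field(nch, 4)
    for ch in recording.channel_ids:
        header += _field(ch, 16)
    header += _field("", 80) * nch                # transducer
    header += _field("uV", 8) * nch               # physical dimension
    header += _num_field(PHYS_MIN, 8) * nch
    header += _num_field(PHYS_MAX, 8) * nch
    header += _num_field(DIG_MIN, 8) * nch
    header += _num_field(DIG_MAX, 8) * nch
    header += _field("", 80) * nch                # prefiltering
    header += _num_field(spr, 8) * nch
    header += _field("", 32) * nch                # reserved

    with open(path, "wb") as f:
        f.write(bytes(header))
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch_i in range(nch):
                f.write(_encode_24bit(digital[ch_i, sl]))


def read_bdf(path: str | Path) -> Recording:
    """Read a BioSemi BDF file into a :class:`Recording` in microvolts.

    Data record blocks are concatenated in order; samples are scaled to
    physical units via each channel's calibration fields.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise SlowWaveError(f"{path}: too short to hold a BDF header")
    if raw[:8] != BDF_MAGIC:
        raise SlowWaveError(
            f"{path}: not a BioSemi BDF file (bad magic {raw[:8]!r}); "
            "other EDF variants are not supported"
        )

    def s(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    header_bytes = int(s(184, 192))
    n_records = int(s(236, 244))
    record_dur = float(s(244, 252))
    nch = int(s(252, 256))
    if nch < 1:
        raise SlowWaveError(f"{path}: no channels in header")
    if len(raw) < header_bytes:
        raise SlowWaveError(f"{path}: truncated header ({len(raw)} < {header_bytes} bytes)")

    def ch_fields(offset: int, width: int) -> list[str]:
        base = 256 + offset * nch
        return [s(base + i * width, base + (i + 1) * width) for i in range(nch)]

    labels = ch_fields(0, 16)
    # per-channel field offsets within the channel header block
    off = {"phys_min": 16 + 80 + 8, "phys_max": 16 + 80 + 16,
           "dig_min": 16 + 80 + 24, "dig_max": 16 + 80 + 32,
           "spr": 16 + 80 + 40 + 80}
    phys_min = [float(v) for v in ch_fields(off["phys_min"], 8)]
    phys_max = [float(v) for v in ch_fields(off["phys_max"], 8)]
    dig_min = [int(float(v)) for v in ch_fields(off["dig_min"], 8)]
    dig_max = [int(float(v)) for v in ch_fields(off["dig_max"], 8)]
    spr = [int(v) for v in ch_fields(off["spr"], 8)]

    if len(set(spr)) != 1:
        raise SlowWaveError(
            f"{path}: mixed per-channel sampling rates {sorted(set(spr))} are unsupported"
        )
    spr0 = spr[0]
    for i in range(nch):
        if phys_min[i] == phys_max[i]:
            raise SlowWaveError(
                f"{path}: degenerate calibration on channel {labels[i]!r} "
                f"(physical_min == physical_max == {phys_min[i]})"
            )
    fs = spr0 / record_dur

    record_bytes = nch * spr0 * 3
    body = raw[header_bytes:]
    complete = len(body) // record_bytes
    if n_records < 0:
        n_records = complete
    if complete < n_records:
        raise SlowWaveError(
            f"{path}: truncated data — header promises {n_records} records but only "
            f"{complete} complete records are present (last complete record: {complete})"
        )

    samples = np.empty((nch, n_records * spr0), dtype=float)
    for rec in range(n_records):
        block = body[rec * record_bytes:(rec + 1) * record_bytes]
        digital = _decode_24bit(block).reshape(nch, spr0)
        samples[:, rec * spr0:(rec + 1) * spr0] = digital
    for i in range(nch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        samples[i] = (samples[i] - dig_min[i]) * gain + phys_min[i]

    return Recording(samples=samples, fs=fs, channel_ids=labels)
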