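"""Minimal EDF writer for generating synthetic test fixtures.

Only what the import tests need: uniform sampling rate, 16-bit encoding,
one data record per second.  This is fixture-generation code; reading EDF in
the package always goes through mne.
"""

from __future__ import annotations

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    assert len(b) <= width, text
    return b.ljust(width)


def write_edf(path, data_uv: np.ndarray, channel_names: list[str],
              sampling_rate: int) -> None:
    """Write microvolt data (M x N) as a plain EDF file."""
    data_uv = np.asarray(data_uv, dtype=float)
    m, n = data_uv.shape
    assert len(channel_names) == m
    spr = int(sampling_rate)  # samples per 1 s record
    n_records = n // spr
    assert n_records * spr == n, "length must be a whole number of 1 s records"

    phys_min, phys_max = -5000.0, 5000.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _field("0", 8)                      # version
    header += _field("X X X X", 80)               # patient id
    header += _field("Startdate X", 80)           # recording id
    header += _field("01.01.20", 8)               # start date
    header += _field("00.00.00", 8)               # start time
    header += _field(str(256 * (1 + m)), 8)       # header bytes
    header += _field("", 44)                      # reserved
    header += _field(str(n_records), 8)
    header += _field("1", 8)                      # record duration (s)
    header += _field(str(m), 4)

    def per_channel(values, width):
        return b"".join(_field(v, width) for v in values)

    header += per_channel(channel_names, 16)
    header += per_channel(["" for _ in range(m)], 80)      # transducer
    header += per_channel(["uV"] * m, 8)
    header += per_channel([f"{phys_min:g}"] * m, 8)
    header += per_channel([f"{phys_max:g}"] * m, 8)
    header += per_channel([str(dig_min)] * m, 8)
    header += per_channel([str(dig_max)] * m, 8)
    header += per_channel([""] * m, 80)                     # prefiltering
    header += per_channel([str(spr)] * m, 8)
    header += per_channel([""] * m, 32)                     # reserved

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data_uv - phys_min) * gain + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            f.write(chunk.tobytes())  # channel-sequential within record
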