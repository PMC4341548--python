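from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from ectmse.io import TimeSeriesSegment
from ectmse.synth import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_segment(rng):
    """A 10 s white-noise segment at 500 Hz."""
    return TimeSeriesSegment(
        samples=20.0 * rng.standard_normal(5000),
        sampling_rate_hz=500.0,
        channel="C3",
    )


@pytest.fixture
def tiny_study_cfg():
    """A fast surrogate study: one session per condition, 4 s segments."""
    return GeneratorConfig(
        seed=7,
        segment_s=4.0,
        n_sessions_per_condition={
            "pre_ect": 1, "during_ect": 1, "after_ect": 1, "lorazepam": 1
        },
    )


def write_minimal_edf(
    path: Path,
    labels: list[str],
    data: np.ndarray,
    rate_hz: int = 500,
) -> Path:
    """Write a minimal single-record EDF file (synthetic test input).

    One data record spanning the whole signal, 16-bit samples, physical
    range chosen so integer microvolt values round-trip exactly.
    """
    n_sig = len(labels)
    n_samp = data.shape[1]
    dur_s = n_samp / rate_hz
    header = b""
    header += b"0".ljust(8)
    header += b"X X X X".ljust(80)  # patient id (anonymous)
    header += b"Startdate X X X X".ljust(80)
    header += b"01.01.20".ljust(8) + b"00.00.00".ljust(8)
    header += str(256 + 256 * n_sig).encode().ljust(8)
    header += b"".ljust(44)
    header += b"1".ljust(8)  # one data record
    header += f"{dur_s:g}".encode().ljust(8)
    header += str(n_sig).encode().ljust(4)

    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767

    def field(vals, width):
        return b"".join(str(v).encode().ljust(width) for v in vals)

    header += field(labels, 16)
    header += field([""] * n_sig, 80)  # transducer
    header += field(["uV"] * n_sig, 8)
    header += field([phys_min] * n_sig, 8)
    header += field([phys_max] * n_sig, 8)
    header += field([dig_min] * n_sig, 8)
    header += field([dig_max] * n_sig, 8)
    header += field([""] * n_sig, 80)  # prefiltering
    header += field([n_samp] * n_sig, 8)
    header += field([""] * n_sig, 32)  # reserved

    scale = (dig_max - dig_min) / (phys_max - phys_min)  # 10 digits per uV
    with open(path, "wb") as fh:
        fh.write(header)
        for sig in data:
            dig = np.round((sig - phys_min) * scale + dig_min).astype("<i2")
            fh.write(dig.tobytes())
    return path
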