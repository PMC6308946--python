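"""Fixed-size telemetry frames and a lossy delivery channel.

Remote stations without cellular coverage report over a satellite
short-message service whose payload is a fixed 72-byte frame.  Only the
size constraint and the per-frame loss probability are modelled here — no
protocol, latency or ordering behaviour.

Frame layout, version 1 (all integers big-endian):

======  ====  =====================================================
offset  size  field
======  ====  =====================================================
0       2     magic ``b"FG"``
2       1     layout version (1)
3       1     reserved (0)
4       16    station id, UTF-8, NUL-padded
20      8     timestamp, signed seconds since the Unix epoch
28      2     air temperature, signed, 0.01 °C steps
30      2     relative humidity, unsigned, 0.0001 (0.01 %) steps
32      2     wind speed, unsigned, 0.01 m/s steps
34      2     precipitation over the interval, unsigned, 0.01 mm steps
36      2     soil VWC at 10 cm, unsigned, 0.0001 steps
38      2     soil VWC at 40 cm, unsigned, 0.0001 steps
40      30    reserved (0)
70      2     CRC-16/CCITT over bytes 0–69
======  ====  =====================================================

Round-trip quantisation error is therefore at most half a step per channel:
0.005 °C / m/s / mm and 5e-5 on the fractional channels.
"""

from __future__ import annotations

import binascii
import datetime as dt
import struct
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aggregate import SensorRecord
from .errors import DecodingError, EncodingError, ValidationError

__all__ = ["Frame", "ChannelConfig", "encode_frame", "decode_frame", "transmit",
           "FRAME_SIZE"]

FRAME_SIZE = 72
_MAGIC = b"FG"
_VERSION = 1
_STRUCT = struct.Struct(">2sBB16sqhHHHHH30sH")
assert _STRUCT.size == FRAME_SIZE

# (scale, signed min, max) per channel in encoding order
_TEMP_STEP = 0.01
_FRAC_STEP = 1e-4
_RATE_STEP = 0.01


@dataclass(frozen=True)
class Frame:
    """One 72-byte telemetry frame."""

    payload: bytes

    def __post_init__(self):
        if len(self.payload) != FRAME_SIZE:
            raise ValidationError(
                f"frame payload must be {FRAME_SIZE} bytes, got {len(self.payload)}"
            )

    def __len__(self) -> int:
        return len(self.payload)


@dataclass(frozen=True)
class ChannelConfig:
    """Bernoulli per-frame delivery channel."""

    success_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValidationError("success_prob must be in [0, 1]")


def _quantize(name: str, value: float, step: float, lo: float, hi: float) -> int:
    if not lo <= value <= hi:
        raise EncodingError(f"{name}={value} outside encodable range [{lo}, {hi}]")
    return int(round(value / step))


def encode_frame(record: SensorRecord) -> Frame:
    """Pack one sensor record into a 72-byte frame."""
    sid = record.station_id.encode("utf-8")
    if len(sid) > 16:
        raise EncodingError(f"station_id longer than 16 bytes: {record.station_id!r}")
    ts = record.timestamp
    if isinstance(ts, dt.datetime):
        epoch = int(ts.replace(tzinfo=ts.tzinfo or dt.timezone.utc).timestamp())
    else:
        epoch = int(ts.timestamp())
    body = _STRUCT.pack(
        _MAGIC,
        _VERSION,
        0,
        sid.ljust(16, b"\x00"),
        epoch,
        _quantize("air_temp", record.air_temp, _TEMP_STEP, -55.0, 80.0),
        _quantize("rel_humidity", record.rel_humidity, _FRAC_STEP, 0.0, 1.0),
        _quantize("wind_speed", record.wind_speed, _RATE_STEP, 0.0, 60.0),
        _quantize("precip", record.precip, _RATE_STEP, 0.0, 600.0),
        _quantize("soil_vwc_10cm", record.soil_vwc_10cm, _FRAC_STEP, 0.0, 1.0),
        _quantize("soil_vwc_40cm", record.soil_vwc_40cm, _FRAC_STEP, 0.0, 1.0),
        b"\x00" * 30,
        0,
    )
    crc = binascii.crc_hqx(body[:-2], 0xFFFF)
    return Frame(body[:-2] + struct.pack(">H", crc))


def decode_frame(frame: Frame | bytes) -> SensorRecord:
    """Unpack a frame back into a sensor record (within quantisation)."""
    payload = frame.payload if isinstance(frame, Frame) else bytes(frame)
    if len(payload) != FRAME_SIZE:
        raise DecodingError(f"expected {FRAME_SIZE} bytes, got {len(payload)}")
    magic, version, _, sid, epoch, t, rh, w, p, s10, s40, _, crc = _STRUCT.unpack(payload)
    if magic != _MAGIC:
        raise DecodingError(f"bad magic {magic!r}")
    if version != _VERSION:
        raise DecodingError(f"unsupported frame version {version}")
    if binascii.crc_hqx(payload[:-2], 0xFFFF) != crc:
        raise DecodingError("CRC mismatch: corrupt frame")
    return SensorRecord(
        timestamp=dt.datetime.fromtimestamp(epoch, dt.timezone.utc).replace(tzinfo=None),
        station_id=sid.rstrip(b"\x00").decode("utf-8"),
        air_temp=t * _TEMP_STEP,
        rel_humidity=rh * _FRAC_STEP,
        wind_speed=w * _RATE_STEP,
        precip=p * _RATE_STEP,
        soil_vwc_10cm=s10 * _FRAC_STEP,
        soil_vwc_40cm=s40 * _FRAC_STEP,
    )


def transmit(
    frames: Sequence[Frame], channel: ChannelConfig
) -> tuple[list[Frame], dict]:
    """Deliver frames over an independent-loss channel.

    Each frame is delivered with probability ``channel.success_prob``,
    independently.  Returns the delivered frames and a report with the sent
    count, delivered count and empirical delivery rate.
    """
    frames = list(frames)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=channel.seed, spawn_key=(100,))
    )
    ok = rng.random(len(frames)) < channel.success_prob
    delivered = [f for f, keep in zip(frames, ok) if keep]
    report = {
        "sent": len(frames),
        "delivered": len(delivered),
        "empirical_rate": (len(delivered) / len(frames)) if frames else float("nan"),
        "success_prob": channel.success_prob,
    }
    return delivered, report
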