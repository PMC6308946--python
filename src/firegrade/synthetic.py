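"""Synthetic station weather: a stochastic generator for pipeline testing.

No public accessions of the original station data exist, so the package
ships a generator that emulates the statistical character of a temperate
spring fire season at 10-minute cadence:

* temperature = daily mean + diurnal sinusoid (warmest mid-afternoon) +
  AR(1) noise, with wet days cooler by a fixed offset (cloud cover);
* relative humidity anti-correlated with temperature, elevated on wet days;
* precipitation occurrence as a daily two-state Markov chain, with the wet
  day's exponential-distributed total spread over a random intra-day event
  window;
* 10 cm soil moisture as a leaky bucket — it gains a fixed fraction of each
  interval's rainfall and relaxes slowly toward a dry floor, so it rises
  fast under rain and decays slowly afterwards;
* 40 cm soil moisture relaxing toward the 10 cm value with a small
  coupling, so brief showers barely reach it.

All randomness derives from one seed via named substreams, so the rain
process can be varied without disturbing the temperature draw.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["WeatherGenConfig", "generate_weather", "recover_parameters"]

# substream indices
_TEMP, _RH, _WIND, _RAIN, _SOIL = range(5)

_TEMP_RANGE = (-55.0, 80.0)
_WIND_MAX = 60.0
_AR1_PHI = 0.95          # per-interval autocorrelation of the noise terms
_RH_NOISE_SD = 0.03
_PEAK_HOUR = 14.0        # warmest time of day


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the synthetic weather generator.

    Defaults describe a 92-day temperate spring fire season (the length of
    the monitoring campaigns the package is aimed at): cool mornings, dry
    air, episodic frontal rain, and litter-layer soil that wets quickly and
    dries over one to two weeks.
    """

    seed: int = 0
    days: int = 92
    cadence: int = 10                     # minutes
    start_date: dt.date = dt.date(2017, 3, 1)
    station_id: str = "SYN-001"

    temp_mean: float = 12.0               # °C, season mean
    temp_diurnal_amp: float = 8.0         # °C, half peak-to-trough
    temp_noise_sd: float = 1.5            # °C
    wet_day_temp_drop: float = 4.0        # °C cooler on wet (overcast) days

    rh_base: float = 0.45                 # fraction, season mean
    rh_temp_coupling: float = 0.015       # fraction per °C of temperature anomaly
    wet_day_rh_boost: float = 0.30        # fraction added on wet days

    wind_shape: float = 2.0               # Weibull shape
    wind_scale: float = 3.0               # m/s, Weibull scale

    p_wet_given_wet: float = 0.45         # rain-occurrence Markov chain
    p_wet_given_dry: float = 0.12
    rain_event_mean_mm: float = 8.0       # mean wet-day total (exponential)

    soil_infiltration_gain: float = 0.012  # VWC fraction gained per mm of rain
    soil10_decay_per_day: float = 0.04     # relaxation rate toward the floor
    soil40_coupling: float = 0.08          # per-day relaxation toward the 10 cm value
    soil_floor: float = 0.08               # fraction
    soil_cap: float = 0.45                 # fraction
    soil_init: float = 0.15                # fraction at t0

    def __post_init__(self):
        for name in ("p_wet_given_wet", "p_wet_given_dry"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.soil10_decay_per_day < 1.0:
            raise ValidationError("soil10_decay_per_day must be in (0, 1)")
        if not self.soil_cap > self.soil_floor:
            raise ValidationError("soil_cap must exceed soil_floor")
        if self.days <= 0 or self.cadence <= 0:
            raise ValidationError("days and cadence must be positive")
        if self.rain_event_mean_mm < 0 or self.temp_noise_sd < 0:
            raise ValidationError("noise and rain parameters must be non-negative")
        if self.wind_shape <= 0 or self.wind_scale < 0:
            raise ValidationError("wind Weibull parameters must be positive")

    @property
    def records_per_day(self) -> int:
        if (24 * 60) % self.cadence:
            raise ValidationError("cadence must divide the day evenly")
        return (24 * 60) // self.cadence


def _rng(config: WeatherGenConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _ar1(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    z = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = z[0] * sd
    innov_sd = sd * np.sqrt(1.0 - _AR1_PHI ** 2)
    for i in range(1, n):
        out[i] = _AR1_PHI * out[i - 1] + innov_sd * z[i]
    return out


def _wet_day_states(config: WeatherGenConfig, rng: np.random.Generator) -> np.ndarray:
    pww, pwd = config.p_wet_given_wet, config.p_wet_given_dry
    denom = 1.0 - pww + pwd
    stationary = pwd / denom if denom > 0 else 0.0
    u = rng.random(config.days)
    states = np.zeros(config.days, dtype=bool)
    states[0] = u[0] < stationary
    for d in range(1, config.days):
        p = pww if states[d - 1] else pwd
        states[d] = u[d] < p
    return states


def _intraday_rain(
    config: WeatherGenConfig, rng: np.random.Generator, wet: np.ndarray
) -> np.ndarray:
    """Per-interval precipitation: each wet day's exponential total is spread
    uniformly over one random 2–6 h event window."""
    per_day = config.records_per_day
    precip = np.zeros(config.days * per_day)
    totals = rng.exponential(config.rain_event_mean_mm, size=config.days)
    for d in np.flatnonzero(wet):
        min_len = max(1, (2 * 60) // config.cadence)
        max_len = max(min_len, (6 * 60) // config.cadence)
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, per_day)
        start = int(rng.integers(0, per_day - length + 1))
        i0 = d * per_day + start
        precip[i0 : i0 + length] += totals[d] / length
    return precip


def generate_weather(config: WeatherGenConfig | None = None) -> pd.DataFrame:
    """Generate a station record frame (internal column names, fractions).

    The output is reproducible for a fixed seed and compatible with
    :func:`firegrade.aggregate.summarize_series` and
    :func:`firegrade.aggregate.write_sensor_csv`.
    """
    config = config or WeatherGenConfig()
    per_day = config.records_per_day
    n = config.days * per_day
    dt_days = config.cadence / (24.0 * 60.0)

    start = pd.Timestamp(config.start_date)
    times = pd.date_range(start, periods=n, freq=f"{config.cadence}min")
    hours = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    day_idx = np.repeat(np.arange(config.days), per_day)

    wet = _wet_day_states(config, _rng(config, _RAIN))
    wet_iv = wet[day_idx]

    diurnal = config.temp_diurnal_amp * np.cos(2 * np.pi * (hours - _PEAK_HOUR) / 24.0)
    temp = (
        config.temp_mean
        - config.wet_day_temp_drop * wet_iv
        + diurnal
        + _ar1(_rng(config, _TEMP), n, config.temp_noise_sd)
    )
    temp = np.clip(temp, *_TEMP_RANGE)

    rh = (
        config.rh_base
        + config.wet_day_rh_boost * wet_iv
        - config.rh_temp_coupling * (temp - config.temp_mean)
        + _ar1(_rng(config, _RH), n, _RH_NOISE_SD)
    )
    rh = np.clip(rh, 0.0, 1.0)

    wind = config.wind_scale * _rng(config, _WIND).weibull(config.wind_shape, size=n)
    wind = np.clip(wind, 0.0, _WIND_MAX)

    precip = _intraday_rain(config, _rng(config, _RAIN).spawn(1)[0], wet)

    # leaky-bucket soil: fast gain from rain, slow exponential relaxation
    keep = (1.0 - config.soil10_decay_per_day) ** dt_days
    s10 = np.empty(n)
    s40 = np.empty(n)
    s10_prev = s40_prev = config.soil_init
    gain, floor, cap = config.soil_infiltration_gain, config.soil_floor, config.soil_cap
    c40 = config.soil40_coupling * dt_days
    for i in range(n):
        s = s10_prev + gain * precip[i]
        s = floor + (s - floor) * keep
        s10_prev = min(max(s, floor), cap)
        s40_prev = min(max(s40_prev + c40 * (s10_prev - s40_prev), floor), cap)
        s10[i] = s10_prev
        s40[i] = s40_prev

    return pd.DataFrame(
        {
            "timestamp": times,
            "station_id": config.station_id,
            "air_temp": temp,
            "rel_humidity": rh,
            "wind_speed": wind,
            "precip": precip,
            "soil_vwc_10cm": s10,
            "soil_vwc_40cm": s40,
        }
    )


def recover_parameters(
    records: pd.DataFrame, rain_day_threshold: float = 0.1
) -> dict[str, float]:
    """Method-of-moments estimates of the rain process from a record frame.

    Returns the wet-day frequency and the mean wet-day precipitation total;
    used to confirm that generated series hit their configured targets.
    Requires at least 30 days of records.
    """
    ts = pd.to_datetime(records["timestamp"])
    daily = records.groupby(ts.dt.normalize())["precip"].sum()
    if len(daily) < 30:
        raise ValidationError(f"need >= 30 days of records, got {len(daily)}")
    wet = daily >= rain_day_threshold
    wet_frequency = float(wet.mean())
    mean_wet_day_rain = float(daily[wet].mean()) if wet.any() else float("nan")
    return {
        "n_days": int(len(daily)),
        "wet_day_frequency": wet_frequency,
        "mean_wet_day_rain_mm": mean_wet_day_rain,
    }
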