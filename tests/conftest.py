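import datetime as dt

import numpy as np
import pandas as pd
import pytest

from firegrade import builtin_sample_sets


@pytest.fixture(scope="session")
def sample_sets():
    return builtin_sample_sets()


def make_day_frame(
    date: dt.date = dt.date(2017, 3, 20),
    cadence: int = 10,
    station_id: str = "S1",
    air_temp=10.0,
    rel_humidity=0.5,
    wind_speed=2.0,
    precip=0.0,
    soil_vwc_10cm=0.2,
    soil_vwc_40cm=0.2,
    drop_slots=(),
) -> pd.DataFrame:
    """One station-day of records on a regular grid.

    Channel arguments may be scalars or per-slot arrays; ``drop_slots``
    removes grid slots to simulate data gaps.
    """
    n = (24 * 60) // cadence
    times = pd.date_range(pd.Timestamp(date), periods=n, freq=f"{cadence}min")
    df = pd.DataFrame(
        {
            "timestamp": times,
            "station_id": station_id,
            "air_temp": np.broadcast_to(air_temp, n).astype(float),
            "rel_humidity": np.broadcast_to(rel_humidity, n).astype(float),
            "wind_speed": np.broadcast_to(wind_speed, n).astype(float),
            "precip": np.broadcast_to(precip, n).astype(float),
            "soil_vwc_10cm": np.broadcast_to(soil_vwc_10cm, n).astype(float),
            "soil_vwc_40cm": np.broadcast_to(soil_vwc_40cm, n).astype(float),
        }
    )
    if drop_slots:
        df = df.drop(index=list(drop_slots)).reset_index(drop=True)
    return df
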