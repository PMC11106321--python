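import datetime as dt

import numpy as np
import pytest

from peatflux.chamber import ChamberRun


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_run(
    elapsed=None,
    co2=None,
    ch4=None,
    site="PPSF",
    plot=1,
    replicate=1,
    temp_k=301.15,
    pressure_kpa=101.325,
    volume=0.0058,
    area=0.0318,
):
    """Minimal chamber run for unit tests; defaults give a clean linear rise."""
    if elapsed is None:
        elapsed = np.arange(0.0, 121.0)
    if co2 is None:
        co2 = 420.0 + 0.1 * elapsed
    if ch4 is None:
        ch4 = 2.0 + 0.001 * elapsed
    return ChamberRun(
        run_id=f"{site}-{plot}-{replicate}",
        site=site,
        plot=plot,
        date=dt.date(2022, 10, 10),
        replicate=replicate,
        elapsed_s=elapsed,
        co2_ppm=co2,
        ch4_ppm=ch4,
        air_temp_k=temp_k,
        pressure_kpa=pressure_kpa,
        chamber_volume_m3=volume,
        collar_area_m2=area,
    )


def ols_oracle(t, y):
    """Brute-force normal-equations least squares: independent of the
    implementation's centered formulation."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = beta
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    return slope, intercept, r2
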