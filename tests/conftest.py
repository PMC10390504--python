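import numpy as np
import pandas as pd
import pytest

from leafphen import SiteMeta, build_window
from leafphen.base import WindowBatch
from leafphen.synth import WeatherGenSpec, gen_weather


@pytest.fixture(scope="session")
def site():
    return SiteMeta("s1", latitude=45.0)


@pytest.fixture(scope="session")
def calm_weather(site):
    """Two noiseless years of the default seasonal cycle."""
    return gen_weather(WeatherGenSpec(noise_sd=0.0), site, [2019, 2020])


@pytest.fixture(scope="session")
def noisy_weather(site):
    return gen_weather(WeatherGenSpec(seed=7), site, [2019, 2020])


@pytest.fixture(scope="session")
def emergence_window(noisy_weather, site):
    return build_window(noisy_weather, site, 2020, "emergence")


@pytest.fixture(scope="session")
def senescence_window(noisy_weather, site):
    return build_window(noisy_weather, site, 2020, "senescence")


def random_windows(phenophase, n, seed, latitudes=(42.0, 48.0)):
    """A batch of n windows with varied climate settings, plus the raw
    per-window (T, L) lists for feeding naive oracles."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n):
        site = SiteMeta(f"r{i}", latitude=float(rng.uniform(*latitudes)))
        spec = WeatherGenSpec(
            annual_mean=float(rng.uniform(2.0, 12.0)),
            seasonal_amplitude=float(rng.uniform(8.0, 18.0)),
            ar1_rho=float(rng.uniform(0.0, 0.9)),
            noise_sd=float(rng.uniform(0.5, 4.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        weather = gen_weather(spec, site, [2019, 2020])
        windows.append(build_window(weather, site, 2020, phenophase))
    batch = WindowBatch.from_windows(windows)
    return windows, batch
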