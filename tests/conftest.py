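import logging

import pytest

from homenet.config import ScenarioConfig
from homenet.synth import (
    DiurnalProfile,
    generate_occupations,
    generate_regions,
    generate_traffic,
)

logging.getLogger("homenet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(seed=11, n_regions=16, n_occupations=40,
                          persons_per_region=500, baseline_days=7, wave_days=7)


@pytest.fixture(scope="session")
def occupations(small_config):
    return generate_occupations(small_config)


@pytest.fixture(scope="session")
def region_data(small_config, occupations):
    return generate_regions(small_config, occupations)


@pytest.fixture(scope="session")
def exact_config():
    """Noise-free scenario in which every windowed metric is exact:
    integer slot means, effect divisible by the rank denominator, no
    weekend scaling and no baseline heterogeneity."""
    return ScenarioConfig(seed=3, n_regions=9, n_occupations=30,
                          persons_per_region=400, baseline_days=14,
                          wave_days=7, noise_sd=0.0,
                          planted_upload_effect=64_000.0,
                          children_download_effect=0.0,
                          household_level_sd=0.0)


@pytest.fixture(scope="session")
def flat_profiles():
    return (DiurnalProfile.default("download", weekend_scale=1.0),
            DiurnalProfile.default("upload", weekend_scale=1.0))


@pytest.fixture(scope="session")
def exact_traffic(exact_config, flat_profiles):
    occ = generate_occupations(exact_config)
    reg = generate_regions(exact_config, occ)
    traffic = generate_traffic(exact_config, reg.regions, *flat_profiles)
    return reg, traffic
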