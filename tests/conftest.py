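import numpy as np
import pandas as pd
import pytest

from aopipe import survey_synth


@pytest.fixture
def tiny_config():
    """One 2x2 km basin, 0.5 km spacing, no random extras: 25 stations."""
    basin = survey_synth.Basin("B01", width_km=2.0, height_km=2.0)
    species = survey_synth.SpeciesTruth("focal", mu=100.0, k=1.0)
    return survey_synth.SyntheticConfig(
        basins=(basin,), species=(species,), n_years=2,
        random_fraction=0.0, outlier_rate=0.0,
        missing_mass_rate=0.0, missing_all_rate=0.0, seed=7)


@pytest.fixture
def big_single_species():
    """4000-station, one-year, one-species survey for occupancy checks."""
    cfg = survey_synth.single_basin_config(mu=100.0, k=1.0,
                                           n_stations=4000, seed=11)
    return survey_synth.generate_survey(cfg)


def powerlaw_records(n=200, a=1e-5, b=3.0, sigma_log10=0.0, seed=0,
                     species="biv", length_range=(5.0, 40.0)):
    """Hand-built bivalve records on (or scattered about) a mass power law."""
    rng = np.random.default_rng(seed)
    length = np.exp(rng.uniform(np.log(length_range[0]),
                                np.log(length_range[1]), n))
    log10_mass = np.log10(a) + b * np.log10(length) + \
        sigma_log10 * rng.standard_normal(n)
    return pd.DataFrame({
        "station_id": "S1", "year": 2008, "species": species,
        "length_mm": length, "size_class": None,
        "afdm_g": 10.0 ** log10_mass,
    })
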