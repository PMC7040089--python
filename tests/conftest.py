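"""Shared fixtures: Monte-Carlo photon ensembles and the default synthetic study.

The heavy artefacts (10^6-packet photon ensembles, the full 18-participant
study) are session-scoped so the physics suite, the inversion suite and the
decoding acceptance checks all reuse one computation.
"""

import numpy as np
import pytest

from trbci.config import PipelineConfig
from trbci.montecarlo import Geometry, default_head_medium, run_photon_mc
from trbci.pipeline import decode_study, prepare_sensitivity, run_study

MC_SEED = 424242
N_PHOTONS = 1_000_000


@pytest.fixture(scope="session")
def medium():
    return default_head_medium()


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def mc_records(medium, geometry):
    """10^6-packet ensemble with the default (index-mismatched) boundary."""
    return run_photon_mc(medium, geometry, N_PHOTONS, MC_SEED)


@pytest.fixture(scope="session")
def mc_records_matched(medium):
    """10^6-packet ensemble with an index-matched boundary (diffusion checks)."""
    geo = Geometry(external_refractive_index=medium.refractive_index)
    return run_photon_mc(medium, geo, N_PHOTONS, MC_SEED + 1)


@pytest.fixture(scope="session")
def default_config():
    cfg = PipelineConfig()
    cfg.optics.n_photons = N_PHOTONS
    cfg.optics.mc_seed = MC_SEED
    cfg.master_seed = 1
    return cfg


@pytest.fixture(scope="session")
def sensitivity_stage(default_config, mc_records):
    return prepare_sensitivity(default_config, mc_records)


@pytest.fixture(scope="session")
def default_study(default_config, mc_records):
    """Full default synthetic study (18 participants x 4 questions)."""
    return run_study(default_config, records=mc_records)


@pytest.fixture(scope="session")
def default_report(default_study, default_config):
    return decode_study(default_study, default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
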