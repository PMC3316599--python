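import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from terriforage.borders import calibrate_saturation_map
from terriforage.config import SimConfig
from terriforage.lattice import run_replicates


def scaled_2d_config(beta: float, Z: float, cp_sites: int = 12,
                     relax_times: float = 25.0, n_records: int = 400) -> SimConfig:
    """2D configuration run for ~25 border relaxation times (>= 8000 sweeps)."""
    c = SimConfig(dimension=2, cp_sites=cp_sites, t_max=1000.0,
                  record_every=20.0).with_dimensionless(beta=beta, Z=Z)
    t_max = max(8000.0, relax_times * c.active_scent_time)
    d = c.to_dict()
    d.update(t_max=t_max, record_every=t_max / n_records)
    return SimConfig(**d)


@pytest.fixture(scope="session")
def ring_beta0_ensemble():
    """2-animal ring, no bias, 1e5 sweeps, 100 replicates (growing borders)."""
    cfg = SimConfig(dimension=1, cp_sites=20, t_max=100_000, record_every=100
                    ).with_dimensionless(beta=0.0, Z=1.0)
    return cfg, run_replicates(cfg, 100, seed=211)


@pytest.fixture(scope="session")
def ring_beta4_ensemble():
    """2-animal ring, beta=4, matched length (saturating borders)."""
    cfg = SimConfig(dimension=1, cp_sites=20, t_max=100_000, record_every=100
                    ).with_dimensionless(beta=4.0, Z=1.0)
    return cfg, run_replicates(cfg, 100, seed=212)


@pytest.fixture(scope="session")
def calibration_2d():
    """Session 2D calibration map used by the inference pipeline tests."""
    base = SimConfig(dimension=2, cp_sites=12, t_max=60_000, record_every=150)
    return calibrate_saturation_map(
        base, betas=[2.0, 4.0, 8.0], Zs=[4.0, 8.0, 16.0, 32.0],
        replicates=5, seed=307,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
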