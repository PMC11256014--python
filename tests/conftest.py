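import numpy as np
import pytest

from lodie.records import CalibrationSeries
from lodie.simulate import SimConfig

GRID_16 = np.sort(
    1.67e-6
    * np.array(
        [1.0, 0.2, 0.1, 0.02, 0.01, 0.002, 0.001, 2e-4,
         1e-4, 2e-5, 1e-5, 2e-6, 1e-6, 2e-7, 1e-7, 2e-8]
    )
)


def make_series(
    concs,
    areas,
    compound_id="X",
    sn=None,
    blank_area=None,
):
    return CalibrationSeries(
        compound_id=compound_id,
        concentrations=np.asarray(concs, dtype=float),
        areas=np.asarray(areas, dtype=float),
        sn=None if sn is None else np.asarray(sn, dtype=float),
        blank_area=blank_area,
    )


@pytest.fixture
def exact_series():
    """Noise-free series: area = RF * c exactly, RF = 1e14, triplicate."""
    rf = 1e14
    concs = GRID_16
    areas = np.repeat((rf * concs)[:, None], 3, axis=1)
    sn = areas / 1000.0
    return make_series(concs, areas, compound_id="exact", sn=sn), rf


def noisy_series(seed=0, rf=1e14, sigma=2000.0, cv=0.02, concs=GRID_16, reps=3):
    """Linear series with additive + multiplicative noise, S/N = area/sigma."""
    rng = np.random.default_rng(seed)
    mu = rf * concs
    areas = mu[:, None] * (1 + rng.normal(0, cv, (concs.size, reps)))
    areas = np.maximum(areas + rng.normal(0, sigma, (concs.size, reps)), 0.0)
    sn = areas / sigma
    return make_series(concs, areas, compound_id=f"noisy{seed}", sn=sn)


@pytest.fixture
def sim_config():
    return SimConfig(n_compounds=20, seed=11)
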