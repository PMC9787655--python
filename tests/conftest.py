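import numpy as np
import pytest

from scrmove.landscape import (
    SurveyRegion,
    build_potential,
    build_state_space,
    synthetic_landscape,
)
from scrmove.inference import ModelConfig, Priors, Sampler, _ModelData
from scrmove.observation import EncounterData, TelemetryData


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def flat_landscape():
    """All-ice 10x10 grid of 10-km cells: flat potential, zero drift."""
    ss = synthetic_landscape(0, 10, 10, resolution_km=10.0)
    return ss, build_potential(ss)


@pytest.fixture(scope="session")
def coastal_landscape():
    """20x20 grid of 5-km cells with a 25% no-ice shore band."""
    ss = synthetic_landscape(3, 20, 20, resolution_km=5.0, shore_fraction=0.25)
    return ss, build_potential(ss)


def tiny_sampler(seed=0, T=4, m_total=8, with_telemetry=True, n_det=2,
                 movement_model="crw", delta=0.0):
    """A miniature model with hand-built data: an all-ice 4x4 grid of 25-km
    cells, one 50-km trap cell, a couple of detected individuals."""
    ss = synthetic_landscape(1, 4, 4, resolution_km=25.0)
    pot = build_potential(ss)
    region = SurveyRegion.from_grid((25.0, 25.0), (1, 1), 50.0)
    rng = np.random.default_rng(seed)
    effort = np.zeros((T, 1))
    effort[:, 0] = rng.uniform(15.0, 30.0, T)
    J = 1
    y = np.full((n_det, T), J, dtype=int)
    for i in range(n_det):
        y[i, int(rng.integers(T))] = 0
    from scrmove.inference import behavioural_flags

    B = behavioural_flags(y, J, effort.sum(axis=1) > 0)
    enc = EncounterData(
        y=y, effort=effort, B=B, state=np.ones(n_det, dtype=int)
    )
    tel = None
    if with_telemetry:
        n_fix = 2 * T
        tel = TelemetryData(
            individual=np.zeros(n_fix, dtype=int),
            occasion=np.repeat(np.arange(T), 2),
            u=rng.uniform(20, 80, (n_fix, 2)),
        )
    cfg = ModelConfig(
        movement_model=movement_model,
        m_per_state={1: m_total},
        class_of_state={1: "all"},
        delta=delta,
        adapt=False,
        param_repeats=1,
        priors=Priors(
            alpha_sd=2.0,
            sigma_shape=9.0,
            sigma_rate=1.0,
            sigma_det_shape=25.0,
            sigma_det_rate=5.0,
            gamma_a=2.0,
            gamma_b=2.0,
        ),
        init={
            "sigma": 10.0,
            "gamma": 0.4,
            "alpha0": -1.0,
            "alpha1": 0.5,
            "alpha2": 0.0,
            "sigma_det": 5.0,
            "psi": 0.4,
        },
    )
    data = _ModelData(enc, tel, ss, region, pot, cfg)
    return Sampler(data, np.random.default_rng(seed + 1))
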