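import numpy as np
import pytest

import hepaflux as hf


@pytest.fixture
def unit_protocol() -> hf.InfusionProtocol:
    """Protocol with I6 = 2.5 and Igal = 1.0 μmol·kg⁻¹·min⁻¹ exactly."""
    return hf.InfusionProtocol.from_rates(2.5, 1.0)


@pytest.fixture
def worked_params() -> hf.PrimaryIsotopeParams:
    """Isotope parameters of the hand-derived flux example."""
    return hf.PrimaryIsotopeParams(
        d_glc=0.0625, d_udpglc=1.0 / 31.0, c_glc=0.25,
        c_udpglc=0.15, f_glc=0.8, f_udpglc=0.5,
    )


@pytest.fixture
def worked_truth(unit_protocol) -> hf.SyntheticTruth:
    """Noise-free, instantly-equilibrating truth matching the worked example."""
    return hf.SyntheticTruth(
        gck=20.0, g6pase=50.0, gs=30.0, gp=20.0, gng_g6p=40.0,
        noise_cv=0.0, tau_glc=1.0, tau_udpglc=1.0, urine_lag_min=0.0,
        protocol=unit_protocol,
    )


WORKED_FLUXES = {
    "ra": 40.0, "ru": 31.0, "egp": 37.5, "g6pase": 50.0, "gs": 30.0,
    "gck": 20.0, "gng_g6p": 40.0, "gp": 20.0,
    "glucose_balance": 30.0, "glycogen_balance": 10.0,
}


@pytest.fixture
def worked_fluxes() -> dict[str, float]:
    return dict(WORKED_FLUXES)


def random_feasible_params(rng: np.random.Generator) -> hf.PrimaryIsotopeParams:
    """Draw isotope parameters uniformly inside the feasible region."""
    c_glc = rng.uniform(0.0, 0.95)
    f_udpglc = rng.uniform(0.0, 1.0 - c_glc)
    return hf.PrimaryIsotopeParams(
        d_glc=rng.uniform(0.01, 1.0),
        d_udpglc=rng.uniform(0.01, 1.0),
        c_glc=c_glc,
        c_udpglc=rng.uniform(0.0, 1.0),
        f_glc=rng.uniform(0.0, 1.0),
        f_udpglc=f_udpglc,
    )
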