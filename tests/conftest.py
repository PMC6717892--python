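import numpy as np
import pytest

from allosense.binding import TwoSetsParams
from allosense.itc import TitrationProtocol, simulate_titration
from allosense.synth import PUBLISHED_ITC_PARAMS


@pytest.fixture(scope="session")
def camp_params() -> TwoSetsParams:
    return PUBLISHED_ITC_PARAMS["cAMP"]


@pytest.fixture(scope="session")
def cgmp_params() -> TwoSetsParams:
    return PUBLISHED_ITC_PARAMS["cGMP"]


@pytest.fixture(scope="session")
def standard_protocol() -> TitrationProtocol:
    """The default titration design: 1.4 ml cell, 2 then 24 x 6 ul injections."""
    return TitrationProtocol(cell_conc=100e-6, syr_conc=1.0e-3)


@pytest.fixture(scope="session")
def noiseless_camp_thermogram(camp_params, standard_protocol):
    return simulate_titration(camp_params, standard_protocol)


@pytest.fixture(scope="session")
def noiseless_cgmp_thermogram(cgmp_params, standard_protocol):
    return simulate_titration(cgmp_params, standard_protocol)


def perturbed_start(p: TwoSetsParams, direction: int = +1) -> TwoSetsParams:
    """Deterministic perturbation: x3 on K's, +-30% on the others."""
    s = 1.3 if direction > 0 else 0.7
    kf = 3.0 if direction > 0 else 1.0 / 3.0
    return TwoSetsParams(
        n1=p.n1 * s, n2=p.n2 * (2 - s), K1=p.K1 * kf, K2=p.K2 / kf,
        dH1=p.dH1 * s, dH2=p.dH2 * (2 - s),
    )
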