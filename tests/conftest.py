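import numpy as np
import pytest

from torpormix import GeneratorConfig, ThermoParams, default_fixtures, generate


def random_admissible_params(rng: np.random.Generator) -> ThermoParams:
    """Rejection-sample one admissible parameter vector (natural units)."""
    while True:
        m_tnz = rng.uniform(0.3, 3.0)
        t_lc = rng.uniform(22.0, 35.0)
        t_be = t_lc + rng.uniform(1.0, 15.0)
        t_bt = rng.uniform(-5.0, t_lc - 4.0)
        tmr = rng.uniform(0.01, 0.8) * m_tnz
        m_r = rng.uniform(tmr, m_tnz)
        p = ThermoParams(
            m_tnz=m_tnz, t_lc=t_lc, t_be=t_be, t_bt=t_bt, tmr=tmr, m_r=m_r,
            sd_tnz=0.05 * m_tnz, sd_r=0.07 * m_tnz, sd_c=0.03 * m_tnz,
        )
        try:
            return p.validate()
        except Exception:
            continue


@pytest.fixture(scope="session")
def param_rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def deep_dataset():
    return generate(default_fixtures()["deep_hibernator"])


@pytest.fixture(scope="session")
def homeotherm_dataset():
    return generate(default_fixtures()["homeotherm"])


@pytest.fixture(scope="session")
def quick_mcmc():
    """Reduced run protocol for unit tests (full protocol is exercised by the
    acceptance suite)."""
    return dict(iterations=4000, burn_in=2000, thinning=10)
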