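import numpy as np
import pytest

from fanwave.auxiliary import AuxParams
from fanwave.engine import WaveFrame
from fanwave.solutions import SolutionSpec
from fanwave.verify import AuditConfig, audit_catalogue


@pytest.fixture(scope="session")
def audit_report():
    """One full catalogue audit shared by the verification/acceptance tests."""
    return audit_catalogue(AuditConfig(seed=7))


@pytest.fixture
def fig2_spec():
    """The first published caption configuration (kink family, valid regime)."""
    return SolutionSpec(
        family_index=1,
        aux=AuxParams(sigma=1.0, mu=1.0, rho=0.01),
        frame=WaveFrame(xi=1.0, zeta=4.0, Lambda1=1.0),
        phi1=1.0,
        phi2=1.0,
    )


def draw_for_case(case_id: int, type_id: int, rng: np.random.Generator) -> AuxParams:
    """Regime-valid auxiliary parameter draw (mirrors the audit defaults)."""
    if case_id == 1 and type_id == 1:
        return AuxParams(sigma=1.0, mu=float(rng.uniform(2.2, 3.5)), rho=1.0,
                         E=3.0, F=5.0)
    if case_id == 1:
        mu = float(rng.uniform(0.3, 1.2)) * (1 if rng.random() < 0.5 else -1)
        return AuxParams(sigma=1.0, mu=mu, rho=1.0, E=5.0, F=3.0)
    if case_id == 2:
        return AuxParams(sigma=1.0, mu=0.0, rho=-float(rng.uniform(0.5, 2.0)),
                         E=3.0, F=5.0)
    if case_id == 3:
        return AuxParams(
            alpha1=float(rng.uniform(0.8, 1.5)),
            alpha2=float(rng.uniform(0.5, 1.0)),
            alpha3=float(rng.uniform(1.5, 2.5)),
            alpha4=float(rng.uniform(0.3, 0.8)),
        )
    if case_id == 4:
        return AuxParams(q=float(rng.uniform(0.3, 0.8)))
    return AuxParams()
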