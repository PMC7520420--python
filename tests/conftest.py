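import numpy as np
import pytest

from adcpkpd import (
    DosingRegimen,
    IIVSpec,
    ResidualErrorModel,
    StudyDesign,
    TGIParams,
    TwoCptParams,
    fixtures,
    generate_xenograft_study,
)


@pytest.fixture(scope="session")
def mouse_pk():
    return fixtures.mouse_pk_pf()


@pytest.fixture(scope="session")
def monkey_pk():
    return fixtures.monkey_pk_pf()


@pytest.fixture(scope="session")
def jimt1():
    """Fitted JIMT-1 efficacy parameterization for PF-06804103."""
    return fixtures.PF_TGI["JIMT-1"]


@pytest.fixture(scope="session")
def jimt1_params(jimt1):
    return jimt1.params


@pytest.fixture(scope="session")
def q4d4():
    return DosingRegimen.uniform(1.0, 4.0, 4)


@pytest.fixture(scope="session")
def human_tmdd():
    return fixtures.tmdd_pf_human()


@pytest.fixture(scope="session")
def jimt1_study(jimt1, mouse_pk):
    """One synthetic Q4d×4 JIMT-1-like study at the reported noise levels."""
    design = StudyDesign(dose_arms=(0, 0.25, 0.5, 1.0))
    return generate_xenograft_study(
        design,
        jimt1.params,
        IIVSpec(jimt1.omega_kgEx, jimt1.omega_kg),
        ResidualErrorModel(jimt1.additive_error, jimt1.proportional_error),
        mouse_pk,
        seed=20240,
    )


@pytest.fixture(scope="session")
def clean_study(jimt1, mouse_pk):
    """Noise-free, no-IIV study for self-consistency checks."""
    design = StudyDesign(dose_arms=(0, 0.25, 0.5, 1.0))
    return generate_xenograft_study(
        design, jimt1.params, IIVSpec(0.0, 0.0), ResidualErrorModel(0.0, 0.0),
        mouse_pk, seed=7,
    )


def random_tgi_params(rng) -> TGIParams:
    """A random valid parameter set with reachable stasis."""
    kgEx = rng.uniform(0.02, 0.2)
    return TGIParams(
        kgEx=kgEx,
        kg=rng.uniform(10, 400),
        Vmax=rng.uniform(2000, 8000),
        tau=rng.uniform(0.5, 8),
        kkmax=kgEx * rng.uniform(1.5, 20),
        kc50=rng.uniform(1, 100),
        n=rng.uniform(0.5, 3),
        v0=rng.uniform(150, 300),
    )
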