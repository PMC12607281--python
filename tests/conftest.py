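import numpy as np
import pytest

from cbgpk import (
    PopulationModel,
    StructuralParams,
    StudyDesign,
    generate_study,
    published_model,
)

#: Table-1-style typical structural constants used throughout the tests
TYPICAL = dict(
    F=0.28, ka=0.99, beta=1.59, Cl=1.67, Vc=32.15, Q=154.5, Vp=36.12,
    Fm=0.75, Clm=0.016, Vm=0.0047,
)


@pytest.fixture(scope="session")
def pop():
    return published_model()


@pytest.fixture(scope="session")
def typical_params():
    return StructuralParams(**TYPICAL)


@pytest.fixture(scope="session")
def oil_params():
    p = dict(TYPICAL)
    p.update(ka=0.31, beta=0.70)
    return StructuralParams(**p)


def noise_free_population(**overrides) -> PopulationModel:
    """Published typicals with every random-effect and residual term at 0."""
    kw = dict(
        typical={
            "F": 0.28, "ka": 0.99, "beta": 1.59, "Cl": 1.67, "Vc": 32.15,
            "Q": 154.5, "Vp": 36.12, "Vm": 0.0047, "Clm": 0.016,
        },
        iiv_percent={},
        iov_percent={},
        covariates={
            "ka": {"oil": float(np.log(0.31 / 0.99))},
            "beta": {"oil": float(np.log(0.70 / 1.59))},
        },
        b1=0.0,
        b2=0.0,
    )
    kw.update(overrides)
    return PopulationModel(**kw)


@pytest.fixture(scope="session")
def study8(pop):
    """One default eight-horse crossover study (fixed seed)."""
    ds, truth = generate_study(pop, StudyDesign(), seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def noise_free_study():
    pop0 = noise_free_population()
    ds, truth = generate_study(pop0, StudyDesign(n_subjects=4), seed=1)
    return ds, truth, pop0
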