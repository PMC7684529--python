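import numpy as np
import pytest
from hypothesis import settings

from biomoneq import (
    ChemicalParameterSet,
    PopulationSpec,
    Stratum,
    demo_chemicals,
    generate_population,
)
from biomoneq.population import PhysiologyParameterSet, _build_individual

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chems():
    return demo_chemicals()


@pytest.fixture(scope="session")
def adult_pop():
    """Twenty adult females, fixed seed."""
    return generate_population(
        PopulationSpec(n=20, stratum=Stratum.ADULT_FEMALE, age_range=(32, 56), seed=42)
    )


@pytest.fixture(scope="session")
def child_pop():
    return generate_population(
        PopulationSpec(
            n=20, stratum=Stratum.CHILD, age_range=(6, 11),
            sex_mix={"F": 0.5, "M": 0.5}, seed=43,
        )
    )


@pytest.fixture
def reference_individual():
    """One deterministic 70-kg adult female (no sampled variability)."""
    return _build_individual(
        "ref-0", "F", 40.0, 70.0, 165.0, Stratum.ADULT_FEMALE, 1600.0, 1.0
    )


@pytest.fixture
def renal_only_chemical():
    """Fully absorbed, unbound, non-metabolised: urinary excretion only."""
    return ChemicalParameterSet(
        name="renalX", mw=200.0, log_kow=-0.5, fub=1.0, clint=0.0, ka=5.0, fabs=1.0
    )


def homogeneous_population(individual: PhysiologyParameterSet, n: int):
    import copy

    out = []
    for i in range(n):
        ind = copy.deepcopy(individual)
        ind.id = f"homog-{i:03d}"
        out.append(ind)
    return out
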