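import numpy as np
import pytest

from zolpitox import (
    DoseRegimen,
    PopulationParams,
    StructuralParams,
    reference_params,
)

# typical values of the final zolpidem model, used throughout the suite
TYPICAL = dict(ka=5.41, v=61.7, cl=16.9, tlag=0.394)


@pytest.fixture(scope="session")
def typical_params() -> StructuralParams:
    return StructuralParams(**TYPICAL)


@pytest.fixture(scope="session")
def ref_pop() -> PopulationParams:
    return reference_params()


@pytest.fixture(scope="session")
def no_iiv_pop(typical_params) -> PopulationParams:
    """Population with all variability switched off."""
    return PopulationParams(theta=typical_params, omega=np.zeros((3, 3)), sigma_prop=0.0)


@pytest.fixture(scope="session")
def single_10mg() -> DoseRegimen:
    return DoseRegimen.single(10.0)
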