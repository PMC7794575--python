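import numpy as np
import pytest

from soilntrace.model_core import (
    ExperimentDesign,
    IsotopePool,
    ModelStructure,
    Parameter,
    ParameterSet,
    ProcessSpec,
    SoilState,
)
from soilntrace.synthetic_data import land_use_truth


NA_FRAC = 0.3663 / 100.0


def make_state(nh4=20.0, no3=10.0, n_lab=40.0, n_rec=800.0, nh4_ads=0.0,
               nh4_frac=NA_FRAC, no3_frac=NA_FRAC, time=0.0):
    return SoilState(
        time,
        nh4=IsotopePool(nh4, nh4_frac),
        no3=IsotopePool(no3, no3_frac),
        n_lab=IsotopePool(n_lab, NA_FRAC),
        n_rec=IsotopePool(n_rec, NA_FRAC),
        nh4_ads=IsotopePool(nh4_ads, NA_FRAC),
    )


def single_process(process_id, kinetic_order, **params):
    """A one-process model plus its parameter set."""
    model = ModelStructure([ProcessSpec(process_id, kinetic_order)])
    pset = ParameterSet(
        {f"{process_id}.{k}": Parameter(v, 0.0, max(10.0, 4 * v + 1)) for k, v in params.items()}
    )
    return model, pset


@pytest.fixture(scope="session")
def forest_truth():
    return land_use_truth("forestland")


@pytest.fixture(scope="session")
def crop_truth():
    return land_use_truth("cropland")


@pytest.fixture()
def design():
    return ExperimentDesign()
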