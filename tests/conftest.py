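import warnings

import numpy as np
import pytest

from nfkbmicro.model import (DEFAULT_PARAMS, LEGACY_MODEL, NEW_MODEL,
                             build_driven_model, build_model)
from nfkbmicro.simulate import equilibrate, simulate
from nfkbmicro.experiments import nominal_drives, run_baseline

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def full_system(params):
    return build_model(NEW_MODEL, params)


@pytest.fixture(scope="session")
def legacy_system(params):
    return build_model(LEGACY_MODEL, params)


@pytest.fixture(scope="session")
def equilibrium(full_system):
    return equilibrate(full_system)


@pytest.fixture(scope="session")
def baseline():
    """Nominal equilibrate-then-stimulate run with headline metrics."""
    return run_baseline()


@pytest.fixture(scope="session")
def drives(baseline):
    """(ikk_drive, nfkbn_drive) loop-breaking inputs from the nominal run."""
    return nominal_drives(baseline)


@pytest.fixture(scope="session")
def downstream_system(params):
    return build_driven_model(NEW_MODEL, params, "IKKa")


@pytest.fixture(scope="session")
def upstream_system(params):
    return build_driven_model(NEW_MODEL, params, "NFkBn")
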