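import numpy as np
import pytest

from lumbarload import default_constants, make_params, build_posture
from lumbarload.sweep import run_sweep

CENTRAL_PI = {"RT1": 40, "RT2": 40, "RT3": 50, "RT4": 60}


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def full_sweep():
    """The complete 2772-configuration standing sweep (computed once)."""
    return run_sweep()


@pytest.fixture(scope="session")
def sweep_frame(full_sweep):
    return full_sweep.to_frame()


@pytest.fixture(scope="session")
def reference_posture(constants):
    """The worked-example standing configuration: RT1, SS 25, PI 40, balanced."""
    return build_posture(make_params("RT1", 25, 40, "med", constants), constants)


@pytest.fixture(scope="session")
def corner_params(constants):
    """SS-range endpoints at central PI for every type and balance condition."""
    out = []
    for rt, cpi in CENTRAL_PI.items():
        lo, hi = constants.rt(rt).ss_range
        for cond in ("back", "med", "front"):
            for ss in (lo, hi):
                out.append(make_params(rt, ss, cpi, cond, constants))
    return out
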