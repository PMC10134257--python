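import numpy as np
import pytest

import nsclc_cea as n


@pytest.fixture(scope="session")
def table1():
    """The shipped parameter table (no curves)."""
    return n.builtin_parameter_set()


@pytest.fixture(scope="session")
def study():
    """Synthetic noise-free study: shipped parameters + cohort-consistent curves."""
    return n.fixture_parameter_set(seed=1)


@pytest.fixture(scope="session")
def ref_all(study):
    """Calibrated + extrapolated reference (chemotherapy) schedule, stratum 'all'."""
    return n.reference_schedule(study, "all")


@pytest.fixture()
def constant_schedule():
    def make(p=0.1, q=0.2, cycles=40):
        return n.TransitionSchedule(
            p_pf_pd=np.full(cycles, p), p_pd_death=np.full(cycles, q),
            observed_cycles=cycles,
        )
    return make
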