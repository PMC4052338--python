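import numpy as np
import pytest
from hypothesis import settings

import audconn as ac

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_2run():
    return ac.generate_design(7, n_runs=2)


@pytest.fixture(scope="session")
def inputs_2run(design_2run):
    return ac.build_input_functions(design_2run)


@pytest.fixture(scope="session")
def scenario_gt():
    return ac.scenario_paper_effect(0.4)


@pytest.fixture(scope="session")
def subject_ts(scenario_gt, design_2run):
    return ac.generate_subject(scenario_gt, design_2run, seed=1)


def two_node_model(a21=0.3, c=(1.0, 0.0), b21=0.0, modulator="poa"):
    """Small driven two-node chain used throughout the inversion tests.

    Node 1 receives the driving input; the 1->2 connection is the only
    permitted coupling and the only modulated one.
    """
    mask_A = np.array([[False, False], [True, False]])
    A = np.array([[-0.5, 0.0], [a21, -0.5]])
    mask_B = np.array([[False, False], [True, False]])
    B = np.array([[0.0, 0.0], [b21, 0.0]])
    C = np.array([[c[0]], [c[1]]])
    mask_C = np.array([[True], [c[1] != 0.0]])
    return ac.DCMModel(nodes=("n1", "n2"), A=A, B={modulator: B}, C=C,
                       mask_A=mask_A, mask_B={modulator: mask_B},
                       mask_C=mask_C)
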