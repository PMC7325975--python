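import numpy as np
import pytest

import custress as cs


@pytest.fixture(scope="session")
def default_schedules():
    return {
        "control": cs.build_control_schedule(9),
        "gradual": cs.build_gradual_schedule(1.0, 9),
        "abrupt": cs.build_abrupt_schedule(1.0, 9, 5),
    }


@pytest.fixture(scope="session")
def design17():
    return cs.default_design()


@pytest.fixture(scope="session")
def tree32():
    """Fixed 32-tip Yule tree used for signal calibration."""
    tree, _ = cs.generate_phylogeny(
        [f"t{i:02d}" for i in range(32)], seed=5, trait_mode="independent"
    )
    return tree


@pytest.fixture(scope="session")
def tree3():
    """Three-taxon tree with hand-checkable covariance structure."""
    return cs.load_tree("((A:1,B:1):1,C:2);", from_path=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
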