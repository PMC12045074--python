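import pytest

import tavicea as tc


@pytest.fixture(scope="session")
def base_ps():
    """The bundled base-case parameter set."""
    return tc.load_base_case()


@pytest.fixture(scope="session")
def base_result(base_ps):
    """Full two-arm pipeline on the base case (lifetime horizon)."""
    return tc.run_base_case(base_ps)


@pytest.fixture(scope="session")
def equal_arm_ps():
    """Parameter set in which both arms are identical in every input."""
    from tavicea.synth import degenerate_equal_arm_set

    return degenerate_equal_arm_set(seed=7)
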