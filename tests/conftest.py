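import pytest

from gdmcost import build_arm, builtin_pilot_parameters, per_case_cost


@pytest.fixture(scope="session")
def config():
    """The packaged 2011-USA pilot parameterization."""
    return builtin_pilot_parameters()


@pytest.fixture(scope="session")
def calibrated_breakdowns(config):
    """Calibrated per-case breakdowns for the three base-case arms."""
    return {
        name: per_case_cost(build_arm(name, config, mode="calibrated"))
        for name in ("normal", "gdm", "overweight")
    }
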