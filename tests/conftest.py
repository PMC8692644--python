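import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polarfoodweb as pw
from polarfoodweb.fleet import default_fleet
from polarfoodweb.runner import run_scenario

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_forcing():
    return pw.generate_forcing(pw.ScenarioSpec.baseline())


@pytest.fixture(scope="session")
def future_forcing():
    return pw.generate_forcing(pw.ScenarioSpec.future())


@pytest.fixture(scope="session")
def fleet():
    return default_fleet()


@pytest.fixture(scope="session")
def baseline_run(baseline_forcing, fleet):
    t0 = time.time()
    res = run_scenario(baseline_forcing, fleet=fleet)
    res.walltime_s = time.time() - t0
    return res


@pytest.fixture(scope="session")
def future_run(future_forcing, fleet, baseline_run):
    return run_scenario(future_forcing, fleet=fleet,
                        initial_state=baseline_run.state_final)
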