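"""Shared fixtures: the canonical geometry and (session-cached) pipeline runs."""

import io

import pytest
from hypothesis import settings as hsettings

from spinalwave.geometry import load_centerline_table

hsettings.register_profile("deterministic", derandomize=True, deadline=None)
hsettings.load_profile("deterministic")
from spinalwave.materials import DEFAULT_MATERIALS, assemble_compliance_matrix
from spinalwave.pipeline import build_profile, run_pulse_experiment, run_scenario
from spinalwave.synth import builtin_fixture, straightened

#: straight uniform syrinx-bearing waveguide (radii of the x = 95 mm station)
UNIFORM_TABLE = """x_mm,y_mm,r_syrinx_mm,r_cord_mm,r_sas_mm,r_eds_mm
0,0,2.6,3.8,5.1,6.0
175,0,2.6,3.8,5.1,6.0
350,0,2.6,3.8,5.1,6.0
"""


@pytest.fixture(scope="session")
def ms():
    return DEFAULT_MATERIALS


@pytest.fixture(scope="session")
def fixture_samples():
    return builtin_fixture()


@pytest.fixture(scope="session")
def uniform_samples():
    return load_centerline_table(io.StringIO(UNIFORM_TABLE))


@pytest.fixture(scope="session")
def profile(fixture_samples):
    """Resampled (1 mm) and cranially extended fixture profile, with syrinx."""
    return build_profile(fixture_samples)


@pytest.fixture(scope="session")
def compliance(profile, ms):
    return assemble_compliance_matrix(profile, ms)


@pytest.fixture(scope="session")
def pulse_result(fixture_samples, ms):
    return run_pulse_experiment(fixture_samples, ms)


@pytest.fixture(scope="session")
def pulse_result_straight(fixture_samples, ms):
    return run_pulse_experiment(straightened(fixture_samples), ms)


@pytest.fixture(scope="session")
def normal_run(fixture_samples, ms):
    return run_scenario(fixture_samples, ms, "normal")


@pytest.fixture(scope="session")
def chiari_run(fixture_samples, ms):
    return run_scenario(fixture_samples, ms, "chiari_no_syrinx")


@pytest.fixture(scope="session")
def chiari_syrinx_run(fixture_samples, ms):
    return run_scenario(fixture_samples, ms, "chiari_with_syrinx")


@pytest.fixture(scope="session")
def straight_chiari_run(fixture_samples, ms):
    return run_scenario(straightened(fixture_samples), ms, "chiari_no_syrinx")
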