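import numpy as np
import pandas as pd
import pytest

import mcrc_cea as m


@pytest.fixture(scope="session")
def arm_specs():
    return m.trial.default_arm_specs()


@pytest.fixture(scope="session")
def curve_sets():
    """(control, aci) trial-calibrated Weibull curve sets."""
    return m.trial_curve_sets()


@pytest.fixture(scope="session")
def econ():
    return m.default_econ_params()


@pytest.fixture(scope="session")
def settings():
    return m.ModelSettings()


@pytest.fixture(scope="session")
def schedule():
    return m.Schedule()


@pytest.fixture(scope="session")
def patient():
    return m.Patient()


@pytest.fixture(scope="session")
def base_result(curve_sets, econ, settings, schedule, patient):
    control, aci = curve_sets
    return m.run_cea(control, aci, econ, settings, schedule, patient)


@pytest.fixture
def simple_ipd():
    """Five subjects, all events at 1..5 months."""
    return pd.DataFrame(
        {
            "subject_id": range(5),
            "arm": "control",
            "endpoint": "PFS",
            "time_months": [1.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 1, 1, 1, 1],
        }
    )


@pytest.fixture(scope="session")
def run_fn(curve_sets, schedule, patient):
    control, aci = curve_sets

    def _run(econ, settings):
        return m.run_cea(control, aci, econ, settings, schedule, patient)

    return _run
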