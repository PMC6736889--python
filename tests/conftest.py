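import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from metadyn.synthetic import (  # noqa: E402
    build_patient_model,
    generate_patient,
    load_patient_config,
    patient_fixture_path,
)


@pytest.fixture(scope="session")
def patient1():
    """Calibrated adenocarcinoma reference patient (trajectory, scenario)."""
    cfg = load_patient_config(patient_fixture_path("patient1"))
    traj, scenario = build_patient_model(cfg)
    return cfg, traj, scenario


@pytest.fixture(scope="session")
def patient2():
    """Calibrated squamous reference patient (trajectory, scenario)."""
    cfg = load_patient_config(patient_fixture_path("patient2"))
    traj, scenario = build_patient_model(cfg)
    return cfg, traj, scenario


@pytest.fixture(scope="session")
def patient1_tables(patient1):
    cfg, traj, scenario = patient1
    pt, bm, truth = generate_patient(cfg)
    return pt, bm, truth
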