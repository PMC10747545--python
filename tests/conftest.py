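import pytest

from ondapbpk.drug import load_ondansetron
from ondapbpk.engine import DosingRegimen, build_model, simulate_individual
from ondapbpk.physiology import build_reference_physiology


@pytest.fixture(scope="session")
def drug():
    return load_ondansetron()


@pytest.fixture(scope="session")
def ref_phys():
    return build_reference_physiology(73.0, 30.0, "male")


@pytest.fixture(scope="session")
def iv5():
    return DosingRegimen(route="iv_infusion", dose=8.0, infusion_duration=5.0)


@pytest.fixture(scope="session")
def iv15():
    return DosingRegimen(route="iv_infusion", dose=8.0, infusion_duration=15.0)


@pytest.fixture(scope="session")
def oral8():
    return DosingRegimen(route="oral", dose=8.0)


@pytest.fixture(scope="session")
def healthy_iv_profile(drug, ref_phys, iv5):
    """Calibrated healthy reference subject, 8 mg IV over 5 min."""
    model = build_model(drug, ref_phys, iv5)
    return model, simulate_individual(model)


@pytest.fixture(scope="session")
def healthy_oral_profile(drug, ref_phys, oral8):
    model = build_model(drug, ref_phys, oral8)
    return model, simulate_individual(model)
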