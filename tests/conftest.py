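import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spatialimmune.synthetic import CohortConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def mihc_cohort():
    """10-patient synthetic cohort with the full marker panel."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42))


@pytest.fixture(scope="session")
def gated(mihc_cohort):
    from spatialimmune.phenotyping import classify_cell_types, gate_cells

    cells = mihc_cohort[0]
    positivity = gate_cells(cells)
    classes = classify_cell_types(positivity)
    return positivity, classes


@pytest.fixture(scope="session")
def hne_cohort():
    """H&E-flavor cohort (no marker panel), larger n for proportion tests."""
    return generate_cohort(CohortConfig(n_patients=24, seed=7, marker_panel=()))
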