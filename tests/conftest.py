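import logging

import pytest
from hypothesis import settings

from barrel4.ffi import RescueScenario, rescue_matrix, sweep_ga_frequency
from barrel4.params import default_genotype_params

# deterministic property-based testing
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# placeholder-parameter warnings are intentional but noisy under pytest
logging.getLogger("barrel4.params").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def wt():
    return default_genotype_params("WT")


@pytest.fixture(scope="session")
def ko():
    return default_genotype_params("KO")


@pytest.fixture(scope="session")
def default_sweeps(wt, ko):
    """Full-grid single-cell sweeps for both genotypes (shared, ~3 s)."""
    return {
        "WT": sweep_ga_frequency(wt),
        "KO": sweep_ga_frequency(ko),
    }


@pytest.fixture(scope="session")
def rescue(wt, ko):
    """All 16 rescue scenarios on the default grid (shared, ~20 s)."""
    results, summary = rescue_matrix(wt, ko)
    return {"results": results, "summary": summary}


def scenario_row(summary, stp, delay, intrinsic, kinetics):
    """Select the summary row of one scenario by its group flags."""
    m = (
        (summary["stp_wt"] == stp)
        & (summary["delay_wt"] == delay)
        & (summary["intrinsic_wt"] == intrinsic)
        & (summary["kinetics_wt"] == kinetics)
    )
    rows = summary[m]
    assert len(rows) == 1
    return rows.iloc[0]


@pytest.fixture(scope="session")
def all_wt_scenario():
    return RescueScenario(True, True, True, True)


@pytest.fixture(scope="session")
def all_ko_scenario():
    return RescueScenario(False, False, False, False)
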