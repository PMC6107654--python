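import pytest

from ssge import synthgen as sg
from ssge.paneldesign import GenePanel


@pytest.fixture(scope="session")
def paper_sim():
    return sg.paper_design()


@pytest.fixture(scope="session")
def cohort(paper_sim):
    """One seven-group cohort at the default calibration."""
    return sg.simulate_cohort(paper_sim, seed=7)


@pytest.fixture(scope="session")
def panel(paper_sim, cohort):
    """Six-gene panel with control means taken from the cohort's controls."""
    controls = cohort[cohort["group"] == "C"]
    return GenePanel.from_controls(
        list(paper_sim.design.genes), paper_sim.design.directions, controls
    )


@pytest.fixture(scope="session")
def selection_fixture():
    return sg.make_selection_fixture(seed=1)
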