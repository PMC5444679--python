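import pytest

import kmflux as kf


@pytest.fixture(scope="session")
def ref_model():
    return kf.build_reference_model()


@pytest.fixture(scope="session")
def figure_reports(ref_model):
    """All eleven figure scenarios, solved once per session (no FVA)."""
    return {
        fig: kf.run_scenario(ref_model, kf.scenario_registry(fig), fva=False)
        for fig in kf.FIGURE_IDS
    }


@pytest.fixture(scope="session")
def fig2_with_fva(ref_model):
    return kf.run_scenario(ref_model, kf.scenario_registry("fig2"), fva=True)
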