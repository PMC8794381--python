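import pytest

import clonecomp as cc


@pytest.fixture(scope="session")
def params():
    return cc.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def schedule():
    return cc.PhaseSchedule()


@pytest.fixture(scope="session")
def noiseless_bundle(params, schedule):
    """Noiseless synthetic datasets generated at the reference parameter set."""
    design = cc.ExperimentDesign()
    noise = cc.NoiseConfig.noiseless()
    curves_L = cc.generate_homotypic_timelapse(params, schedule, "L", design, noise)
    curves_W = cc.generate_homotypic_timelapse(params, schedule, "W", design, noise)
    assays_72 = cc.generate_competition_assays(params, schedule, design, noise)
    assays_96 = cc.generate_competition_assays(
        params, schedule, cc.ExperimentDesign(round_duration=96.0), noise
    )
    return curves_L, curves_W, assays_72, assays_96


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_bundle, schedule):
    """Full pipeline run on the noiseless bundle (shared across tests)."""
    curves_L, curves_W, a72, a96 = noiseless_bundle
    model = cc.SubcloneCompetitionModel(curves_L, curves_W, a72, a96, schedule)
    return model.fit()
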