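import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fpnbind import models, pipeline, simulate  # noqa: E402


@pytest.fixture(scope="session")
def wt_direct() -> models.DirectBindingParams:
    """WT-like signal model: tracer K_D 100 nM with the shared calibration."""
    return models.DirectBindingParams(
        b_max=simulate.SHARED_SIGNAL["b_max"],
        k_d=100.0,
        ns_slope=simulate.SHARED_SIGNAL["ns_slope"],
        background=simulate.SHARED_SIGNAL["background"],
    )


@pytest.fixture(scope="session")
def study_config() -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(l_dis_overrides={"R466A": 800.0})


@pytest.fixture(scope="session")
def noiseless_study_report(study_config):
    """Full two-stage pipeline on a zero-noise plate of all study truths."""
    plate = simulate.gen_study_plate(seed=7, fp_sd_mp=0.0)
    return pipeline.run_pipeline(plate, study_config)


@pytest.fixture(scope="session")
def noisy_wt_plate():
    """WT-only plate at the study noise level (sigma = 5 mP)."""
    return simulate.gen_study_plate(seed=11, constructs=["WT"])
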