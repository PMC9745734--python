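import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def replay_result():
    """Full pipeline run on the replay cohort of the audited study margins."""
    from triageaudit.report import RunConfig, run_audit

    return run_audit(RunConfig(mode="replay", seed=1))


@pytest.fixture(scope="session")
def replay_records():
    """The same replay cohort as raw records (seed 1, exclusions included)."""
    from triageaudit.synthetic_data import replay_cohort, study_margins

    return replay_cohort(study_margins(), seed=1)
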