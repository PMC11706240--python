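import pytest

from satbench import ExperimentDesign, TrialRecord


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


def make_trial(**kw) -> TrialRecord:
    """A valid timed trial; override any field via keywords."""
    base = dict(
        observer_id="obsA",
        experiment="gray_noise",
        phase="timed",
        block_index=1,
        beep_latency_ms=500,
        perturbation_kind="noise",
        perturbation_level=0.04,
        true_category="cat",
        response_category="cat",
        response_time_ms=510.0,
        trial_index=11,
        image_id="im1",
    )
    base.update(kw)
    return TrialRecord(**base)


def make_training_trial(**kw) -> TrialRecord:
    base = dict(
        phase="training",
        block_index=0,
        beep_latency_ms=None,
        response_time_ms=1200.0,
        trial_index=kw.pop("trial_index", 1),
    )
    base.update(kw)
    return make_trial(**base)
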