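import numpy as np
import pytest

from e4stress import (
    SampledSignal,
    SubjectModel,
    generate_eda,
    generate_ppg,
    label_schedule_from_protocol,
    process_recording,
)


@pytest.fixture(scope="session")
def schedule():
    """Default acquisition protocol with the untimed task set to 4 minutes."""
    return label_schedule_from_protocol({"task4": 240})


@pytest.fixture(scope="session")
def clean_subject():
    """Artifact-free subject: recovery checks measure the chain, not noise."""
    return SubjectModel(seed=1, artifact_rate_per_min=0.0)


@pytest.fixture(scope="session")
def clean_recording(schedule, clean_subject):
    """One artifact-free session: (bvp, bvp_truth, eda, eda_truth)."""
    bvp, bvp_truth = generate_ppg(clean_subject, schedule)
    eda, eda_truth = generate_eda(clean_subject, schedule)
    return bvp, bvp_truth, eda, eda_truth


@pytest.fixture(scope="session")
def clean_pipeline_result(schedule, clean_recording):
    bvp, _, eda, _ = clean_recording
    return process_recording(bvp, eda, schedule, subject_id="S01")


def make_signal(values, rate_hz=64.0, start=1_600_000_000.0):
    return SampledSignal(values=np.asarray(values, dtype=float), rate_hz=rate_hz,
                        start_utc_s=start)
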