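import numpy as np
import pytest

import synkin


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 3-module cohort shared by extraction/clustering/reporting tests."""
    gt = synkin.make_ground_truth(3, seed=7, noise_sd=0.05)
    recs, manifest = synkin.simulate_cohort(
        gt, n_subjects=5, n_grasps=8, n_repetitions=4, sample_rate=25.0, seed=7
    )
    sms = [synkin.preprocess_recording(r) for r in recs]
    pcsets = [synkin.extract_pcs(sm) for sm in sms]
    return gt, recs, manifest, sms, pcsets


def make_recording(
    angles, stimulus=None, repetition=None, sample_rate=25.0, subject_id="T"
):
    angles = np.asarray(angles, dtype=float)
    n = angles.shape[0]
    if stimulus is None:
        stimulus = np.zeros(n, dtype=int)
    if repetition is None:
        repetition = (np.asarray(stimulus) > 0).astype(int)
    return synkin.JointAngleRecording(
        subject_id=subject_id,
        sample_rate=sample_rate,
        angles=angles,
        stimulus=np.asarray(stimulus),
        repetition=np.asarray(repetition),
    )
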