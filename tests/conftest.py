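import numpy as np
import pytest

import synergait as sg


@pytest.fixture(scope="session")
def unit_gains_gt():
    """Ground truth with unit gains at every support level."""
    return sg.make_ground_truth(seed=5)


@pytest.fixture(scope="session")
def study_gains_gt():
    """Ground truth whose level gains follow the study's printed modulations."""
    return sg.make_ground_truth(level_gains=sg.STUDY_LEVEL_GAINS, seed=42)


@pytest.fixture(scope="session")
def session_default(unit_gains_gt):
    return sg.simulate_session(unit_gains_gt, seed=6)


def analyse_session(gt, sess, nnmf_seed=0):
    """Full analysis chain for one simulated session; returns (X, index, model)."""
    rec = sg.interpolate_artifacts(sess.emg)
    rec = sg.filter_emg(rec)
    env = sg.envelope(rec)
    timeline = sg.select_valid_strides(sess.timeline, sess.interruptions)
    body_weight = sg.estimate_body_weight(sess.weighing)
    support = sg.bws_per_stride(sess.force, timeline, body_weight)
    cycles = sg.time_normalize(env, timeline)
    cycles = sg.attach_levels(cycles, support.level)
    cycles = sg.scale_to_low_support(cycles)
    X, index = sg.concatenate_levels(sg.grand_average(cycles))
    model = sg.select_n(X, index, seed=nnmf_seed, channels=cycles.channels)
    return X, index, sg.order_synergies(model)


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty seeded synthetic studies analysed end-to-end.

    Shared by the synergy-count and parameter-recovery checks; each entry
    holds the ground truth and the fitted, ordered model.
    """
    runs = []
    for seed in range(1, 21):
        gt = sg.make_ground_truth(level_gains=sg.STUDY_LEVEL_GAINS, seed=seed)
        sess = sg.simulate_session(gt, seed=10_000 + seed)
        _, _, model = analyse_session(gt, sess, nnmf_seed=seed)
        runs.append((gt, model))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
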