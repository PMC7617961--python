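import numpy as np
import pytest

from tonicpag import synth


@pytest.fixture(scope="session")
def default_session():
    """Default-condition synthetic session (slow indicator, noise 0.5 Z)."""
    return synth.gen_session(synth.SessionSpec(seed=42))


@pytest.fixture(scope="session")
def clean_fast_session():
    """Noiseless session with a near-instantaneous indicator rise, for
    construction-level checks where peak timing must not lag the drive."""
    return synth.gen_session(
        synth.SessionSpec(
            n_ramp=3,
            n_dip=3,
            n_unmod=2,
            n_trials=6,
            n_fail_trials=2,
            noise_sd=0.0,
            kernel_rise=0.01,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def two_motif_session():
    """Two-motif session at the cohort scale used for clustering."""
    return synth.gen_session(
        synth.SessionSpec(n_ramp=72, n_dip=48, n_unmod=0, seed=11)
    )


def trial_windows(session, trial, pad_s=2.0):
    """Frame-index window of one trial (stimulus to escape stop + pad)."""
    fs = session.frame_rate
    i0 = int(round(trial.stimulus_onset * fs))
    end = max(trial.events.values()) + pad_s
    i1 = int(round(end * fs))
    return i0, i1
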