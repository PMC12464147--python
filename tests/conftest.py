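import copy

import numpy as np
import pytest

import nocturne as nt


@pytest.fixture(scope="session")
def cohort():
    """A default-sized cohort with ground truth (seed 1)."""
    profiles, truth = nt.generate_cohort(nt.SimConfig(n_subjects=79, seed=1))
    return profiles, truth


@pytest.fixture
def subject(cohort):
    profiles, truth = cohort
    return profiles[0], copy.deepcopy(truth[0])


def make_clean_night(subject_pair, ppt_ms, hours=0.15, seed=11, **overrides):
    """Noise-free constant-PPT night for construction-oracle tests."""
    profile, truth = subject_pair
    truth = copy.deepcopy(truth)
    truth.true_mean_ppt = float(ppt_ms)
    cfg = nt.SimConfig(seed=seed, night_hours=hours, noise_sd=0.0,
                       artifact_fraction=0.0, baseline_wander_amp=0.0,
                       ppt_beat_sd_ms=0.0, **overrides)
    record = nt.simulate_ppg_night(profile, truth, cfg)
    return record, truth, cfg


@pytest.fixture
def clean_night_factory(subject):
    def _make(ppt_ms, **kw):
        return make_clean_night(subject, ppt_ms, **kw)
    return _make
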