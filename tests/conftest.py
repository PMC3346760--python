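"""Shared fixtures: small synthetic recordings and aligned feature/truth pairs."""

import numpy as np
import pytest

import lfp2spike as l
from lfp2spike.synthetic import (
    GroundTruth,
    LFPSimSpec,
    ProtocolSpec,
    first_pulse_events,
    make_dataset,
)


@pytest.fixture(scope="session")
def small_recording():
    """A 100-couplet noise-free recording with known ground truth."""
    gt = GroundTruth(spike_noise=0.0)
    rec = make_dataset(ProtocolSpec(n_couplets=100), LFPSimSpec(), gt, seed=11)
    return rec, gt


@pytest.fixture(scope="session")
def aligned_data(small_recording):
    """(features, truth) extracted from the small recording the pipeline way."""
    rec, gt = small_recording
    trials = first_pulse_events(rec.events)
    feats = l.extract_features(rec.lfp, trials, (0.0, 50.0))
    truth = l.binarize_spikes(rec.spikes, trials, (0.0, 50.0))
    return feats, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
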