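"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from arteeg import montage, preprocess, studies, synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_session():
    """One short synthetic session on the full 32-channel montage."""
    spec = synthetic.SessionSpec(
        subject_id="S00", seed=11, baseline_s=12.0,
        pieces=[synthetic.PieceEpoch("1", "complex", 6.0),
                synthetic.PieceEpoch("2", "moderate", 6.0),
                synthetic.PieceEpoch("4", "complex", 6.0)],
        channels=montage.ACTICAP_32)
    rec, truth = synthetic.generate_session(spec)
    return rec, truth, spec


@pytest.fixture(scope="session")
def small_feature_table():
    """Feature table from a 6-subject cohort on the retained montage."""
    table, meta = studies.clustering_feature_table(n_subjects=6, seed=5)
    return table, meta


@pytest.fixture(scope="session")
def small_epoch_adtf():
    """ADTF tensor for one coupled epoch on the small lateralized montage."""
    from arteeg import connectivity as conn

    chs = list(studies.SMALL_MONTAGE)
    spec = synthetic.ConnectivitySpec(
        len(chs),
        couplings=[synthetic.Coupling(chs.index("O2"), chs.index("O1"), 0.35,
                                      freq=10.0),
                   synthetic.Coupling(chs.index("F4"), chs.index("F3"), 0.35,
                                      freq=10.0)],
        osc_freqs=10.0, damping=0.92, noise_scale=1.0)
    rec, _ = synthetic.simulate_mvar_eeg(spec, 5.0, 250.0, 21, ch_names=chs)
    tensor = conn.epoch_adtf(rec.data, 250.0, chs, p=2, target_fs=250.0)
    return tensor


@pytest.fixture()
def cleaned_epochs(tiny_session):
    rec, _, _ = tiny_session
    epochs, _ = preprocess.preprocess_recording(rec, subject_id="S00")
    return epochs
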