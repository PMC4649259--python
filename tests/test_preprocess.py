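"""Cleaning chain: filtering, bad channels, ASR, CAR, segmentation."""

import numpy as np
import pytest

from arteeg import montage, preprocess, synthetic
from arteeg.recording import Recording


def _rec(data, fs=250.0, names=None, ann=()):
    names = names or [f"ch{i}" for i in range(len(data))]
    return Recording(np.asarray(data, dtype=float), names, fs, list(ann))


class TestHighpass:
    def test_dc_removed(self):
        rec = _rec(np.full((2, 2500), 100.0))
        out = preprocess.highpass_filter(rec)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_passband_preserved(self):
        t = np.arange(2500) / 250.0
        rec = _rec([np.sin(2 * np.pi * 10 * t)])
        out = preprocess.highpass_filter(rec)
        mid = slice(500, 2000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.01

    def test_deep_stopband_attenuation(self):
        # evaluate the designed filter's own magnitude response at 0.01 Hz
        assert preprocess.highpass_response_db(1000.0, 0.01) < -20.0

    def test_nonfinite_sample_names_channel(self):
        data = np.zeros((2, 600))
        data[1, 5] = np.nan
        with pytest.raises(ValueError, match="ch1"):
            preprocess.highpass_filter(_rec(data))


class TestBadChannels:
    def test_identical_sinusoids_no_rejection(self, rng):
        t = np.arange(2500) / 250.0
        base = np.sin(2 * np.pi * 10 * t)
        data = np.array([base + 0.01 * rng.standard_normal(t.size)
                         for _ in range(5)])
        report = preprocess.detect_bad_channels(_rec(data), corr_threshold=0.4)
        assert report.rejected == []

    def test_noise_channel_rejected(self, rng):
        t = np.arange(2500) / 250.0
        base = np.sin(2 * np.pi * 10 * t)
        data = np.array([base + 0.05 * rng.standard_normal(t.size)
                         for _ in range(5)])
        data[2] = rng.standard_normal(t.size)      # pure noise channel
        report = preprocess.detect_bad_channels(_rec(data), corr_threshold=0.4)
        assert report.rejected == ["ch2"]
        # brute-force check of the per-window fractions for the bad channel
        wlen = 500
        frac = []
        for w in range(data.shape[1] // wlen):
            c = np.corrcoef(data[:, w * wlen:(w + 1) * wlen])
            frac.append(np.mean(np.abs(np.delete(c[2], 2)) < 0.4) >= 0.8)
        assert np.mean(frac) >= 0.5

    def test_short_recording_errors(self):
        with pytest.raises(ValueError, match="window"):
            preprocess.detect_bad_channels(_rec(np.zeros((3, 100))))


class TestPeripheralRemoval:
    def test_default_list_reduces_32_to_20(self):
        rec = _rec(np.zeros((32, 300)), names=list(montage.ACTICAP_32))
        out = preprocess.remove_peripheral_channels(rec)
        assert out.n_channels == 20
        assert out.ch_names == list(montage.RETAINED_20)

    def test_case_insensitive_match(self):
        rec = _rec(np.zeros((32, 300)), names=list(montage.ACTICAP_32))
        out = preprocess.remove_peripheral_channels(rec, ["FP1", "FP2"])
        assert out.n_channels == 30

    def test_empty_list_identity_and_degenerate(self):
        rec = _rec(np.zeros((3, 300)), names=["F3", "F4", "Cz"])
        assert preprocess.remove_peripheral_channels(rec, []).ch_names == \
            ["F3", "F4", "Cz"]
        with pytest.raises(ValueError, match="no channels"):
            preprocess.remove_peripheral_channels(rec, ["F3", "F4", "Cz"])
        with pytest.raises(ValueError, match="unknown"):
            preprocess.remove_peripheral_channels(rec, ["Qz"], strict=True)


class TestASR:
    def _calib(self, rng, n_ch=4, seconds=8.0, fs=250.0):
        data = rng.standard_normal((n_ch, int(seconds * fs))) * 10.0
        return _rec(data, fs)

    def test_clean_input_near_identity(self, rng):
        calib = self._calib(rng)
        rec = _rec(rng.standard_normal((4, 1000)) * 10.0)
        out = preprocess.asr_clean(rec, calib, k_sd=8.0)
        assert np.allclose(out.data, rec.data, atol=1e-9)

    def test_pop_attenuated(self, rng):
        calib = self._calib(rng)
        rec = _rec(rng.standard_normal((4, 1500)) * 10.0)
        rec, _ = synthetic.inject_artifacts(
            rec, synthetic.ArtifactPlan(pops=[(1, 2.0, 500.0, 0.2)]), seed=0)
        s0, s1 = int(2.0 * 250), int(2.2 * 250)
        before = np.max(np.abs(rec.data[1, s0:s1]))
        out = preprocess.asr_clean(rec, calib, k_sd=3.0)
        after = np.max(np.abs(out.data[1, s0:s1]))
        assert before >= 500.0
        assert after <= 0.5 * before

    def test_infinite_threshold_is_identity(self, rng):
        calib = self._calib(rng)
        rec = _rec(rng.standard_normal((4, 900)) * 50.0)
        out = preprocess.asr_clean(rec, calib, k_sd=np.inf)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_short_calibration_rejected(self, rng):
        calib = _rec(rng.standard_normal((4, 500)))
        rec = _rec(rng.standard_normal((4, 900)))
        with pytest.raises(ValueError, match="5 s"):
            preprocess.asr_clean(rec, calib)


class TestCAR:
    def test_mean_is_zero(self, rng):
        rec = _rec(rng.standard_normal((6, 500)) + 20.0)
        out = preprocess.rereference_car(rec)
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-9

    def test_zero_mean_input_unchanged(self):
        rec = _rec(np.array([[1.0] * 100, [-1.0] * 100]))
        out = preprocess.rereference_car(rec)
        np.testing.assert_allclose(out.data, rec.data)

    def test_single_channel_errors(self):
        with pytest.raises(ValueError):
            preprocess.rereference_car(_rec(np.zeros((1, 100))))


class TestSegmentation:
    def _session_rec(self, rng, n_pieces=8, fs=250.0):
        dur = 20.0 + n_pieces * 6.0
        data = rng.standard_normal((3, int(dur * fs)))
        ann = [("baseline", 0)] + [
            (f"piece_{k}", int((20.0 + 6.0 * k) * fs)) for k in range(n_pieces)]
        return _rec(data, fs, ann=ann)

    def test_full_session_epoch_counts(self, rng):
        es = preprocess.segment_epochs(self._session_rec(rng))
        assert len(es.epochs) == 8
        assert all(ep.segments.shape[0] == 5 for ep in es.epochs)
        assert es.baseline is not None
        assert es.baseline.segments.shape[0] == 5

    def test_truncated_epoch_dropped(self, rng, caplog):
        rec = self._session_rec(rng, n_pieces=2)
        rec.annotations.append(("piece_late", rec.n_samples - 100))
        rec = Recording(rec.data, rec.ch_names, rec.fs, rec.annotations)
        import logging
        with caplog.at_level(logging.WARNING, logger="arteeg.preprocess"):
            es = preprocess.segment_epochs(rec)
        assert len(es.epochs) == 2
        assert any("truncated" in r.message for r in caplog.records)

    def test_degenerate_single_segment(self, rng):
        es = preprocess.segment_epochs(self._session_rec(rng, n_pieces=1),
                                       epoch_len=5.0, sub_len=5.0)
        assert es.epochs[0].segments.shape[0] == 1


class TestFullChain:
    def test_car_invariant_and_counts(self, cleaned_epochs):
        es = cleaned_epochs
        assert len(es.epochs) == 3
        assert es.baseline is not None
        # CAR zero-sum holds on every emitted segment
        for ep in es.all_epochs():
            means = np.asarray(ep.segments).mean(axis=1)
            assert np.max(np.abs(means)) < 1e-6
        assert es.ch_names == list(montage.RETAINED_20)
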