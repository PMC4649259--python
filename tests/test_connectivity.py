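"""Kalman MVAAR tracking, ADTF normalization/directionality, patterns, stats."""

import numpy as np
import pandas as pd
import pytest

from arteeg import connectivity as conn
from arteeg import montage, studies, synthetic
from arteeg.features import BANDS

ALPHA = BANDS[2]


class TestKalmanFit:
    def test_stationary_recovery_vs_truth_and_ls(self):
        out = studies.stationary_var2_recovery(seed=0)
        assert out["rmse_kalman_truth"] < 0.1
        assert out["rmse_kalman_ls"] < 0.1

    def test_ls_oracle_matches_statsmodels(self):
        # independent cross-check of the least-squares reference itself
        from statsmodels.tsa.api import VAR

        spec = synthetic.ConnectivitySpec(
            3, couplings=[synthetic.Coupling(0, 1, 0.3)],
            osc_freqs=[9.0, 10.0, 11.0], damping=0.9, noise_scale=1.0)
        rec, _ = synthetic.simulate_mvar_eeg(spec, 5.0, 250.0, 4)
        ours = conn.least_squares_var(rec.data, p=2)
        sm = VAR(rec.data.T).fit(maxlags=2, trend="n")
        theirs = np.concatenate([sm.coefs[0], sm.coefs[1]], axis=1)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_step_coupling_tracked_within_a_second(self):
        spec = synthetic.ConnectivitySpec(
            2, couplings=[synthetic.Coupling(0, 1, 0.4, freq=10.0, onset=2.5)],
            osc_freqs=10.0, damping=0.9, noise_scale=1.0)
        rec, _ = synthetic.simulate_mvar_eeg(spec, 5.0, 250.0, 3)
        model = conn.fit_mvaar_kalman(rec.data, 250.0, p=2, update_coeff=5e-3)
        cc = model.coeffs[:, 1, 0]           # lag-1 coupling coefficient
        t = np.arange(len(cc)) / 250.0
        pre = cc[(t > 2.0) & (t < 2.5)].mean()
        mid = (pre + 0.4) / 2.0
        crossings = t[(t > 2.5) & (cc > mid)]
        assert crossings.size and crossings[0] < 3.5

    def test_white_noise_coefficients_near_zero(self, rng):
        data = rng.standard_normal((3, 1250))
        model = conn.fit_mvaar_kalman(data, 250.0, p=2)
        assert np.max(np.abs(model.mean_coeffs())) < 0.1

    def test_guards(self, rng):
        with pytest.raises(ValueError):
            conn.fit_mvaar_kalman(rng.standard_normal((2, 30)), 250.0, p=5)
        with pytest.raises(ValueError):
            conn.fit_mvaar_kalman(rng.standard_normal((2, 500)), 250.0,
                                  p=2, update_coeff=2.0)


class TestADTF:
    def test_row_normalization(self, small_epoch_adtf):
        sums = small_epoch_adtf.gamma2.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_unidirectional_asymmetry(self):
        out = studies.directionality_ratio(seed=0)
        assert out["ratio"] > 5.0
        np.testing.assert_allclose(out["tensor"].gamma2.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_uncoupled_model_stays_diagonal(self):
        # diagonal coefficients -> H(f) diagonal in closed form, so all
        # off-diagonal gamma^2 vanish
        spec = synthetic.ConnectivitySpec(3, osc_freqs=[9.0, 10.0, 11.0],
                                          damping=0.9, noise_scale=1.0)
        a1, a2 = spec.lag_matrices(250.0, [])
        coeffs = np.tile(np.concatenate([a1, a2], axis=1), (500, 1, 1))
        model = conn.MVAARModel(coeffs=coeffs, order=2, fs=250.0,
                                ch_names=["a", "b", "c"], update_coeff=1e-3,
                                innovation_var=np.ones(3))
        tensor = conn.adtf(model)
        off = tensor.gamma2.copy()
        for i in range(3):
            off[i, i] = 0.0
        assert np.max(off) < 0.1
        np.testing.assert_allclose(tensor.gamma2.sum(axis=1), 1.0, atol=1e-6)


class TestPatterns:
    def test_pair_counts_on_retained_montage(self):
        pats = conn.define_patterns(montage.RETAINED_20)
        anterior = [ch for ch in montage.RETAINED_20 if montage.is_anterior(ch)]
        posterior = [ch for ch in montage.RETAINED_20 if montage.is_posterior(ch)]
        assert len(pats["A->P"].pairs) == len(anterior) * len(posterior)
        assert len(pats["P->A"].pairs) == len(anterior) * len(posterior)

    def test_lateral_patterns_exclude_midline(self):
        pats = conn.define_patterns(montage.RETAINED_20)
        for name in ("L->R", "R->L", "L->L", "R->R"):
            for src, tgt in pats[name].pairs:
                assert not src.endswith("z") and not tgt.endswith("z")
        assert all(s != t for s, t in pats["L->L"].pairs)

    def test_missing_channel_shrinks_patterns(self):
        full = conn.define_patterns(montage.RETAINED_20)
        reduced = conn.define_patterns(
            [ch for ch in montage.RETAINED_20 if ch != "O2"])
        assert len(reduced["P->A"].pairs) < len(full["P->A"].pairs)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            conn.define_patterns(["F3", "bogus!"])


class TestPatternSamples:
    def test_threshold_extremes(self, small_epoch_adtf):
        pats = conn.define_patterns(small_epoch_adtf.ch_names)
        empty = conn.pattern_samples(small_epoch_adtf, ALPHA, pats["R->L"],
                                     threshold=1.0)
        assert empty.values.size == 0
        full = conn.pattern_samples(small_epoch_adtf, ALPHA, pats["R->L"],
                                    threshold=0.0)
        n_bins = int(small_epoch_adtf.band_sel(ALPHA).sum())
        expected = len(pats["R->L"].pairs) * n_bins * len(small_epoch_adtf.times)
        assert full.values.size == expected

    def test_boosted_coupling_raises_median(self, small_epoch_adtf):
        pats = conn.define_patterns(small_epoch_adtf.ch_names)
        chs = list(studies.SMALL_MONTAGE)
        null = synthetic.ConnectivitySpec(len(chs), osc_freqs=10.0,
                                          damping=0.92, noise_scale=1.0)
        rec, _ = synthetic.simulate_mvar_eeg(null, 5.0, 250.0, 22, ch_names=chs)
        base_t = conn.epoch_adtf(rec.data, 250.0, chs, p=2, target_fs=250.0)
        boosted = conn.pattern_samples(small_epoch_adtf, ALPHA, pats["R->L"], 0.0)
        base = conn.pattern_samples(base_t, ALPHA, pats["R->L"], 0.0)
        assert np.median(boosted.values) > np.median(base.values)


class TestConditionContrast:
    def test_identical_samples_null_report(self, rng):
        v = rng.uniform(0.3, 0.9, 200)
        rep = conn.compare_conditions(v, v.copy())
        assert rep["comparable"]
        assert rep["median_viewing"] == rep["median_baseline"]
        assert rep["p_two_sided"] > 0.9

    def test_empty_sample_flagged(self):
        rep = conn.compare_conditions(np.empty(0), np.array([0.5]))
        assert rep["comparable"] is False

    def test_elevated_coupling_detected(self):
        out = studies.condition_contrast_replicate(0.35, 0.0, seed=5)
        assert out["p_one_sided"] < 0.05

    def test_null_type_one_error_short_run(self):
        # 40-replicate sanity check; the full 200-replicate calibration runs
        # in the acceptance suite
        out = studies.null_rejection_rate(n_reps=40, seed=9)
        assert out["rejection_rate"] <= 0.15


class TestCountsAndTimecourse:
    def test_counts_monotone_and_topsource(self, small_epoch_adtf):
        pats = conn.define_patterns(small_epoch_adtf.ch_names)
        at_0 = conn.count_strong_connections(small_epoch_adtf, ALPHA, pats, 0.0)
        at_03 = conn.count_strong_connections(small_epoch_adtf, ALPHA, pats, 0.3)
        at_1 = conn.count_strong_connections(small_epoch_adtf, ALPHA, pats, 1.0)
        for name in pats:
            c0 = at_0[name]["counts"]["count"].to_numpy()
            c3 = at_03[name]["counts"]["count"].to_numpy()
            c1 = at_1[name]["counts"]["count"].to_numpy()
            assert np.all(c3 <= c0) and np.all(c1 == 0)
        # the generator drives O2->O1 and F4->F3; R->L supra-threshold counts
        # should concentrate on those sources
        rl = at_03["R->L"]["counts"]
        strongest = rl.loc[rl["count"].idxmax()]
        assert (strongest["source"], strongest["target"]) in \
            {("O2", "O1"), ("F4", "F3")}

    def test_five_windows_for_five_seconds(self, small_epoch_adtf):
        pats = conn.define_patterns(small_epoch_adtf.ch_names)
        tc = conn.pattern_timecourse(small_epoch_adtf, ALPHA, pats)
        assert tc.shape[1] == 5
        assert set(tc.index) == set(conn.PATTERN_NAMES)

    def test_windowed_coupling_elevates_matching_windows(self):
        chs = list(studies.SMALL_MONTAGE)
        spec = synthetic.ConnectivitySpec(
            len(chs),
            couplings=[synthetic.Coupling(chs.index("O2"), chs.index("O1"),
                                          0.5, freq=10.0, onset=1.0, offset=3.0)],
            osc_freqs=10.0, damping=0.92, noise_scale=1.0)
        rec, _ = synthetic.simulate_mvar_eeg(spec, 5.0, 250.0, 31, ch_names=chs)
        tensor = conn.epoch_adtf(rec.data, 250.0, chs, p=2, target_fs=250.0,
                                 update_coeff=5e-3)
        pats = conn.define_patterns(chs)
        tc = conn.pattern_timecourse(tensor, ALPHA, pats).loc["R->L"]
        active = tc[["window_1", "window_2"]].mean()
        quiet = tc[["window_0", "window_4"]].mean()
        assert active > quiet


class TestGroupContrast:
    def _strength_sets(self, scale_a, scale_b, seed):
        rng = np.random.default_rng(seed)
        keys = [("alpha", p) for p in conn.PATTERN_NAMES]
        return {
            "a": {k: rng.uniform(0.1, 0.4, 12) * scale_a for k in keys},
            "b": {k: rng.uniform(0.1, 0.4, 12) * scale_b for k in keys},
        }

    def test_null_groups_mostly_insignificant(self):
        rep = conn.group_contrast(self._strength_sets(1.0, 1.0, 0))
        assert rep["significant"].sum() <= 1

    def test_elevated_group_dominates(self):
        rep = conn.group_contrast(self._strength_sets(2.0, 1.0, 1))
        assert rep["significant"].all()
        assert (rep["mean_a"] > rep["mean_b"]).all()

    def test_permuted_groups_destroy_significance(self):
        samples = self._strength_sets(2.0, 1.0, 2)
        rng = np.random.default_rng(3)
        permuted = {"a": {}, "b": {}}
        for k in samples["a"]:
            pooled = np.concatenate([samples["a"][k], samples["b"][k]])
            perm = rng.permutation(pooled)
            permuted["a"][k] = perm[:12]
            permuted["b"][k] = perm[12:]
        rep = conn.group_contrast(permuted)
        assert rep["significant"].sum() <= 2

    def test_single_member_group_descriptive(self):
        samples = {"a": {"k": np.array([0.5])}, "b": {"k": np.full(5, 0.4)}}
        rep = conn.group_contrast(samples)
        assert rep.loc[0, "descriptive_only"]
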