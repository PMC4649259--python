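"""mRMR ranking, US-ELM embedding, clustering metrics and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from arteeg import cluster as cl


def _informative_set(rng, n=120, n_inform=10, n_noise=90, sep=3.0):
    labels = np.repeat([0, 1, 2], n // 3)
    cols = {}
    for j in range(n_inform):
        centers = rng.normal(0, sep, 3)
        cols[f"inf{j}"] = centers[labels] + rng.standard_normal(n)
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), labels


class TestMRMR:
    def test_informative_features_rank_first(self, rng):
        table, labels = _informative_set(rng)
        ranking = cl.mrmr_select(table, labels, k=10)
        n_inf = sum(c.startswith("inf") for c in ranking.top)
        assert n_inf >= 8

    def test_duplicate_penalized_by_redundancy(self, rng):
        table, labels = _informative_set(rng, n_inform=3, n_noise=20)
        table["inf0_copy"] = table["inf0"]
        ranking = cl.mrmr_select(table, labels, k=4)
        pair = {"inf0", "inf0_copy"}
        assert len(pair & set(ranking.top[:3])) <= 1

    def test_full_k_is_permutation(self, rng):
        table, labels = _informative_set(rng, n=30, n_inform=3, n_noise=5)
        ranking = cl.mrmr_select(table, labels, k=8)
        assert sorted(ranking.order) == sorted(table.columns)

    def test_matches_exhaustive_mi_oracle(self, rng):
        # greedy difference-criterion ranking recomputed with sklearn's MI
        table, labels = _informative_set(rng, n=90, n_inform=4, n_noise=6)
        ranking = cl.mrmr_select(table, labels, k=10)

        disc = {c: cl.discretize_three_level(table[c].to_numpy())
                for c in table.columns}
        chosen, remaining = [], set(table.columns)
        while remaining:
            def score(c):
                rel = mutual_info_score(labels, disc[c])
                red = (np.mean([mutual_info_score(disc[c], disc[s])
                                for s in chosen]) if chosen else 0.0)
                return rel - red
            best = max(sorted(remaining), key=score)
            chosen.append(best)
            remaining.discard(best)
        assert ranking.order == chosen

    def test_constant_feature_never_first(self, rng):
        table, labels = _informative_set(rng, n=60, n_inform=2, n_noise=2)
        table["flat"] = 1.0
        ranking = cl.mrmr_select(table, labels, k=5)
        assert ranking.order[0] != "flat"

    def test_single_class_rejected(self, rng):
        table, _ = _informative_set(rng, n=30)
        with pytest.raises(ValueError, match="two classes"):
            cl.mrmr_select(table, np.zeros(30), k=2)


def _blobs(rng, n_per=40, dim=6, sep=8.0):
    centers = rng.normal(0, sep, (3, dim))
    x = np.vstack([centers[k] + rng.standard_normal((n_per, dim))
                   for k in range(3)])
    labels = np.repeat([0, 1, 2], n_per)
    return x, labels


class TestUSELM:
    def test_orthonormal_input_weights(self):
        rng = np.random.default_rng(0)
        w = cl._orthonormal_weights(20, 12, rng)
        np.testing.assert_allclose(w.T @ w, np.eye(12), atol=1e-8)

    def test_blob_separation_scatter_ratio(self, rng):
        x, labels = _blobs(rng)
        emb = cl.uselm_embed(x, cl.ELMParams(n_hidden=50, n_components=2,
                                             n_neighbors=7), seed=3)
        centers = np.array([emb[labels == k].mean(axis=0) for k in range(3)])
        within = np.mean([np.var(emb[labels == k], axis=0).sum()
                          for k in range(3)])
        between = np.var(centers, axis=0).sum()
        assert between / within > 5.0

    def test_duplicate_observations_map_identically(self, rng):
        x, _ = _blobs(rng, n_per=10)
        x[5] = x[4]
        emb = cl.uselm_embed(x, cl.ELMParams(n_hidden=30), seed=0)
        np.testing.assert_allclose(emb[4], emb[5], atol=1e-10)

    def test_boundary_dimensions(self, rng):
        x = rng.standard_normal((8, 4))
        emb = cl.uselm_embed(x, cl.ELMParams(n_hidden=10, n_components=7,
                                             n_neighbors=3), seed=0)
        assert emb.shape == (8, 7)

    def test_deterministic_given_seed(self, rng):
        x, _ = _blobs(rng, n_per=15)
        p = cl.ELMParams(n_hidden=40)
        np.testing.assert_array_equal(cl.uselm_embed(x, p, seed=5),
                                      cl.uselm_embed(x, p, seed=5))


class TestClusterEmbedding:
    def test_blobs_recovered(self, rng):
        x, labels = _blobs(rng)
        for method in ("GMM", "k-means"):
            res = cl.cluster_embedding(x, labels, method=method, seed=0)
            assert res.rand_index == 1.0
            assert res.agreement_accuracy == 1.0

    def test_single_class(self, rng):
        x, _ = _blobs(rng, n_per=5)
        res = cl.cluster_embedding(x, None, n_classes=1, seed=0)
        assert len(np.unique(res.assignment)) == 1

    def test_same_seed_same_assignment(self, rng):
        x, labels = _blobs(rng, n_per=10, sep=1.0)
        a = cl.cluster_embedding(x, labels, seed=4).assignment
        b = cl.cluster_embedding(x, labels, seed=4).assignment
        np.testing.assert_array_equal(a, b)


class TestRandAccuracy:
    def test_identity_and_enumerated_case(self):
        assert cl.rand_accuracy([0, 1, 2], [0, 1, 2]) == 1.0
        # labels {a,a,b,b} vs {x,y,x,y}: of the 6 pairs only (1,2) and (3,4)
        # (split in both partitions) agree -> 2/6
        assert cl.rand_accuracy(["x", "y", "x", "y"],
                                ["a", "a", "b", "b"]) == pytest.approx(1 / 3)

    def test_label_permutation_invariance(self):
        labels = [0, 0, 1, 1, 2, 2]
        a = [2, 2, 0, 0, 1, 1]
        assert cl.rand_accuracy(a, labels) == 1.0
        assert cl.match_accuracy(a, labels) == 1.0

    def test_single_observation_errors(self):
        with pytest.raises(ValueError):
            cl.rand_accuracy([0], [0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=2, max_size=12),
           st.data())
    def test_against_pair_enumeration_oracle(self, a, data):
        b = data.draw(st.lists(st.integers(0, 2), min_size=len(a),
                               max_size=len(a)))
        got = cl.rand_accuracy(a, b)
        agree = total = 0
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                total += 1
                agree += (a[i] == a[j]) == (b[i] == b[j])
        assert got == pytest.approx(agree / total)
        assert 0.0 <= got <= 1.0


class TestChance:
    def test_random_assignment_agreement_near_third(self):
        out = cl.chance_accuracy(n=900, reps=200, seed=0)
        assert out["agreement"] == pytest.approx(1 / 3, abs=0.01)
        # plain Rand of two random balanced 3-partitions converges to 5/9
        assert out["rand"] == pytest.approx(5 / 9, abs=0.02)


class TestParameterSearch:
    def test_separable_data_beats_chance(self, rng):
        x, labels = _blobs(rng)
        res = cl.parameter_search(x, labels, n_iter=12, seed=1, n_hidden=40)
        assert res.runs["rand"].mean() > res.chance_rand
        assert res.p_value < 0.01

    def test_shuffled_labels_near_chance(self, rng):
        x, labels = _blobs(rng)
        res = cl.parameter_search(x, rng.permutation(labels), n_iter=8,
                                  seed=2, n_hidden=40)
        assert abs(res.runs["rand"].mean() - res.chance_rand) < 0.1

    def test_single_iteration(self, rng):
        x, labels = _blobs(rng, n_per=12)
        res = cl.parameter_search(x, labels, n_iter=1, seed=0, n_hidden=20)
        assert len(res.runs) == 1


class TestSummaries:
    def _ranking_meta(self, channels, bands, k):
        cols = [f"c{i}" for i in range(k)]
        meta = pd.DataFrame({"column": cols,
                             "channel": channels, "band": bands}).set_index("column")
        return cl.FeatureRanking(cols, [1.0] * k, k=k), meta

    def test_single_channel_dominates(self):
        ranking, meta = self._ranking_meta(["O1"] * 10, ["alpha"] * 10, 10)
        out = cl.importance_summary(ranking, meta)
        assert out["channel_pct"]["O1"] == 100.0

    def test_uniform_channels(self):
        chans = [f"ch{i}" for i in range(20)]
        ranking, meta = self._ranking_meta(chans, ["alpha"] * 20, 20)
        out = cl.importance_summary(ranking, meta)
        assert np.allclose(out["channel_pct"].to_numpy(), 5.0)
        assert out["channel_pct"].sum() == pytest.approx(100.0)

    def test_broadband_excluded_from_band_percentages(self):
        ranking, meta = self._ranking_meta(
            ["a", "b", "c", "d"], ["broadband", "alpha", "alpha", "gamma"], 4)
        out = cl.importance_summary(ranking, meta)
        assert out["band_pct"].sum() == pytest.approx(100.0)
        assert out["band_pct"]["alpha"] == pytest.approx(200 / 3)

    def test_occipital_effect_concentrates_importance(self, small_feature_table):
        table, meta = small_feature_table
        ranking = cl.mrmr_select(table, k=50)
        out = cl.importance_summary(ranking, meta)
        # class information lives where the generator puts it: the boosted
        # occipital/frontal sites plus the class-coupling target channels
        from arteeg.synthetic import CLASS_BOOSTS, CLASS_COUPLING_PAIRS
        effect_sites = {ch for _, sites, _ in CLASS_BOOSTS["complex"]
                        for ch in sites}
        effect_sites |= {tgt for _, tgt in CLASS_COUPLING_PAIRS}
        share = sum(v for ch, v in out["channel_pct"].items()
                    if ch in effect_sites)
        assert share > 60.0


class TestSubjectClustergram:
    def test_planted_groups_recovered(self, rng):
        a = rng.standard_normal((4, 30))
        b = rng.standard_normal((4, 30)) + 4.0
        table = pd.DataFrame(np.vstack([a, b]),
                             index=[f"s{i}" for i in range(8)])
        out = cl.subject_clustergram(table)
        groups = sorted(sorted(g) for g in out["groups"].values())
        assert groups == [[f"s{i}" for i in range(4)],
                          [f"s{i}" for i in range(4, 8)]]

    def test_duplicate_subject_zero_distance(self, rng):
        x = rng.standard_normal((5, 10))
        x[1] = x[0]
        table = pd.DataFrame(x, index=[f"s{i}" for i in range(5)])
        out = cl.subject_clustergram(table)
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self, rng):
        x = np.vstack([rng.standard_normal((3, 12)),
                       rng.standard_normal((3, 12)) + 5.0])
        table = pd.DataFrame(x, index=[f"s{i}" for i in range(6)])
        perm = table.sample(frac=1.0, random_state=1)
        g1 = {frozenset(v) for v in cl.subject_clustergram(table)["groups"].values()}
        g2 = {frozenset(v) for v in cl.subject_clustergram(perm)["groups"].values()}
        assert g1 == g2
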