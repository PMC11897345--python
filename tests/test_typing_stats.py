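import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from neuroexhaust.ccfeatures import PRIMARY_FEATURES, cohort_table, extract_features
from neuroexhaust.typing_stats import (
    classify_cohort,
    correlation_matrix,
    group_compare,
    hcluster,
    holm_adjust,
    pca_embed,
    rule_type,
    type_proportions,
)


@pytest.mark.parametrize("count,label", [
    (0, "T1"), (1, "T2"), (2, "T3"), (7, "T3"), (188, "T3")])
def test_rule_type_thresholds(count, label):
    assert rule_type(count) == label


def test_rule_type_missing_count_unclassified():
    assert rule_type(np.nan) is None
    assert rule_type(None) is None


def _fake_cohort(rng, n=30, n_feat=6, centers=None):
    """Synthetic feature table with three planted clouds."""
    centers = centers if centers is not None else \
        np.array([[0.0] * n_feat, [30.0] * n_feat, [-30.0] * n_feat])
    rows, truth = [], []
    feats = PRIMARY_FEATURES[:n_feat]
    for i in range(n):
        g = i % 3
        x = centers[g] + rng.normal(0, 1.0, n_feat)
        row = dict(zip(feats, x))
        row["cell_id"] = f"c{i}"
        row["genotype"] = "control"
        # make max_ap_count consistent with the cloud for relabelling
        row["max_ap_count"] = float(g * 5)
        rows.append(row)
        truth.append(g)
    df = pd.DataFrame(rows)
    return df, np.array(truth), feats


class TestPCA:
    def test_two_dimensional_data_explained_by_two_components(self, rng):
        n = 40
        u = rng.normal(0, 3, n)
        w = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            PRIMARY_FEATURES[0]: u,
            PRIMARY_FEATURES[1]: u + w,
            PRIMARY_FEATURES[2]: u - 2 * w,
            PRIMARY_FEATURES[3]: 2 * u + w,
        })
        res = pca_embed(df, n_components=3,
                        features=PRIMARY_FEATURES[:4])
        assert res.variance_explained[:2].sum() == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_duplicated_cohort_gives_identical_loadings(self, rng):
        df, _, feats = _fake_cohort(rng)
        doubled = pd.concat([df, df], ignore_index=True)
        doubled["cell_id"] = [f"c{i}" for i in range(len(doubled))]
        a = pca_embed(df, features=feats).loadings
        b = pca_embed(doubled, features=feats).loadings
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        df, _, feats = _fake_cohort(rng)
        res = pca_embed(df, features=feats)
        for col in res.loadings:
            v = res.loadings[col].values
            assert v[np.argmax(np.abs(v))] > 0

    def test_scores_invariant_to_feature_order(self, rng):
        df, _, feats = _fake_cohort(rng)
        a = pca_embed(df, features=feats).scores
        b = pca_embed(df, features=list(reversed(feats))).scores
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_separates_planted_archetypes(self, rng):
        from sklearn.metrics import silhouette_score
        df, truth, feats = _fake_cohort(rng)
        res = pca_embed(df, n_components=2, features=feats)
        assert silhouette_score(res.scores.values, truth) > 0.3


class TestHCluster:
    def test_well_separated_clouds_recovered_exactly(self, rng):
        df, truth, feats = _fake_cohort(rng)
        labels = hcluster(df, k=3, features=feats)
        # independent oracle: nearest planted centroid
        centers = np.array([[0.0] * 6, [30.0] * 6, [-30.0] * 6])
        x = df[list(feats)].values
        oracle = np.argmin(
            ((x[:, None, :] - centers[None]) ** 2).sum(-1), axis=1)
        assert adjusted_rand_score(oracle, labels) == 1.0
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_is_degenerate(self, rng):
        df, truth, feats = _fake_cohort(rng)
        labels = hcluster(df, k=1, features=feats)
        assert set(labels) == {1}
        assert adjusted_rand_score(truth, labels) <= 0.0

    def test_row_permutation_invariance(self, rng):
        df, _, feats = _fake_cohort(rng)
        perm = rng.permutation(len(df))
        a = hcluster(df, k=3, features=feats)
        b = hcluster(df.iloc[perm].reset_index(drop=True), k=3,
                     features=feats)
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_k_larger_than_n_raises(self, rng):
        df, _, feats = _fake_cohort(rng, n=6)
        with pytest.raises(ValueError):
            hcluster(df, k=10, features=feats)

    def test_clusters_ordered_by_excitability(self, rng):
        df, _, feats = _fake_cohort(rng)
        labels = hcluster(df, k=3, features=feats)
        means = [df.max_ap_count[labels == c].mean() for c in (1, 2, 3)]
        assert means == sorted(means)


class TestProportions:
    def test_single_type_group(self):
        props = type_proportions(["T3"] * 10, ["g"] * 10)
        assert props.loc["g"].tolist() == [0.0, 0.0, 1.0]

    def test_planted_shift_direction(self):
        # control-rich-in-T3 vs patient-rich-in-T2 bookkeeping
        labels = (["T1"] * 2 + ["T2"] * 2 + ["T3"] * 16
                  + ["T1"] * 2 + ["T2"] * 8 + ["T3"] * 10)
        groups = ["control"] * 20 + ["patient"] * 20
        props = type_proportions(labels, groups)
        assert props.loc["patient", "T3"] < props.loc["control", "T3"]
        assert props.loc["patient", "T2"] > props.loc["control", "T2"]
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            type_proportions(["T1"], [None])


class TestCorrelationMatrix:
    def test_diagonal_and_anticorrelation(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({PRIMARY_FEATURES[0]: x,
                           PRIMARY_FEATURES[1]: -x,
                           PRIMARY_FEATURES[2]: rng.normal(0, 1, 50)})
        cm = correlation_matrix(df, features=PRIMARY_FEATURES[:3])
        assert cm.r.iloc[0, 0] == 1.0
        assert cm.mask.iloc[0, 0]
        assert cm.r.iloc[0, 1] == pytest.approx(-1.0)
        assert cm.mask.iloc[0, 1]

    def test_null_pair_rarely_displayed(self):
        # type-I control of the display mask at alpha = 0.01
        shown = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({PRIMARY_FEATURES[0]: r.normal(0, 1, 100),
                               PRIMARY_FEATURES[1]: r.normal(0, 1, 100)})
            cm = correlation_matrix(df, features=PRIMARY_FEATURES[:2],
                                    alpha=0.01)
            shown += int(cm.mask.iloc[0, 1])
        assert shown / n_seeds <= 0.05

    def test_constant_feature_masked(self, rng):
        df = pd.DataFrame({PRIMARY_FEATURES[0]: rng.normal(0, 1, 20),
                           PRIMARY_FEATURES[1]: np.ones(20)})
        cm = correlation_matrix(df, features=PRIMARY_FEATURES[:2])
        assert np.isnan(cm.r.iloc[0, 1])
        assert not cm.mask.iloc[0, 1]

    def test_symmetry(self, rng):
        df, _, feats = _fake_cohort(rng)
        cm = correlation_matrix(df, features=feats)
        np.testing.assert_allclose(cm.r.values, cm.r.values.T)


class TestGroupCompare:
    def test_holm_stepdown_hand_computed(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        # never decreases, preserves ordering
        raw = np.array([0.001, 0.02, 0.5, 0.04])
        adj = holm_adjust(raw)
        assert np.all(adj >= raw)
        assert np.all(np.argsort(adj) == np.argsort(raw))

    def test_identical_groups_rank_p_is_one(self, rng):
        x = rng.normal(0, 1, 20)
        df = pd.DataFrame({"v": np.concatenate([x, x]),
                           "genotype": ["a"] * 20 + ["b"] * 20})
        out = group_compare(df, ["v"], method="mann_whitney", adjust=None)
        assert out.p_raw.iloc[0] > 0.99

    def test_one_sd_shift_is_detected_reliably(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({
                "attenuation_ratio": np.concatenate(
                    [r.normal(0.9, 0.1, 50), r.normal(0.8, 0.1, 50)]),
                "genotype": ["control"] * 50 + ["patient"] * 50})
            out = group_compare(df, ["attenuation_ratio"], method="t")
            hits += int(out.p_adj.iloc[0] < 0.05)
        assert hits >= 90

    def test_needs_two_groups(self, rng):
        df = pd.DataFrame({"v": rng.normal(0, 1, 5), "genotype": ["a"] * 5})
        with pytest.raises(ValueError):
            group_compare(df, ["v"])


class TestEndToEndTyping:
    def test_planted_cohort_classified_and_clustered(self, small_cohort):
        recs, truth = small_cohort
        tab = cohort_table([extract_features(r) for r in recs])
        res = classify_cohort(tab)
        want = truth.label.str.replace("-control", "", regex=False)
        assert (res.labels.values == want.values).all()
        assert res.ari >= 0.8
        np.testing.assert_allclose(res.proportions.sum(axis=1), 1.0)
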