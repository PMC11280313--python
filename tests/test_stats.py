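"""Preprocessing and differential-statistics behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oatnp import stats
from oatnp.stats import (
    MetabolomicsPanel,
    diff_test,
    fold_change,
    hierarchical_cluster_columns,
    log_transform,
    pareto_scale,
    quantile_normalize,
    top_split,
    volcano_classify,
)


def brute_quantile_oracle(X):
    """Rank-mean quantile normalization, written the slow obvious way."""
    n, k = X.shape
    ref = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(k):
        order = np.argsort(X[:, j], kind="mergesort")
        for pos, i in enumerate(order):
            ties = [q for q in range(n) if X[q, j] == X[i, j]]
            positions = [p for p, q in enumerate(order) if q in ties]
            out[i, j] = np.mean(ref[positions])
    return out


class TestQuantileNormalize:
    def test_hand_example(self):
        m = pd.DataFrame({"S1": [1.0, 3.0], "S2": [2.0, 4.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["S1"], [1.5, 3.5])
        np.testing.assert_allclose(out["S2"], [1.5, 3.5])

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 2.0], "b": [5.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_columns_share_sorted_values(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(50, 6)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_matches_brute_force_with_ties(self, rng):
        X = rng.integers(0, 5, size=(12, 4)).astype(float)  # plenty of ties
        out = quantile_normalize(pd.DataFrame(X)).to_numpy()
        np.testing.assert_allclose(out, brute_quantile_oracle(X), atol=1e-12)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(30, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestLogTransform:
    def test_base10_example(self):
        m = pd.DataFrame({"s": [1.0, 10.0, 100.0]})
        np.testing.assert_allclose(log_transform(m, base=10)["s"], [0, 1, 2])

    def test_zero_gets_half_min_imputation(self):
        m = pd.DataFrame({"s": [0.0, 2.0, 8.0]})
        out = log_transform(m, base=2)
        assert out["s"][0] == pytest.approx(0.0)  # log2(2/2) = log2(1)

    def test_inverse_identity_on_positive_input(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(10, 3)))
        back = np.exp(log_transform(m, base=np.e).to_numpy())
        np.testing.assert_allclose(back, m.to_numpy())

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-1.0, 2.0]}))


class TestParetoScale:
    def test_constant_row_maps_to_zero(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]])
        np.testing.assert_array_equal(pareto_scale(m).to_numpy(), [[0, 0, 0]])

    def test_hand_arithmetic(self):
        m = pd.DataFrame([[0.0, 0.0, 4.0, 4.0]])
        out = pareto_scale(m).to_numpy()[0]
        np.testing.assert_allclose(out, [-1.316, -1.316, 1.316, 1.316], atol=5e-4)

    def test_output_moments(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 8)))
        out = pareto_scale(m)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(
            out.std(axis=1, ddof=1), np.sqrt(m.std(axis=1, ddof=1)), rtol=1e-10
        )


def welch_oracle(a, b):
    """Welch t-test from the textbook formulas (independent of scipy's path)."""
    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


class TestDiffTest:
    def test_identical_groups(self):
        t, p = diff_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_welch_formulas(self):
        ko = [2.1, 2.2, 2.0, 2.3]
        wt = [1.0, 1.1, 0.9, 1.0]
        t, p = diff_test(ko, wt)
        t0, p0 = welch_oracle(ko, wt)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_label_swap_negates_t_preserves_p(self, rng):
        a, b = rng.normal(size=6), rng.normal(1, 1, size=5)
        t1, p1 = diff_test(a, b)
        t2, p2 = diff_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        assert diff_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = diff_test([3.0, 3.0], [2.0, 2.0])
        assert t == np.inf and p == 0.0

    def test_type_I_error_calibrated(self, rng):
        """Null rejection rate at 0.05 within binomial CI (2000 metabolites)."""
        ko = rng.normal(size=(2000, 6))
        wt = rng.normal(size=(2000, 6))
        _, p = stats.diff_test_matrix(ko, wt)
        rate = (p < 0.05).mean()
        # 3 sigma binomial band around 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < band


class TestFoldChangeAndVolcano:
    def test_fold_change_examples(self):
        assert fold_change([4.0, 5.0], [2.0, 2.5]) == pytest.approx(2.0)
        assert fold_change([1.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0, 0.0])

    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            (0.01, 4.55, "elevated"),
            (0.20, 5.0, "not_significant"),
            (0.01, 1.0, "not_significant"),  # between the lines
            (0.01, 0.5, "decreased"),
            (0.01, 1.1, "elevated"),  # boundary FC counts
            (0.01, 0.9, "decreased"),
            (0.05, 4.0, "not_significant"),  # p boundary: strict <
        ],
    )
    def test_volcano_thresholds(self, p, fc, expected):
        assert volcano_classify(fc, p) == expected

    def test_noisefree_categories_match_truth(self, noisefree_panel):
        panel, truth = noisefree_panel
        diff = stats.differential_analysis(panel)
        for mid, fc in truth.true_fold_change.items():
            cat = diff.loc[mid, "category"]
            if fc >= 1.1:
                assert cat == "elevated"
            elif fc <= 0.9:
                assert cat == "decreased"
            else:
                assert cat == "not_significant"


def brute_average_linkage(D):
    """Naive agglomeration with average linkage; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    D = D.copy()
    while len(clusters) > 1:
        best, pair = np.inf, None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if d < best:
                    best, pair = d, (a, b)
        a, b = pair
        heights.append(best)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestHierarchicalClustering:
    def test_duplicate_columns_merge_first_at_zero(self):
        m = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]}
        )
        Z, _ = hierarchical_cluster_columns(m)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_matches_brute_force_merge_heights(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        Z, _ = hierarchical_cluster_columns(m)
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(m.to_numpy().T))
        np.testing.assert_allclose(
            sorted(Z[:, 2]), brute_average_linkage(D), atol=1e-10
        )

    def test_separated_panel_splits_by_group(self, separation_panel):
        panel, _ = separation_panel
        proc = stats.preprocess(panel.abundance)
        Z, _ = hierarchical_cluster_columns(proc)
        left, right = top_split(Z, list(proc.columns))
        groups = panel.sample_groups
        sides = {frozenset(groups[s] for s in left), frozenset(groups[s] for s in right)}
        assert sides == {frozenset({"KO"}), frozenset({"WT"})}

    def test_nan_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            hierarchical_cluster_columns(m)


class TestPanelRoundTrip:
    def test_tsv_round_trip(self, tmp_path, noisefree_panel):
        panel, _ = noisefree_panel
        p = tmp_path / "panel.tsv"
        panel.to_tsv(p)
        back = MetabolomicsPanel.from_tsv(p)
        pd.testing.assert_frame_equal(back.abundance, panel.abundance)
        pd.testing.assert_series_equal(
            back.sample_groups, panel.sample_groups, check_names=False
        )
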