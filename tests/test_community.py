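"""Core-taxa rules against a brute-force oracle, group aggregation, and the
statistical toolbox (Mantel, OLS, t-tests, summary features)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sludgecast.community import (
    aggregate_groups,
    classify_core,
    intra_inter_similarity,
    linear_fit,
    mantel_test,
    summary_stats,
    t_test_two_sample,
)

from conftest import abund_frame


def brute_force_core(abund: pd.DataFrame) -> pd.Series:
    """Independent re-statement of the core rules with explicit loops."""
    n_samples, n_asvs = abund.shape
    mra = {t: abund[t].mean() for t in abund.columns}
    n_top = int(np.ceil(0.01 * n_asvs))
    ranked = sorted(abund.columns, key=lambda t: (-mra[t], t))
    top = set(ranked[:n_top])

    core = {}
    for t in abund.columns:
        occ = sum(abund.loc[s, t] > 0 for s in abund.index) / n_samples
        ubiquitous = occ > 0.2

        dominant_in = 0
        for s in abund.index:
            order = sorted(abund.columns, key=lambda u: (-abund.loc[s, u], u))
            cum, chosen = 0.0, []
            for u in order:
                chosen.append(u)
                cum += abund.loc[s, u]
                if cum >= 0.8:
                    break
            if t in chosen:
                dominant_in += 1
        frequently = dominant_in / n_samples >= 0.1
        core[t] = (t in top) and ubiquitous and frequently
    return pd.Series(core)


class TestClassifyCore:
    def test_toy_core_asv(self):
        # dominant, omnipresent taxon passes all three rules
        rows = [[0.9, 0.05, 0.05]] * 5
        abund = abund_frame(rows, taxa=["dom", "r1", "r2"])
        out = classify_core(abund)
        assert bool(out.loc["dom", "core"])
        assert not out.loc["r1", "core"]

    def test_ubiquity_boundary_strict(self):
        # present in exactly 20% of samples -> NOT ubiquitous
        arr = np.full((10, 2), 0.0)
        arr[:, 0] = 0.9
        arr[:2, 1] = 0.1
        arr[2:, 0] = 1.0
        abund = abund_frame(arr / arr.sum(axis=1, keepdims=True), taxa=["a", "b"])
        out = classify_core(abund)
        assert out.loc["b", "occurrence_frequency"] == pytest.approx(0.2)
        assert not out.loc["b", "ubiquitous"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            arr = rng.dirichlet(np.full(40, 0.2), size=12)
            abund = abund_frame(arr)
            fast = classify_core(abund)["core"]
            slow = brute_force_core(abund)
            pd.testing.assert_series_equal(fast, slow, check_names=False)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_core(pd.DataFrame(index=["s"]))


class TestAggregateGroups:
    def test_single_group_sums_to_one(self, neutral_abund):
        gm = {t: "all" for t in neutral_abund.columns}
        out = aggregate_groups(neutral_abund, gm)
        assert np.allclose(out["all"], 1.0)

    def test_empty_map_no_columns(self, neutral_abund):
        out = aggregate_groups(neutral_abund, {})
        assert out.shape == (len(neutral_abund), 0)

    def test_two_group_arithmetic(self):
        abund = abund_frame([[0.2, 0.3, 0.5]], taxa=["a", "b", "c"])
        out = aggregate_groups(abund, {"a": "g1", "b": "g1", "c": "g2"})
        assert out.iloc[0]["g1"] == pytest.approx(0.5)
        assert out.iloc[0]["g2"] == pytest.approx(0.5)


def random_distance(n, rng):
    a = rng.uniform(0.1, 1.0, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


class TestMantel:
    def test_self_correlation(self, rng):
        d = random_distance(10, rng)
        r, p = mantel_test(d, d, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_scale_invariance(self, rng):
        d = random_distance(10, rng)
        r, _ = mantel_test(d, 2 * d, n_permutations=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_type_one_error_rate(self):
        # under independence the rejection rate at alpha=0.05 stays near 0.05
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            d1 = random_distance(12, rng)
            d2 = random_distance(12, rng)
            _, p = mantel_test(d1, d2, n_permutations=99, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_constant_matrix_rejected(self):
        ids = list("abcd")
        ones = pd.DataFrame(1 - np.eye(4), index=ids, columns=ids)
        const = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids)
        with pytest.raises(ValueError):
            mantel_test(ones, const * 0.0, n_permutations=9)


class TestLinearFit:
    def test_exact_line(self):
        out = linear_fit([0, 1, 2], [0, 2, 4])
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(0.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_independent_noise_insignificant(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        out = linear_fit(x, y)
        assert abs(out["slope"]) < 0.3
        assert out["r2"] < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_identical_groups(self):
        t, df, p = t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clear_shift(self):
        t, df, p = t_test_two_sample([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_student_equals_welch_when_balanced(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        ts, _, ps = t_test_two_sample(a, b, "student")
        tw, _, pw = t_test_two_sample(a, b, "welch")
        assert ts == pytest.approx(tw, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([2, 2, 2], [2, 2])


class TestSummaryStats:
    def test_constant_asv_zero_cv(self):
        abund = abund_frame([[0.5, 0.5], [0.5, 0.5]])
        out = summary_stats(abund)
        assert out.loc["t0", "cv"] == pytest.approx(0.0)

    def test_two_sample_arithmetic(self):
        abund = abund_frame([[0.0, 1.0], [0.1, 0.9]])
        out = summary_stats(abund)
        assert out.loc["t0", "mra"] == pytest.approx(0.05)
        assert out.loc["t0", "cv"] == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_omnipresent_frequency_one(self, neutral_abund):
        out = summary_stats(neutral_abund)
        always = (neutral_abund > 0).all(axis=0)
        assert (out.loc[always, "occurrence_frequency"] == 1.0).all()

    def test_group_labels(self):
        abund = abund_frame(
            [[0.9, 0.09, 0.005, 0.005]], taxa=["hi", "med", "lo1", "lo2"]
        )
        out = summary_stats(abund, abundance_thresholds=(0.01, 0.1))
        assert out.loc["hi", "abundance_group"] == "high"
        assert out.loc["med", "abundance_group"] == "medium"
        assert out.loc["lo1", "abundance_group"] == "low"


class TestIntraInter:
    def test_perfect_prediction_intra_one(self, neutral_abund):
        intra, inter, _ = intra_inter_similarity(neutral_abund, neutral_abund)
        assert np.allclose(intra, 1.0)

    def test_shuffled_prediction_null(self, neutral_abund):
        rng = np.random.default_rng(1)
        shuffled = neutral_abund.sample(frac=1.0, random_state=7)
        shuffled.index = neutral_abund.index
        intra, inter, _ = intra_inter_similarity(neutral_abund, shuffled)
        # intra values are now ordinary cross-sample similarities
        t, p = stats.ttest_ind(intra, inter)[:2]
        assert p > 0.01

    def test_good_prediction_separates(self, neutral_abund):
        rng = np.random.default_rng(2)
        noisy = neutral_abund + rng.uniform(0, 0.002, neutral_abund.shape)
        noisy = noisy.div(noisy.sum(axis=1), axis=0)
        intra, inter, (t, df, p) = intra_inter_similarity(neutral_abund, noisy)
        assert intra.mean() > inter.mean()
        assert p < 0.05

    def test_id_mismatch_rejected(self, neutral_abund):
        other = neutral_abund.iloc[::-1]
        with pytest.raises(ValueError):
            intra_inter_similarity(neutral_abund, other)
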