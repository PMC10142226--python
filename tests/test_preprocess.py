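"""Preprocessing rules: encoding, imputation, 1-100 normalisation,
near-duplicate removal, rarefaction and occurrence filtering."""

import numpy as np
import pandas as pd
import pytest

from sludgecast.preprocess import (
    dedup_samples,
    encode_binary,
    filter_taxa,
    impute_2nn,
    normalize_1_100,
    rarefy,
    relative_abundance,
)
from sludgecast.tables import EnvTable


def make_env(values: pd.DataFrame, binary=()):
    meta = pd.DataFrame(
        {
            "category": ["climate"] * values.shape[1],
            "is_binary": [c in binary for c in values.columns],
        },
        index=values.columns,
    )
    return EnvTable(values=values, meta=meta)


class TestEncodeBinary:
    def test_lexicographic_mapping(self):
        env = make_env(
            pd.DataFrame({"f": ["yes", "no", "yes"]}, index=list("abc")), binary=("f",)
        )
        out = encode_binary(env)
        assert list(out.values["f"]) == [1.0, 0.0, 1.0]

    def test_single_token_constant(self):
        env = make_env(pd.DataFrame({"f": ["yes", "yes"]}, index=list("ab")), binary=("f",))
        out = encode_binary(env)
        assert set(out.values["f"]) == {0.0}

    def test_numeric_untouched(self):
        vals = pd.DataFrame({"f": ["a", "b"], "x": [1.25, -3.5]}, index=list("ab"))
        out = encode_binary(make_env(vals, binary=("f",)))
        assert list(out.values["x"]) == [1.25, -3.5]

    def test_three_tokens_rejected(self):
        env = make_env(pd.DataFrame({"f": ["a", "b", "c"]}, index=list("xyz")), binary=("f",))
        with pytest.raises(ValueError):
            encode_binary(env)


class TestImpute2NN:
    def test_equal_neighbours_give_their_value(self):
        vals = pd.DataFrame(
            {"x": [0.0, 0.1, 10.0], "y": [5.0, 5.0, 9.0], "z": [np.nan, 5.0, 5.0]},
            index=list("abc"),
        )
        out = impute_2nn(make_env(vals))
        assert out.values.loc["a", "z"] == 5.0

    def test_no_missing_is_identity(self, env_small):
        enc = encode_binary(env_small)
        out = impute_2nn(enc)
        pd.testing.assert_frame_equal(out.values, enc.values)

    def test_mean_of_two_nearest(self):
        # three donors; the two nearest (by the shared-column metric) hold 2 and 4
        vals = pd.DataFrame(
            {
                "x": [0.0, 0.0, 0.0, 100.0],
                "y": [np.nan, 2.0, 4.0, 50.0],
            },
            index=list("abcd"),
        )
        out = impute_2nn(make_env(vals))
        assert out.values.loc["a", "y"] == pytest.approx(3.0)

    def test_all_cells_filled(self):
        vals = pd.DataFrame(
            np.where(np.eye(5, 4, dtype=bool), np.nan, np.arange(20.0).reshape(5, 4)),
            index=list("abcde"),
            columns=list("wxyz"),
        )
        out = impute_2nn(make_env(vals))
        assert not out.values.isna().any().any()


class TestNormalize:
    def test_direct_formula(self):
        vals = pd.DataFrame({"x": [0.0, 50.0, 100.0]}, index=list("abc"))
        out = normalize_1_100(make_env(vals))
        assert list(out.values["x"]) == [1.0, 50.5, 100.0]

    def test_constant_column_midpoint(self):
        vals = pd.DataFrame({"x": [7.0, 7.0, 7.0]}, index=list("abc"))
        out = normalize_1_100(make_env(vals))
        assert set(out.values["x"]) == {50.5}

    def test_bounds_and_idempotence(self, env_normalized):
        vals = env_normalized.values
        for col in vals:
            if vals[col].nunique() > 1:
                assert vals[col].min() == pytest.approx(1.0)
                assert vals[col].max() == pytest.approx(100.0)
        again = normalize_1_100(env_normalized)
        pd.testing.assert_frame_equal(again.values, vals)


class TestDedup:
    @staticmethod
    def dist_frame(arr, ids):
        return pd.DataFrame(arr, index=ids, columns=ids)

    def test_no_identical_rows_all_kept(self):
        vals = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        d = self.dist_frame(1 - np.eye(3), list("abc"))
        assert dedup_samples(make_env(vals), d) == ["a", "b", "c"]

    def test_identical_row_zero_distance_merged(self):
        vals = pd.DataFrame({"x": [1.0, 1.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        arr = np.full((5, 5), 1.0)
        np.fill_diagonal(arr, 0.0)
        arr[0, 1] = arr[1, 0] = 0.0  # identical communities too
        d = self.dist_frame(arr, list("abcde"))
        assert dedup_samples(make_env(vals), d) == ["a", "c", "d", "e"]

    def test_distances_above_fence_all_kept(self):
        vals = pd.DataFrame({"x": [1.0, 1.0, 3.0]}, index=list("abc"))
        arr = np.array([[0, 0.5, 0.6], [0.5, 0, 0.7], [0.6, 0.7, 0]])
        d = self.dist_frame(arr, list("abc"))
        assert dedup_samples(make_env(vals), d) == ["a", "b", "c"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(8)]
        vals = pd.DataFrame({"x": [1, 1, 2, 2, 3, 4, 5, 6.0]}, index=ids)
        arr = rng.uniform(0.2, 1.0, (8, 8))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0)
        arr[0, 1] = arr[1, 0] = 0.0
        d = self.dist_frame(arr, ids)
        keep1 = dedup_samples(make_env(vals), d)
        perm = rng.permutation(8)
        vals2 = vals.iloc[perm]
        keep2 = dedup_samples(make_env(vals2), d.iloc[perm, perm])
        assert keep1 == keep2

    def test_id_mismatch_rejected(self):
        vals = pd.DataFrame({"x": [1.0, 2.0]}, index=list("ab"))
        d = self.dist_frame(np.zeros((2, 2)), list("xy"))
        with pytest.raises(ValueError):
            dedup_samples(make_env(vals), d)


class TestRarefy:
    def test_row_sums_equal_depth(self, neutral_counts):
        counts, _ = neutral_counts
        out = rarefy(counts, 200, seed=0)
        assert (out.sum(axis=1) == 200).all()

    def test_exact_depth_unchanged(self):
        counts = pd.DataFrame({"a": [60], "b": [40]}, index=["s"])
        out = rarefy(counts, 100, seed=0)
        pd.testing.assert_frame_equal(out, counts)

    def test_short_rows_dropped_or_error(self):
        counts = pd.DataFrame({"a": [50, 500], "b": [10, 500]}, index=["lo", "hi"])
        out = rarefy(counts, 100, seed=0, drop_short=True)
        assert list(out.index) == ["hi"]
        with pytest.raises(ValueError):
            rarefy(counts, 100, seed=0, drop_short=False)

    def test_hypergeometric_expectation(self):
        counts = pd.DataFrame({"a": [100], "b": [0], "c": [100]}, index=["s"])
        means = np.mean(
            [rarefy(counts, 100, seed=s).iloc[0].to_numpy() for s in range(400)], axis=0
        )
        assert means[1] == 0
        assert abs(means[0] - 50) < 3 * np.sqrt(100 * 0.5 * 0.5 * (100 / 199)) / 20

    def test_proportions_preserved_in_expectation(self, neutral_counts):
        counts, _ = neutral_counts
        sub = counts.iloc[:3]
        base = sub.div(sub.sum(axis=1), axis=0)
        reps = [
            rarefy(sub, 100, seed=s).div(100) for s in range(300)
        ]
        mean_rel = sum(reps) / len(reps)
        assert np.abs(mean_rel.to_numpy() - base.to_numpy()).max() < 0.02


class TestFilterTaxa:
    def test_singleton_removed(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [5, 5]}, index=["s1", "s2"])
        out = filter_taxa(counts, drop_singletons=True)
        assert list(out.columns) == ["b"]

    def test_ceiling_occurrence_rule(self):
        rng = np.random.default_rng(0)
        base = rng.integers(2, 9, size=(100, 1))
        present10 = np.zeros((100, 1), int)
        present10[:10] = 3
        present9 = np.zeros((100, 1), int)
        present9[:9] = 3
        counts = pd.DataFrame(
            np.hstack([base, present10, present9]), columns=["base", "in10", "in9"]
        )
        out = filter_taxa(counts, min_occurrence_frac=0.10, drop_singletons=False)
        assert "in10" in out.columns and "in9" not in out.columns

    def test_identity_when_disabled(self, neutral_counts):
        counts, _ = neutral_counts
        out = filter_taxa(counts, min_occurrence_frac=0.0, drop_singletons=False)
        pd.testing.assert_frame_equal(out, counts)

    def test_threshold_monotonicity(self, neutral_counts):
        counts, _ = neutral_counts
        hi = filter_taxa(counts, min_occurrence_frac=0.5)
        lo = filter_taxa(counts, min_occurrence_frac=0.2)
        assert set(hi.columns) <= set(lo.columns)


class TestRelativeAbundance:
    def test_arithmetic(self):
        counts = pd.DataFrame({"a": [2, 1], "b": [2, 3]}, index=["s1", "s2"])
        out = relative_abundance(counts)
        assert list(out.loc["s1"]) == [0.5, 0.5]
        assert list(out.loc["s2"]) == [0.25, 0.75]

    def test_rows_sum_to_one(self, neutral_abund):
        assert np.allclose(neutral_abund.sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        counts = pd.DataFrame({"a": [0], "b": [0]}, index=["s"])
        with pytest.raises(ValueError):
            relative_abundance(counts)
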