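import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lateview.containers import FeatureTable
from lateview.preprocess import (
    aggregate_taxa,
    apply_recipe,
    correlation_filter,
    filter_low_total,
    fit_censored_normal,
    lod_filter,
    log2_transform,
    missingness_filter,
    nzv_filter,
    qrilc_impute,
    rclr,
    weight_normalize,
)


def table(arr, columns=None, modality="counts", index=None):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(
        arr,
        index=index or [f"s{i}" for i in range(arr.shape[0])],
        columns=columns or [f"f{j}" for j in range(arr.shape[1])],
    )
    return FeatureTable(values=df, modality=modality)


class TestAggregateTaxa:
    def test_two_genera_sum(self):
        t = table([[1, 2, 3, 4]])
        out = aggregate_taxa(t, {"f0": "g1", "f1": "g1", "f2": "g2", "f3": "g2"})
        assert out.values.values.tolist() == [[3.0, 7.0]]
        assert out.feature_ids == ["g1", "g2"]

    def test_identity_mapping(self):
        t = table([[1, 2], [3, 4]])
        out = aggregate_taxa(t, {"f0": "f0", "f1": "f1"})
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_group_count_matches_distinct_groups(self, rng):
        n_in = 173
        t = table(rng.integers(0, 50, size=(5, n_in)))
        mapping = {f"f{j}": f"g{rng.integers(0, 60)}" for j in range(n_in)}
        out = aggregate_taxa(t, mapping)
        assert out.n_features == len(set(mapping.values()))
        # totals preserved
        assert out.values.values.sum() == pytest.approx(t.values.values.sum())

    def test_unmapped_feature_named_in_error(self):
        t = table([[1, 2]])
        with pytest.raises(KeyError, match="f1"):
            aggregate_taxa(t, {"f0": "g"})


class TestFilterLowTotal:
    def test_strict_less_than_rule(self):
        t = table([[0, 1, 3, 10], [0, 1, 0, 0]])
        out = filter_low_total(t, min_total=3)
        assert out.feature_ids == ["f2", "f3"]

    def test_identity_when_all_pass(self):
        t = table([[3, 4], [0, 0]])
        out = filter_low_total(t, min_total=3)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_against_brute_force_recount(self, rng):
        t = table(rng.integers(0, 4, size=(20, 50)))
        out = filter_low_total(t, min_total=3)
        expected = [
            f for f in t.feature_ids
            if sum(t.values[f].tolist()) >= 3  # independent column-sum oracle
        ]
        assert out.feature_ids == expected

    def test_exclusion_list(self):
        t = table([[5, 5, 5]])
        out = filter_low_total(t, min_total=3, exclude=["f1"])
        assert out.feature_ids == ["f0", "f2"]

    def test_empty_result_warns(self):
        t = table([[1, 1]])
        with pytest.warns(UserWarning):
            out = filter_low_total(t, min_total=10)
        assert out.n_features == 0


class TestRclr:
    def test_hand_oracle(self):
        # positives 1,10,100: geometric mean 10
        out = rclr(table([[1, 10, 100, 0]]))
        row = out.values.iloc[0]
        assert row["f0"] == pytest.approx(-math.log(10))
        assert row["f1"] == pytest.approx(0.0)
        assert row["f2"] == pytest.approx(math.log(10))
        assert math.isnan(row["f3"])

    def test_identical_positives_give_zero(self):
        out = rclr(table([[5, 5, 5]]))
        assert np.allclose(out.values.values, 0.0)

    def test_scale_invariance(self, rng):
        x = rng.integers(0, 20, size=(10, 15)).astype(float)
        x[:, 0] = 1  # guarantee a positive entry per row
        a = rclr(table(x))
        b = rclr(table(x * 37.5))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_row_mean_zero_over_nonmissing(self, rng):
        x = rng.integers(0, 10, size=(8, 12)).astype(float)
        x[:, 0] = 3
        out = rclr(table(x))
        assert np.allclose(np.nanmean(out.values.values, axis=1), 0.0, atol=1e-12)

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            rclr(table([[0, 0, 0]]))


class TestLodFilter:
    def test_boundary_kept(self):
        x = np.ones((10, 1)) * 5
        x[:2, 0] = 0.1  # below LOD in exactly 20% of samples
        assert lod_filter(table(x), lod=1.0).n_features == 1

    def test_above_boundary_dropped(self):
        x = np.ones((10, 1)) * 5
        x[:3, 0] = 0.1
        assert lod_filter(table(x), lod=1.0).n_features == 0

    def test_brute_force_oracle(self, rng):
        x = rng.random((25, 30)) * 2
        t = table(x)
        out = lod_filter(t, lod=0.5, max_frac=0.2)
        expected = [
            f for f in t.feature_ids
            if sum(v < 0.5 for v in t.values[f]) / 25 <= 0.2
        ]
        assert out.feature_ids == expected


class TestMissingnessFilter:
    def test_boundary_kept(self):
        x = np.ones((10, 1))
        x[:2, 0] = np.nan
        assert missingness_filter(table(x)).n_features == 1

    def test_strict_drop(self):
        x = np.ones((10, 1))
        x[:3, 0] = np.nan
        assert missingness_filter(table(x)).n_features == 0

    def test_oracle_recount(self, rng):
        x = rng.random((20, 40))
        x[rng.random((20, 40)) < 0.2] = np.nan
        t = table(x)
        out = missingness_filter(t, max_frac=0.2)
        expected = [
            f for f in t.feature_ids
            if t.values[f].isna().sum() / 20 <= 0.2
        ]
        assert out.feature_ids == expected


class TestWeightNormalize:
    def test_unit_weight_identity(self):
        t = table([[2, 4]])
        out = weight_normalize(t, [1.0])
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_simple_division(self):
        out = weight_normalize(table([[2, 4]]), [2.0])
        assert out.values.values.tolist() == [[1.0, 2.0]]

    def test_elementwise_oracle(self, rng):
        x = rng.random((6, 5))
        w = rng.random(6) + 0.5
        out = weight_normalize(table(x), w)
        assert np.allclose(out.values.values, x / w[:, None])

    def test_nonpositive_weight_errors(self):
        with pytest.raises(ValueError, match="onpositive"):
            weight_normalize(table([[1], [2]]), [1.0, 0.0])


class TestLog2:
    def test_basic_values(self):
        out = log2_transform(table([[8, 1]]))
        assert out.values.values.tolist() == [[3.0, 0.0]]

    def test_missing_stays_missing(self):
        out = log2_transform(table([[np.nan, 2]]))
        assert math.isnan(out.values.iloc[0, 0])

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            log2_transform(table([[0.0, 1.0]]))


class TestQrilc:
    def test_no_missing_is_identity(self, rng):
        x = rng.normal(size=(10, 4))
        t = table(x, modality="metabolite")
        out = qrilc_impute(t, seed=0)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_censored_normal_fit_recovers_params(self):
        # oracle: N(0,1) censored below -1 at n=1000; tolerances fixed by simulation
        for seed in range(3):
            x = np.random.default_rng(seed).normal(0, 1, 1000)
            obs = x[x >= -1]
            mu, sd = fit_censored_normal(obs, 1000)
            assert abs(mu) < 0.1
            assert abs(sd - 1) < 0.1

    def test_imputed_below_observed_minimum(self, rng):
        x = rng.normal(5, 1, size=(40, 6))
        x[rng.random((40, 6)) < 0.15] = np.nan
        t = table(x, modality="metabolite")
        out = qrilc_impute(t, seed=1)
        assert not out.values.isna().any().any()
        for col in t.values.columns:
            observed_min = t.values[col].min()
            imputed = out.values.loc[t.values[col].isna(), col]
            assert (imputed <= observed_min).all()

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(size=(30, 5))
        x[rng.random((30, 5)) < 0.2] = np.nan
        t = table(x, modality="metabolite")
        a = qrilc_impute(t, seed=7)
        b = qrilc_impute(t, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_sparse_feature_uses_global_fit(self, rng):
        x = rng.normal(size=(10, 3))
        x[2:, 0] = np.nan  # only 2 observed values
        with pytest.warns(UserWarning, match="global fit"):
            out = qrilc_impute(table(x, modality="metabolite"), seed=0)
        assert not out.values.isna().any().any()


class TestNzv:
    def test_constant_dropped(self):
        t = table([[1, 1], [1, 2], [1, 3]])
        assert nzv_filter(t).feature_ids == ["f1"]

    def test_strictly_increasing_kept(self):
        t = table(np.arange(20).reshape(-1, 1))
        assert nzv_filter(t).n_features == 1

    def test_95_5_binary_dropped(self):
        # ratio 19, unique fraction 2% in n=100
        x = np.zeros((100, 1))
        x[:5, 0] = 1
        assert nzv_filter(table(x)).n_features == 0

    def test_90_10_binary_kept(self):
        x = np.zeros((100, 1))
        x[:10, 0] = 1
        assert nzv_filter(table(x)).n_features == 1


class TestCorrelationFilter:
    def test_identical_columns_one_dropped(self, rng):
        c = rng.random(20)
        t = table(np.column_stack([c, c, rng.random(20)]))
        assert correlation_filter(t).n_features == 2

    def test_orthogonal_identity(self):
        t = table(np.eye(4))
        out = correlation_filter(t)
        assert out.n_features == 4

    def test_survivors_below_cutoff(self, rng):
        base = rng.random((30, 3))
        noisy = np.column_stack([base + rng.normal(0, 0.05, (30, 3)), base, rng.random((30, 4))])
        out = correlation_filter(table(noisy), cutoff=0.9)
        corr = out.values.corr().abs().values
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9


class TestIdempotence:
    @pytest.mark.parametrize(
        "op",
        [
            lambda t: filter_low_total(t, 3),
            lambda t: missingness_filter(t),
            lambda t: nzv_filter(t),
            lambda t: correlation_filter(t),
        ],
    )
    def test_filters_idempotent(self, rng, op):
        x = rng.integers(0, 5, size=(25, 30)).astype(float)
        x[:, 0] = 1.0  # constant column for nzv
        once = op(table(x))
        twice = op(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


def test_apply_recipe_chain(rng):
    x = rng.integers(0, 30, size=(10, 8)).astype(float)
    x[:, 0] = 3
    t = table(x)
    out = apply_recipe(t, [{"name": "filter_low_total", "params": {"min_total": 3}}, "rclr"])
    assert np.allclose(np.nanmean(out.values.values, axis=1), 0.0, atol=1e-12)


def test_apply_recipe_unknown_step():
    with pytest.raises(KeyError):
        apply_recipe(table([[1.0]]), ["not_a_transform"])
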