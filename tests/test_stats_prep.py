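"""Standardization, correlation, clustering, PCA, and split behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverbio import stats_prep
from riverbio.errors import (
    AmbiguousSeasonError,
    InsufficientDataError,
    InvalidKError,
    InvalidSplitError,
    RiverbioError,
    UndefinedCorrelationError,
)
from riverbio.stats_prep import (
    ClusterAssignment,
    drop_collinear,
    exclude_winter_cluster,
    kmeans_cluster,
    minmax_standardize,
    pca_varimax,
    pearson_correlation_matrix,
    train_validation_split,
)


class TestMinmaxStandardize:
    def test_affine_rescale(self):
        std = minmax_standardize(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        assert std.values["a"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        std = minmax_standardize(pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [0.0, 1.0, 2.0]}))
        assert (std.values["a"] == 0.0).all()

    def test_unit_interval_column_unchanged(self):
        col = pd.DataFrame({"a": [0.0, 0.25, 1.0]})
        std = minmax_standardize(col)
        pd.testing.assert_frame_equal(std.values, col)

    def test_non_numeric_raises(self):
        with pytest.raises((ValueError, TypeError)):
            minmax_standardize(pd.DataFrame({"a": ["x", "y", "z"]}))

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=30, unique=True
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity_and_range(self, values):
        frame = pd.DataFrame({"v": values})
        std = minmax_standardize(frame)
        assert std.values["v"].between(0, 1).all()
        assert std.values["v"].min() == 0.0 and std.values["v"].max() == 1.0
        back = std.inverse(std.values)
        np.testing.assert_allclose(back["v"], frame["v"], atol=1e-9 * max(1, np.abs(values).max()))


class TestCorrelation:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=30)
        frame = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        corr = pearson_correlation_matrix(frame)
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert corr.loc["x", "z"] == pytest.approx(-1.0)

    def test_matches_two_pass_brute_force(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        corr = pearson_correlation_matrix(frame)
        x = frame.to_numpy()
        xc = x - x.mean(axis=0)
        brute = (xc.T @ xc) / np.outer(
            np.sqrt((xc**2).sum(axis=0)), np.sqrt((xc**2).sum(axis=0))
        )
        np.testing.assert_allclose(corr.to_numpy(), brute, atol=1e-12)
        # symmetric, unit diagonal, PSD
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr.to_numpy()).min() > -1e-10

    def test_constant_column_named_in_error(self):
        frame = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            pearson_correlation_matrix(frame)


class TestDropCollinear:
    def _corr(self, values, names):
        return pd.DataFrame(values, index=names, columns=names)

    def test_ec_kept_over_tds(self):
        corr = self._corr(
            [[1.0, 1.0, 0.3], [1.0, 1.0, 0.3], [0.3, 0.3, 1.0]], ["ec", "tds", "ph"]
        )
        kept = drop_collinear(corr, 0.95, ["ec", "tds"])
        assert kept == ["ec", "ph"]

    def test_identity_matrix_keeps_all(self):
        corr = self._corr(np.eye(3), ["a", "b", "c"])
        assert drop_collinear(corr, 0.95, []) == ["a", "b", "c"]

    def test_threshold_is_inclusive_bound(self):
        corr = self._corr([[1.0, 0.99], [0.99, 1.0]], ["a", "b"])
        assert drop_collinear(corr, 1.0, ["a"]) == ["a", "b"]
        assert drop_collinear(corr, 0.99, ["a"]) == ["a"]

    def test_no_remaining_pair_above_threshold(self, rng):
        x = rng.normal(size=(60, 5))
        x[:, 1] = x[:, 0] + 0.01 * rng.normal(size=60)
        x[:, 3] = -x[:, 2] + 0.01 * rng.normal(size=60)
        corr = pearson_correlation_matrix(pd.DataFrame(x, columns=list("abcde")))
        kept = drop_collinear(corr, 0.9, list("abcde"))
        sub = corr.loc[kept, kept].to_numpy()
        assert np.abs(sub - np.eye(len(kept))).max() < 0.9


class TestKmeans:
    def test_separated_clouds_partitioned(self, rng):
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(5, 0.1, size=(20, 2))
        frame = pd.DataFrame(np.vstack([a, b]))
        assignment = kmeans_cluster(frame, 2, seed=0)
        labels = assignment.labels.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_rows_gives_zero_sse(self, rng):
        frame = pd.DataFrame(rng.normal(size=(6, 2)))
        assignment = kmeans_cluster(frame, 6, seed=0)
        assert assignment.inertia == pytest.approx(0.0, abs=1e-12)

    def test_invalid_k(self, rng):
        frame = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(InvalidKError):
            kmeans_cluster(frame, 4, seed=0)


class TestWinterExclusion:
    def _assignment(self, labels, index):
        return ClusterAssignment(
            labels=pd.Series(labels, index=index),
            centroids=np.zeros((2, 1)),
            inertia=0.0,
        )

    def test_pure_winter_cluster_dropped(self):
        index = pd.Index(range(6))
        months = pd.Series([12, 1, 2, 6, 7, 8], index=index)
        assignment = self._assignment([0, 0, 0, 1, 1, 1], index)
        retained = exclude_winter_cluster(assignment, months)
        assert list(retained) == [3, 4, 5]

    def test_tie_is_ambiguous(self):
        index = pd.Index(range(4))
        months = pd.Series([12, 1, 6, 7], index=index)
        assignment = self._assignment([0, 1, 0, 1], index)
        with pytest.raises(AmbiguousSeasonError):
            exclude_winter_cluster(assignment, months)

    def test_k3_assignment_rejected(self):
        index = pd.Index(range(3))
        months = pd.Series([12, 1, 6], index=index)
        assignment = ClusterAssignment(
            labels=pd.Series([0, 1, 2], index=index),
            centroids=np.zeros((3, 1)),
            inertia=0.0,
        )
        with pytest.raises(RiverbioError):
            exclude_winter_cluster(assignment, months)


class TestPcaVarimax:
    def test_correlated_pair_shares_a_rotated_component(self, rng):
        x = rng.normal(size=(200, 4))
        x[:, 1] = x[:, 0] + 0.05 * rng.normal(size=200)
        frame = pd.DataFrame(x, columns=["a", "b", "c", "d"])
        result = pca_varimax(frame, 4)
        rot = result.rotated_loadings
        comp = rot.loc["a"].abs().idxmax()
        assert rot.loc["b"].abs().idxmax() == comp
        assert abs(rot.loc["a", comp]) > 0.9 and abs(rot.loc["b", comp]) > 0.9

    def test_explained_variance_properties(self, rng):
        frame = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        result = pca_varimax(frame, 5)
        ratios = result.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() == pytest.approx(1.0)
        # near-isotropic data spreads variance nearly uniformly
        assert ratios.max() < 0.4

    def test_rotation_preserves_communalities(self, rng):
        x = rng.normal(size=(150, 6))
        x[:, 1] += x[:, 0]
        x[:, 3] -= 0.5 * x[:, 2]
        frame = pd.DataFrame(x, columns=list("abcdef"))
        result = pca_varimax(frame, 4)
        h_before = (result.loadings**2).sum(axis=1)
        h_after = (result.rotated_loadings**2).sum(axis=1)
        np.testing.assert_allclose(h_before, h_after, atol=1e-6)

    def test_unrotated_loading_columns_orthogonal(self, rng):
        frame = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        result = pca_varimax(frame, 4)
        load = result.loadings.to_numpy()
        gram = load.T @ load
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-10

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            pca_varimax(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}), 2)


class TestSplit:
    def test_sizes_and_partition(self):
        keys = [f"k{i}" for i in range(50)]
        train, valid = train_validation_split(keys, 0.8, seed=4)
        assert len(train) == 40 and len(valid) == 10
        assert set(train) | set(valid) == set(keys)
        assert set(train) & set(valid) == set()

    def test_deterministic(self):
        keys = list(range(30))
        assert train_validation_split(keys, 0.8, 9) == train_validation_split(keys, 0.8, 9)
        assert train_validation_split(keys, 0.8, 9) != train_validation_split(keys, 0.8, 10)

    @pytest.mark.parametrize("n, fraction", [(2, 0.1), (5, 0.99), (1, 0.8)])
    def test_degenerate_splits_rejected(self, n, fraction):
        with pytest.raises(InvalidSplitError):
            train_validation_split(list(range(n)), fraction, seed=0)
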