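"""GP engine: evaluation semantics, operators, serialization, evolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverbio import gp
from riverbio.errors import MalformedTreeError, RiverbioError, TreeParseError
from riverbio.gp import (
    GpConfig,
    evaluate_tree,
    evolve,
    fitness,
    parse_tree,
    protected_divide,
    random_tree,
    tree_depth,
    tree_to_infix,
    tree_to_string,
    tree_variables,
)


@pytest.mark.parametrize(
    "num, den, expected",
    [(6, 3, 2.0), (5, 0, 1.0), (0, 0, 1.0), (1, 1e-12, 1.0), (-4, 2, -2.0)],
)
def test_protected_divide(num, den, expected):
    assert protected_divide(num, den) == expected


class TestEvaluate:
    def test_division_tree(self):
        assert evaluate_tree(["div", 0, 1], np.array([[8.0, 20.0]]))[0] == pytest.approx(0.4)

    def test_constant_tree(self, rng):
        rows = rng.normal(size=(10, 3))
        np.testing.assert_allclose(evaluate_tree([0.7], rows), 0.7)

    def test_protected_zero_denominator(self, rng):
        rows = rng.normal(size=(5, 2))
        tree = ["div", 0, "sub", 1, 1]  # div(x0, sub(x1, x1))
        np.testing.assert_allclose(evaluate_tree(tree, rows), 1.0)

    def test_unbound_variable_raises(self):
        with pytest.raises(MalformedTreeError):
            evaluate_tree(["add", 0, 5], np.zeros((3, 2)))

    def test_matches_direct_arithmetic(self, rng):
        rows = rng.uniform(0.1, 1, size=(20, 2))
        tree = ["add", "mul", 0, 1, "div", 0.5, 1]  # x0*x1 + 0.5/x1
        expected = rows[:, 0] * rows[:, 1] + 0.5 / rows[:, 1]
        np.testing.assert_allclose(evaluate_tree(tree, rows), expected)


class TestFitness:
    def test_perfect_prediction(self):
        report = fitness(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert report.rmse == 0.0 and report.pearson_r == pytest.approx(1.0)

    def test_constant_prediction_scores_zero_r(self):
        report = fitness(np.full(4, 2.0), np.array([1.0, 2.0, 3.0, 4.0]))
        assert report.pearson_r == 0.0
        assert report.rmse > 0

    def test_anti_correlated(self):
        report = fitness(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert report.rmse == pytest.approx(1.0)
        assert report.pearson_r == pytest.approx(-1.0)

    def test_length_mismatch(self):
        with pytest.raises(RiverbioError):
            fitness(np.ones(3), np.ones(4))


class TestRandomTree:
    def test_depths_within_init_range(self, rng):
        config = GpConfig()
        depths = {tree_depth(random_tree(config, 3, rng)) for _ in range(1000)}
        assert depths <= set(range(2, 7))
        assert min(depths) == 2 and max(depths) == 6

    def test_deterministic_given_rng_state(self):
        config = GpConfig()
        t1 = random_tree(config, 3, np.random.default_rng(5))
        t2 = random_tree(config, 3, np.random.default_rng(5))
        assert t1 == t2

    def test_restricted_function_set(self, rng):
        config = GpConfig(function_set=("add",))
        for _ in range(50):
            tree = random_tree(config, 2, rng)
            assert all(tok == "add" for tok in tree if isinstance(tok, str))


class TestSerialization:
    def test_known_string(self):
        assert tree_to_string(["div", 0, 1]) == "div(x0, x1)"
        assert tree_to_infix(["div", 0, 1], ["DO", "T"]) == "(DO / T)"

    def test_parse_simple(self):
        tree = parse_tree("add(x0, 0.5)", 2)
        assert tree == ["add", 0, 0.5]
        assert tree_depth(tree) == 2

    @pytest.mark.parametrize("text", ["add(x0", "add(x0 x1)", "frob(x0, x1)", "x9", ""])
    def test_malformed_strings_rejected(self, text):
        with pytest.raises(TreeParseError):
            parse_tree(text, 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(GpConfig(), 4, rng)
        recovered = parse_tree(tree_to_string(tree), 4)
        assert len(recovered) == len(tree)
        for a, b in zip(recovered, tree):
            if isinstance(a, float):
                assert a == pytest.approx(b, rel=1e-11)
            else:
                assert a == b


class TestEvolve:
    def test_recovers_identity_target(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(50, 3))
        config = GpConfig(generations=100, population_size=100, seed=2)
        result = evolve(config, X, X[:, 0])
        assert result.train.rmse <= 0.01

    def test_trajectory_monotone_with_elitism(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(30, 2))
        y = X[:, 0] + X[:, 1]
        config = GpConfig(generations=20, population_size=50, seed=3)
        result = evolve(config, X, y)
        traj = np.asarray(result.trajectory)
        assert np.all(np.diff(traj) <= 1e-15)

    def test_same_seed_same_tree(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(25, 2))
        y = X[:, 0] * X[:, 1]
        config = GpConfig(generations=10, population_size=40, seed=9)
        r1 = evolve(config, X, y)
        r2 = evolve(config, X, y)
        assert tree_to_string(r1.tree) == tree_to_string(r2.tree)

    def test_constant_target_warns_but_runs(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(10, 2))
        config = GpConfig(generations=2, population_size=20, seed=1)
        with pytest.warns(UserWarning):
            result = evolve(config, X, np.full(10, 0.5))
        assert result.warning is not None

    def test_offspring_respect_depth_cap(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(20, 2))
        y = X[:, 0]
        config = GpConfig(generations=15, population_size=60, max_depth=7, seed=5)
        result = evolve(config, X, y)
        assert tree_depth(result.tree) <= 7


def test_tree_variables():
    assert tree_variables(["add", "div", 0, 2, 0.5]) == {0, 2}
    assert tree_variables([0.3]) == set()


def test_config_validation():
    with pytest.raises(RiverbioError):
        GpConfig(population_size=1)
    with pytest.raises(RiverbioError):
        GpConfig(mutation_rate=1.5)
    with pytest.raises(RiverbioError):
        GpConfig(function_set=("pow",))
    with pytest.raises(RiverbioError):
        GpConfig(max_depth=3)
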