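"""Tree-based genetic-programming symbolic regression.

A Koza-style generational GP evolving arithmetic expression trees over a
predictor matrix: function set {add, sub, mul, div} (division protected),
terminals = predictor variables and ephemeral random constants, tournament
selection, subtree crossover and subtree mutation, one-individual elitism,
fitness = training RMSE (minimised). Trees are stored as flat prefix token
lists — operators are strings, variable references ints, constants floats —
which keeps subtree surgery and stack-based vectorised evaluation cheap.

The engine is deliberately self-contained: determinism is guaranteed by a
single numpy Generator per run, and every stochastic decision flows through
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MalformedTreeError, RiverbioError, TreeParseError

__all__ = [
    "GpConfig",
    "FitnessReport",
    "GpRunResult",
    "FUNCTION_SET",
    "protected_divide",
    "random_tree",
    "evaluate_tree",
    "fitness",
    "evolve",
    "tree_depth",
    "tree_to_string",
    "tree_to_infix",
    "parse_tree",
    "tree_variables",
]

FUNCTION_SET = ("add", "sub", "mul", "div")
DIV_EPS = 1e-9

# Tree = list of tokens in prefix order.
# token: str (binary operator) | int (variable index) | float (constant)
Tree = list


@dataclass(frozen=True)
class GpConfig:
    """Hyperparameters of one GP run.

    Defaults follow the classical Koza setup used in water-quality symbolic
    regression: population 300, 500 generations, mutation 0.1, crossover 0.9,
    tournament size 3, ramped initial depths 2-6, hard depth cap 12,
    ephemeral constants uniform on [0, 1].
    """

    population_size: int = 300
    generations: int = 500
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    tournament_size: int = 3
    init_depth: tuple[int, int] = (2, 6)
    max_depth: int = 12
    function_set: tuple[str, ...] = FUNCTION_SET
    constant_range: tuple[float, float] = (0.0, 1.0)
    p_constant: float = 0.2
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise RiverbioError("need population_size >= 2 and generations >= 1")
        for r in (self.mutation_rate, self.crossover_rate):
            if not (0.0 <= r <= 1.0):
                raise RiverbioError("rates must lie in [0, 1]")
        if self.mutation_rate + self.crossover_rate > 1.0 + 1e-12:
            raise RiverbioError("mutation_rate + crossover_rate must be <= 1")
        if self.init_depth[0] < 1 or self.init_depth[0] > self.init_depth[1]:
            raise RiverbioError("invalid init_depth range")
        if self.max_depth < self.init_depth[1]:
            raise RiverbioError("max_depth must be >= init depth max")
        unknown = set(self.function_set) - set(FUNCTION_SET)
        if unknown or not self.function_set:
            raise RiverbioError(f"function_set must be a non-empty subset of {FUNCTION_SET}")


@dataclass(frozen=True)
class FitnessReport:
    rmse: float
    pearson_r: float


@dataclass
class GpRunResult:
    """Best-of-run expression tree plus its goodness-of-fit."""

    tree: Tree
    train: FitnessReport
    trajectory: list[float]  # per-generation best training rmse
    seed: int
    run_index: int = 0
    validation: FitnessReport | None = None
    warning: str | None = None


def protected_divide(numerator: float, denominator: float) -> float:
    """Total division: returns 1.0 when |denominator| <= 1e-9."""
    if abs(denominator) > DIV_EPS:
        return numerator / denominator
    return 1.0


# ---------------------------------------------------------------------------
# tree structure helpers

def subtree_slice(tree: Tree, start: int) -> slice:
    """Prefix-order slice of the subtree rooted at token ``start``."""
    pending, j = 1, start
    while pending:
        pending += 1 if isinstance(tree[j], str) else -1
        j += 1
    return slice(start, j)


def tree_depth(tree: Tree) -> int:
    """Number of levels: a lone terminal has depth 1, ``add(x0, c)`` depth 2."""
    stack = [1]
    deepest = 0
    for tok in tree:
        d = stack.pop()
        deepest = max(deepest, d)
        if isinstance(tok, str):
            stack.extend((d + 1, d + 1))
    return deepest


def tree_variables(tree: Tree) -> set[int]:
    """Indices of the predictor variables appearing anywhere in the tree."""
    return {tok for tok in tree if isinstance(tok, int)}


# ---------------------------------------------------------------------------
# random generation

def _random_terminal(config: GpConfig, n_variables: int, rng: np.random.Generator):
    if rng.random() < config.p_constant:
        lo, hi = config.constant_range
        return float(rng.uniform(lo, hi))
    return int(rng.integers(n_variables))


def _grow(
    config: GpConfig,
    n_variables: int,
    rng: np.random.Generator,
    level: int,
    target: int,
    full: bool,
) -> Tree:
    at_bottom = level >= target
    # grow-method internal nodes flip a coin; the root is always an operator
    # so the configured minimum depth is honoured
    make_op = not at_bottom and (full or level == 1 or rng.random() < 0.5)
    if not make_op:
        return [_random_terminal(config, n_variables, rng)]
    op = config.function_set[rng.integers(len(config.function_set))]
    left = _grow(config, n_variables, rng, level + 1, target, full)
    right = _grow(config, n_variables, rng, level + 1, target, full)
    return [op, *left, *right]


def random_tree(config: GpConfig, n_variables: int, rng: np.random.Generator) -> Tree:
    """Ramped half-and-half tree with depth within the configured init range."""
    if n_variables < 1:
        raise RiverbioError("need at least one predictor variable")
    lo, hi = config.init_depth
    target = int(rng.integers(lo, hi + 1))
    full = bool(rng.random() < 0.5)
    return _grow(config, n_variables, rng, 1, target, full)


# ---------------------------------------------------------------------------
# evaluation and fitness

def evaluate_tree(tree: Tree, rows: np.ndarray) -> np.ndarray:
    """Evaluate the tree on every row of a (n_samples, n_variables) matrix."""
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    n, n_vars = X.shape
    stack: list[np.ndarray] = []
    for tok in reversed(tree):
        if isinstance(tok, str):
            a = stack.pop()
            b = stack.pop()
            if tok == "add":
                stack.append(a + b)
            elif tok == "sub":
                stack.append(a - b)
            elif tok == "mul":
                stack.append(a * b)
            else:  # div, protected
                out = np.ones(n)
                np.divide(a, b, out=out, where=np.abs(b) > DIV_EPS)
                stack.append(out)
        elif isinstance(tok, int):
            if tok >= n_vars:
                raise MalformedTreeError(
                    f"tree references x{tok} but matrix has {n_vars} columns"
                )
            stack.append(X[:, tok].copy())
        else:
            stack.append(np.full(n, tok))
    if len(stack) != 1:
        raise MalformedTreeError("malformed prefix token list")
    result = stack[0]
    if not np.all(np.isfinite(result)):
        result = np.nan_to_num(result, nan=0.0, posinf=1e12, neginf=-1e12)
    return result


def fitness(predictions: np.ndarray, targets: np.ndarray) -> FitnessReport:
    """RMSE plus Pearson r; a zero-variance prediction vector scores r = 0."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise RiverbioError("predictions and targets must be equal-length vectors (>= 2)")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    sp, st = p.std(), t.std()
    if sp == 0.0 or st == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(p, t)[0, 1])
    return FitnessReport(rmse=rmse, pearson_r=r)


def _rmse(tree: Tree, X: np.ndarray, y: np.ndarray) -> float:
    pred = evaluate_tree(tree, X)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


# ---------------------------------------------------------------------------
# variation operators

def _tournament(
    fits: np.ndarray, config: GpConfig, rng: np.random.Generator
) -> int:
    contenders = rng.integers(len(fits), size=config.tournament_size)
    return int(contenders[np.argmin(fits[contenders])])


def _crossover(parent_a: Tree, parent_b: Tree, rng: np.random.Generator) -> Tree:
    i = int(rng.integers(len(parent_a)))
    j = int(rng.integers(len(parent_b)))
    sl_a = subtree_slice(parent_a, i)
    sl_b = subtree_slice(parent_b, j)
    return parent_a[: sl_a.start] + parent_b[sl_b] + parent_a[sl_a.stop :]


def _mutate(
    parent: Tree, config: GpConfig, n_variables: int, rng: np.random.Generator
) -> Tree:
    i = int(rng.integers(len(parent)))
    sl = subtree_slice(parent, i)
    target = int(rng.integers(1, 5))  # replacement subtree depth 1-4
    full = bool(rng.random() < 0.5)
    sub = (
        [_random_terminal(config, n_variables, rng)]
        if target == 1
        else _grow(config, n_variables, rng, 1, target, full)
    )
    return parent[: sl.start] + sub + parent[sl.stop :]


# ---------------------------------------------------------------------------
# evolution loop

def evolve(
    config: GpConfig, train_predictors: np.ndarray, train_targets: np.ndarray
) -> GpRunResult:
    """Run one GP search minimising training RMSE; returns the best-ever tree.

    Offspring exceeding ``max_depth`` are rejected in favour of a copy of the
    first parent. With ``elitism >= 1`` the per-generation best fitness is
    monotone non-increasing.
    """
    X = np.asarray(train_predictors, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or y.size < 2:
        raise RiverbioError("predictor matrix rows must match target length (>= 2)")
    n_vars = X.shape[1]
    warning = None
    if np.std(y) == 0.0:
        warning = "constant training target; correlation fitness is degenerate"
        warnings.warn(warning, stacklevel=2)

    rng = np.random.default_rng(config.seed)
    pop = [random_tree(config, n_vars, rng) for _ in range(config.population_size)]
    fits = np.array([_rmse(t, X, y) for t in pop])

    best_i = int(np.argmin(fits))
    best_tree, best_fit = list(pop[best_i]), float(fits[best_i])
    trajectory = [best_fit]

    cx, mut = config.crossover_rate, config.mutation_rate
    for _ in range(config.generations):
        elite_order = np.argsort(fits, kind="stable")[: config.elitism]
        new_pop: list[Tree] = [list(pop[i]) for i in elite_order]
        while len(new_pop) < config.population_size:
            u = rng.random()
            pa = _tournament(fits, config, rng)
            if u < cx:
                pb = _tournament(fits, config, rng)
                child = _crossover(pop[pa], pop[pb], rng)
            elif u < cx + mut:
                child = _mutate(pop[pa], config, n_vars, rng)
            else:
                child = list(pop[pa])
            if tree_depth(child) > config.max_depth:
                child = list(pop[pa])
            new_pop.append(child)
        pop = new_pop
        fits = np.array([_rmse(t, X, y) for t in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_tree, best_fit = list(pop[gen_best]), float(fits[gen_best])
        trajectory.append(min(best_fit, float(fits[gen_best])))

    report = fitness(evaluate_tree(best_tree, X), y)
    return GpRunResult(
        tree=best_tree,
        train=report,
        trajectory=trajectory,
        seed=int(config.seed),
        warning=warning,
    )


# ---------------------------------------------------------------------------
# serialization

def _format_const(v: float) -> str:
    return f"{v:.12g}"


def tree_to_string(tree: Tree) -> str:
    """Canonical prefix string, e.g. ``div(x0, add(x1, 0.5))``."""

    def emit(pos: int) -> tuple[str, int]:
        tok = tree[pos]
        if isinstance(tok, str):
            left, p = emit(pos + 1)
            right, p = emit(p)
            return f"{tok}({left}, {right})", p
        if isinstance(tok, int):
            return f"x{tok}", pos + 1
        return _format_const(tok), pos + 1

    text, end = emit(0)
    if end != len(tree):
        raise MalformedTreeError("trailing tokens after root subtree")
    return text


_INFIX_OP = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


def tree_to_infix(tree: Tree, variable_names: Sequence[str] | None = None) -> str:
    """Human-readable infix rendering with optional variable names."""

    def emit(pos: int) -> tuple[str, int]:
        tok = tree[pos]
        if isinstance(tok, str):
            left, p = emit(pos + 1)
            right, p = emit(p)
            return f"({left} {_INFIX_OP[tok]} {right})", p
        if isinstance(tok, int):
            name = variable_names[tok] if variable_names else f"x{tok}"
            return name, pos + 1
        return _format_const(tok), pos + 1

    return emit(0)[0]


def parse_tree(text: str, n_variables: int) -> Tree:
    """Parse the canonical prefix syntax back into a token list."""
    tokens: Tree = []
    i, n = 0, len(text)

    def skip_ws(i: int) -> int:
        while i < n and text[i].isspace():
            i += 1
        return i

    def parse_expr(i: int) -> int:
        i = skip_ws(i)
        if i >= n:
            raise TreeParseError("unexpected end of input", i)
        j = i
        while j < n and (text[j].isalnum() or text[j] in "+-._"):
            j += 1
        word = text[i:j]
        if not word:
            raise TreeParseError(f"unexpected character {text[i]!r}", i)
        if word in FUNCTION_SET:
            j = skip_ws(j)
            if j >= n or text[j] != "(":
                raise TreeParseError(f"expected '(' after {word!r}", j)
            tokens.append(word)
            j = parse_expr(j + 1)
            j = skip_ws(j)
            if j >= n or text[j] != ",":
                raise TreeParseError("expected ',' between operands", j)
            j = parse_expr(j + 1)
            j = skip_ws(j)
            if j >= n or text[j] != ")":
                raise TreeParseError("expected ')'", j)
            return j + 1
        if word.startswith("x") and word[1:].isdigit():
            idx = int(word[1:])
            if idx >= n_variables:
                raise TreeParseError(f"variable x{idx} out of range", i)
            tokens.append(idx)
            return j
        try:
            tokens.append(float(word))
        except ValueError:
            raise TreeParseError(f"unrecognised token {word!r}", i) from None
        return j

    end = skip_ws(parse_expr(0))
    if end != n:
        raise TreeParseError("trailing characters after expression", end)
    return tokens
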