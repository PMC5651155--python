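"""Tree-based genetic programming over the eight window statistics.

Evolves a single scalar formula combining X1..X8 that minimizes the KNN
misclassification rate on a held-out validation group.  Individuals are
expression trees whose terminals are feature indices 1..8 and whose
internal nodes come from the function set {plus, minus, times, sin, cos,
log}.  log is protected (ln|x|, with log 0 := 0) so every formula is total
and finite.

Evolution is an elitist mu+lambda loop: each generation the 25 parents
produce 25 offspring by subtree crossover or subtree mutation, and the
fittest 25 of parents-plus-offspring survive, so the best fitness never
worsens.  Operator probabilities adapt: stagnation of the generation best
raises the mutation probability by 0.05 (capped at 0.40, crossover keeping
the sum at 1); an improvement resets both to their initial 0.90/0.10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .knn import KNNModel

UNARY_OPS = ("sin", "cos", "log")
BINARY_OPS = ("plus", "minus", "times")
N_FEATURES = 8
LOG_EPS = 1e-12
_FINITE_CAP = 1e300


class MalformedTreeError(ValueError):
    pass


# A formula tree is an immutable nested tuple:
#   terminal:   ("X", i)            i in 1..8
#   unary op:   (op, child)         op in UNARY_OPS
#   binary op:  (op, left, right)   op in BINARY_OPS
Tree = tuple


def terminal(i: int) -> Tree:
    if not 1 <= i <= N_FEATURES:
        raise MalformedTreeError(f"terminal index {i} outside 1..{N_FEATURES}")
    return ("X", i)


def is_terminal(node: Tree) -> bool:
    return node[0] == "X"


def depth(node: Tree) -> int:
    """Number of levels; a bare terminal has depth 1."""
    if is_terminal(node):
        return 1
    return 1 + max(depth(c) for c in node[1:])


def size(node: Tree) -> int:
    if is_terminal(node):
        return 1
    return 1 + sum(size(c) for c in node[1:])


def to_sexp(node: Tree) -> str:
    """Prefix s-expression, e.g. '(plus X1 (times X2 X3))'."""
    if is_terminal(node):
        return f"X{node[1]}"
    return "(" + " ".join([node[0]] + [to_sexp(c) for c in node[1:]]) + ")"


def from_sexp(text: str) -> Tree:
    """Parse the prefix s-expression dialect written by `to_sexp`."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> Tree:
        nonlocal pos
        if pos >= len(tokens):
            raise MalformedTreeError("unexpected end of expression")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            op = tokens[pos]
            pos += 1
            children = []
            while tokens[pos] != ")":
                children.append(parse())
            pos += 1
            if op in UNARY_OPS and len(children) == 1:
                return (op, children[0])
            if op in BINARY_OPS and len(children) == 2:
                return (op, children[0], children[1])
            raise MalformedTreeError(f"bad node ({op} ...) with "
                                     f"{len(children)} children")
        if tok.startswith("X"):
            return terminal(int(tok[1:]))
        raise MalformedTreeError(f"unexpected token {tok!r}")

    tree = parse()
    if pos != len(tokens):
        raise MalformedTreeError("trailing tokens after expression")
    return tree


def validate(node: Tree) -> None:
    if not isinstance(node, tuple) or not node:
        raise MalformedTreeError(f"not a tree node: {node!r}")
    if node[0] == "X":
        if len(node) != 2 or not 1 <= node[1] <= N_FEATURES:
            raise MalformedTreeError(f"bad terminal {node!r}")
    elif node[0] in UNARY_OPS:
        if len(node) != 2:
            raise MalformedTreeError(f"unary node arity: {node!r}")
        validate(node[1])
    elif node[0] in BINARY_OPS:
        if len(node) != 3:
            raise MalformedTreeError(f"binary node arity: {node!r}")
        validate(node[1])
        validate(node[2])
    else:
        raise MalformedTreeError(f"unknown operator {node[0]!r}")


def _finite(x: np.ndarray) -> np.ndarray:
    return np.nan_to_num(x, nan=0.0, posinf=_FINITE_CAP, neginf=-_FINITE_CAP)


def evaluate_formula(tree: Tree, features: np.ndarray) -> np.ndarray | float:
    """Bottom-up evaluation of `tree` on feature rows.

    `features` is either a length-8 vector (returns a scalar) or an
    (n, 8) matrix (returns a length-n vector).  The result is always
    finite: log is protected and overflows are clamped.
    """
    validate(tree)
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    scalar_in = np.asarray(features).ndim == 1

    def ev(node: Tree) -> np.ndarray:
        if is_terminal(node):
            return feats[:, node[1] - 1].copy()
        op = node[0]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if op == "sin":
                return np.sin(ev(node[1]))
            if op == "cos":
                return np.cos(ev(node[1]))
            if op == "log":
                x = ev(node[1])
                out = np.where(np.abs(x) > LOG_EPS,
                               np.log(np.maximum(np.abs(x), LOG_EPS)), 0.0)
                return _finite(out)
            a, b = ev(node[1]), ev(node[2])
            if op == "plus":
                return _finite(a + b)
            if op == "minus":
                return _finite(a - b)
            if op == "times":
                return _finite(a * b)
        raise MalformedTreeError(f"unknown operator {op!r}")

    result = ev(tree)
    return float(result[0]) if scalar_in else result


# ---------------------------------------------------------------------------
# random trees and variation operators
# ---------------------------------------------------------------------------

def _grow(rng: np.random.Generator, max_depth: int,
          terminals: tuple[int, ...], full: bool) -> Tree:
    if max_depth <= 1 or (not full and rng.random() < 0.3):
        return terminal(int(rng.choice(terminals)))
    ops = UNARY_OPS + BINARY_OPS
    op = ops[rng.integers(len(ops))]
    if op in UNARY_OPS:
        return (op, _grow(rng, max_depth - 1, terminals, full))
    return (op, _grow(rng, max_depth - 1, terminals, full),
            _grow(rng, max_depth - 1, terminals, full))


def random_tree(max_depth: int, rng: np.random.Generator,
                terminals: tuple[int, ...] = tuple(range(1, 9))) -> Tree:
    """Ramped half-and-half tree up to `max_depth` levels.

    The target depth is drawn from 2..min(6, max_depth); half the draws
    use the "full" method, half "grow".  max_depth 1 forces a bare
    terminal.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if max_depth == 1:
        return terminal(int(rng.choice(terminals)))
    d = int(rng.integers(2, min(6, max_depth) + 1))
    full = bool(rng.random() < 0.5)
    return _grow(rng, d, terminals, full)


def _nodes(tree: Tree, path: tuple[int, ...] = ()) -> list[tuple[tuple[int, ...], Tree]]:
    out = [(path, tree)]
    if not is_terminal(tree):
        for i, child in enumerate(tree[1:]):
            out.extend(_nodes(child, path + (i,)))
    return out


def _replace_at(tree: Tree, path: tuple[int, ...], sub: Tree) -> Tree:
    if not path:
        return sub
    i = path[0]
    children = list(tree[1:])
    children[i] = _replace_at(children[i], path[1:], sub)
    return (tree[0], *children)


def crossover(a: Tree, b: Tree, rng: np.random.Generator,
              max_depth: int = 25, max_tries: int = 10) -> tuple[Tree, Tree]:
    """Swap uniformly chosen subtrees between two parents.

    Offspring exceeding `max_depth` are rejected and the swap resampled up
    to `max_tries` times; on exhaustion the parents pass through unchanged.
    """
    nodes_a, nodes_b = _nodes(a), _nodes(b)
    for _ in range(max_tries):
        pa, sa = nodes_a[rng.integers(len(nodes_a))]
        pb, sb = nodes_b[rng.integers(len(nodes_b))]
        child_a = _replace_at(a, pa, sb)
        child_b = _replace_at(b, pb, sa)
        if depth(child_a) <= max_depth and depth(child_b) <= max_depth:
            return child_a, child_b
    return a, b


def mutate(a: Tree, rng: np.random.Generator,
           terminals: tuple[int, ...] = tuple(range(1, 9)),
           max_depth: int = 25, subtree_depth: int = 4,
           max_tries: int = 10) -> Tree:
    """Replace a uniformly chosen subtree with a fresh random tree."""
    nodes = _nodes(a)
    for _ in range(max_tries):
        path, _old = nodes[rng.integers(len(nodes))]
        sub = random_tree(subtree_depth, rng, terminals)
        child = _replace_at(a, path, sub)
        if depth(child) <= max_depth:
            return child
    return a


# ---------------------------------------------------------------------------
# fitness and evolution
# ---------------------------------------------------------------------------

@dataclass
class FitnessContext:
    """Reference/validation groups for the KNN-wrapper fitness.

    Both groups hold raw feature vectors; a candidate formula is applied to
    the reference features to obtain the 1-D reference points, and to each
    validation vector to obtain the query scalar.  Both groups are expected
    to be class-balanced.
    """

    reference_features: np.ndarray   # (n_ref, 8)
    reference_labels: np.ndarray     # (n_ref,) of {0, 1}
    validation_features: np.ndarray  # (n_val, 8)
    validation_labels: np.ndarray    # (n_val,)
    k: int = 100

    def __post_init__(self) -> None:
        self.reference_features = np.asarray(self.reference_features, float)
        self.reference_labels = np.asarray(self.reference_labels, int)
        self.validation_features = np.asarray(self.validation_features, float)
        self.validation_labels = np.asarray(self.validation_labels, int)
        if self.validation_features.shape[0] == 0:
            raise ValueError("validation set is empty")
        if self.reference_features.shape[0] == 0:
            raise ValueError("reference set is empty")


@dataclass
class GPConfig:
    """Evolution parameters (defaults follow the published run settings)."""

    population_size: int = 25
    n_generations: int = 100
    max_tree_level: int = 25
    p_crossover_init: float = 0.90
    p_mutation_init: float = 0.10
    adaptation_step: float = 0.05
    p_mutation_cap: float = 0.40
    terminal_subset: tuple[int, ...] = tuple(range(1, 9))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if abs(self.p_crossover_init + self.p_mutation_init - 1.0) > 1e-12:
            raise ValueError("p_crossover_init + p_mutation_init must be 1")
        if not self.terminal_subset:
            raise ValueError("terminal_subset must be non-empty")


def fitness(tree: Tree, ctx: FitnessContext) -> float:
    """KNN misclassification rate of the formula on the validation group."""
    ref_scalars = np.atleast_1d(
        evaluate_formula(tree, ctx.reference_features))
    model = KNNModel(ref_scalars, ctx.reference_labels, k=ctx.k)
    queries = np.atleast_1d(
        evaluate_formula(tree, ctx.validation_features))
    predicted = model.classify_many(queries)
    return float(np.mean(predicted != ctx.validation_labels))


@dataclass
class EvolutionResult:
    best_tree: Tree
    best_fitness: float
    trace: np.ndarray                 # per-generation best fitness
    p_mutation_trace: np.ndarray
    population_sizes: np.ndarray      # survivors per generation


def evolve(ctx: FitnessContext, cfg: GPConfig,
           fitness_fn: Callable[[Tree, FitnessContext], float] | None = None,
           ) -> EvolutionResult:
    """Elitist mu+lambda GP search for the minimum-error formula.

    Returns the best individual after `n_generations` together with the
    per-generation best-fitness trace (monotone non-increasing by
    elitism).  Fully deterministic for a fixed `cfg.rng_seed`.
    """
    fit = fitness_fn or fitness
    rng = np.random.default_rng(cfg.rng_seed)
    mu = cfg.population_size
    cache: dict[Tree, float] = {}

    def scored(tree: Tree) -> float:
        if tree not in cache:
            cache[tree] = fit(tree, ctx)
        return cache[tree]

    population = [random_tree(min(6, cfg.max_tree_level), rng,
                              cfg.terminal_subset) for _ in range(mu)]
    p_mut = cfg.p_mutation_init
    trace, p_trace, pop_sizes = [], [], []
    best_so_far = min(scored(t) for t in population)

    for _gen in range(cfg.n_generations):
        offspring: list[Tree] = []
        while len(offspring) < mu:
            if rng.random() < 1.0 - p_mut:  # crossover
                i, j = rng.integers(mu), rng.integers(mu)
                c1, c2 = crossover(population[i], population[j], rng,
                                   cfg.max_tree_level)
                offspring.append(c1)
                if len(offspring) < mu:
                    offspring.append(c2)
            else:
                i = rng.integers(mu)
                offspring.append(mutate(population[i], rng,
                                        cfg.terminal_subset,
                                        cfg.max_tree_level))
        pool = population + offspring
        # stable sort: ties keep parents-before-offspring insertion order
        order = sorted(range(len(pool)), key=lambda i: scored(pool[i]))
        population = [pool[i] for i in order[:mu]]
        gen_best = scored(population[0])
        if gen_best < best_so_far:
            best_so_far = gen_best
            p_mut = cfg.p_mutation_init
        else:
            p_mut = min(p_mut + cfg.adaptation_step, cfg.p_mutation_cap)
        trace.append(gen_best)
        p_trace.append(p_mut)
        pop_sizes.append(len(population))

    return EvolutionResult(
        best_tree=population[0],
        best_fitness=trace[-1],
        trace=np.array(trace),
        p_mutation_trace=np.array(p_trace),
        population_sizes=np.array(pop_sizes),
    )
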