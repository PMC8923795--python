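"""Expression-tree genetic programming core.

Single-tree binary classifiers: a tree maps a feature vector to a real
number and the sign against a threshold (default 0) decides the class.
Fitness is training-set classification accuracy.  This module provides the
genotype, ramped half-and-half initialization with enforced structural
diversity, vectorized evaluation with protected operators, tournament
selection, and the three generational operators — reproduction (elitism),
hill-climbing crossover and hill-climbing mutation.  The hill-climbing
variants admit a child only when it is strictly fitter than its parent,
which makes the best-of-population fitness non-decreasing.

Every fitness evaluation is tallied on a run-wide counter, so the true
computational cost of a run (including the operators' internal retry
evaluations) is always reported alongside the generational budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .data_model import FeatureTable

__all__ = [
    "FSGPConfig",
    "GPTree",
    "FunctionNode",
    "FeatureRef",
    "Constant",
    "Individual",
    "Population",
    "TrainingFitness",
    "ConfigError",
    "DiversityError",
    "make_random_tree",
    "evaluate_tree",
    "evaluate_matrix",
    "classify",
    "fitness",
    "init_population",
    "tournament_select",
    "hc_crossover",
    "hc_mutation",
    "next_generation",
    "serialize_tree",
    "parse_tree",
]

# magnitude cap applied at every function node so outputs stay finite
_CLIP = 1.0e12
# |denominator| below this triggers the protected-division convention (-> 1)
_DIV_EPS = 1.0e-9
# attempts allowed per slot when enforcing structural diversity at init
MAX_INIT_RETRIES = 200


class ConfigError(ValueError):
    """Invalid algorithm configuration."""


class DiversityError(RuntimeError):
    """Could not produce a structurally new tree within the retry cap."""


@dataclass
class FSGPConfig:
    """All tunable parameters of a GP / FSGP run.

    Defaults follow the study configuration: population 100, operator
    probabilities 60/20/20 (crossover/reproduction/mutation), initial ramp
    depths 5-10, and an evaluation budget of 80000 training-accuracy
    computations.  ``max_tree_depth`` 17 and tournament size 7 are standard
    GP conventions.
    """

    population_size: int = 100
    p_crossover: float = 0.6
    p_reproduction: float = 0.2
    p_mutation: float = 0.2
    init_min_depth: int = 5
    init_max_depth: int = 10
    max_tree_depth: int = 17
    tournament_size: int = 7
    evaluation_budget: int = 80000
    function_set: tuple[str, ...] = ("+", "-", "*", "div")
    constant_range: tuple[float, float] = (-1.0, 1.0)
    use_constants: bool = True
    constant_prob: float = 0.1
    hc_max_retries: int = 10
    classification_threshold: float = 0.0
    per_tree_presence: bool = False
    average_over_nonzero: bool = False
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        probs = (self.p_crossover, self.p_reproduction, self.p_mutation)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"operator probabilities must be non-negative and sum to 1, got {probs}"
            )
        if not 1 <= self.init_min_depth <= self.init_max_depth <= self.max_tree_depth:
            raise ConfigError(
                "need 1 <= init_min_depth <= init_max_depth <= max_tree_depth, got "
                f"{self.init_min_depth}/{self.init_max_depth}/{self.max_tree_depth}"
            )
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not 1 <= self.tournament_size:
            raise ConfigError("tournament_size must be >= 1")
        if self.evaluation_budget < 1:
            raise ConfigError("evaluation_budget must be >= 1")
        if self.hc_max_retries < 0:
            raise ConfigError("hc_max_retries must be >= 0")
        if self.constant_range[0] > self.constant_range[1]:
            raise ConfigError("constant_range must be a non-empty interval")
        unknown = set(self.function_set) - set(_FUNCTIONS)
        if unknown:
            raise ConfigError(f"unknown function symbols: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "FSGPConfig":
        return dc_replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["function_set"] = list(self.function_set)
        d["constant_range"] = list(self.constant_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FSGPConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "function_set" in known:
            known["function_set"] = tuple(known["function_set"])
        if "constant_range" in known:
            known["constant_range"] = tuple(known["constant_range"])
        cfg = cls(**known)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Genotype
# ---------------------------------------------------------------------------

class FeatureRef:
    """Terminal node referencing a feature column by name."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name


class Constant:
    """Terminal node holding a real constant."""

    __slots__ = ("value",)

    def __init__(self, value: float):
        self.value = float(value)


class FunctionNode:
    __slots__ = ("symbol", "children")

    def __init__(self, symbol: str, children: list):
        self.symbol = symbol
        self.children = children


Node = FunctionNode | FeatureRef | Constant

_FUNCTIONS = {"+": 2, "-": 2, "*": 2, "div": 2}


@dataclass
class GPTree:
    """An expression tree; a lone terminal has depth 1 by convention."""

    root: Node

    def depth(self) -> int:
        return _depth(self.root)

    def size(self) -> int:
        return _size(self.root)

    def feature_counts(self) -> dict[str, int]:
        """Occurrence count of every feature terminal in the tree."""
        counts: dict[str, int] = {}
        _count_features(self.root, counts)
        return counts

    def features(self) -> list[str]:
        """Distinct feature names, ordered by first (prefix-order) occurrence."""
        seen: dict[str, None] = {}
        for node in _iter_nodes(self.root):
            if isinstance(node, FeatureRef) and node.name not in seen:
                seen[node.name] = None
        return list(seen)

    def copy(self) -> "GPTree":
        return GPTree(_copy(self.root))

    def serialize(self) -> str:
        return serialize_tree(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def _depth(node: Node) -> int:
    if isinstance(node, FunctionNode):
        return 1 + max(_depth(c) for c in node.children)
    return 1


def _size(node: Node) -> int:
    if isinstance(node, FunctionNode):
        return 1 + sum(_size(c) for c in node.children)
    return 1


def _count_features(node: Node, counts: dict[str, int]) -> None:
    if isinstance(node, FeatureRef):
        counts[node.name] = counts.get(node.name, 0) + 1
    elif isinstance(node, FunctionNode):
        for c in node.children:
            _count_features(c, counts)


def _iter_nodes(node: Node):
    yield node
    if isinstance(node, FunctionNode):
        for c in node.children:
            yield from _iter_nodes(c)


def _copy(node: Node) -> Node:
    if isinstance(node, FunctionNode):
        return FunctionNode(node.symbol, [_copy(c) for c in node.children])
    if isinstance(node, FeatureRef):
        return FeatureRef(node.name)
    return Constant(node.value)


# ---------------------------------------------------------------------------
# Canonical serialization (prefix s-expressions, injective up to structure)
# ---------------------------------------------------------------------------

def _fmt_const(v: float) -> str:
    return f"{v:.6g}"


def serialize_tree(tree: GPTree) -> str:
    """Canonical prefix s-expression, constants at 6 significant digits."""
    out: list[str] = []
    _serialize(tree.root, out)
    return "".join(out)


def _serialize(node: Node, out: list[str]) -> None:
    if isinstance(node, FunctionNode):
        out.append("(" + node.symbol)
        for c in node.children:
            out.append(" ")
            _serialize(c, out)
        out.append(")")
    elif isinstance(node, FeatureRef):
        out.append(node.name)
    else:
        out.append(_fmt_const(node.value))


def parse_tree(text: str) -> GPTree:
    """Parse the canonical s-expression grammar; serialize∘parse is identity."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of expression")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            symbol = tokens[pos]
            pos += 1
            if symbol not in _FUNCTIONS:
                raise ValueError(f"unknown function symbol {symbol!r}")
            children = []
            while pos < len(tokens) and tokens[pos] != ")":
                children.append(parse_node())
            if pos >= len(tokens):
                raise ValueError("unbalanced parentheses")
            pos += 1
            if len(children) != _FUNCTIONS[symbol]:
                raise ValueError(f"{symbol} expects {_FUNCTIONS[symbol]} arguments")
            return FunctionNode(symbol, children)
        if tok == ")":
            raise ValueError("unexpected ')'")
        try:
            return Constant(float(tok))
        except ValueError:
            return FeatureRef(tok)

    root = parse_node()
    if pos != len(tokens):
        raise ValueError("trailing tokens after expression")
    return GPTree(root)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _apply(symbol: str, a, b):
    if symbol == "+":
        r = a + b
    elif symbol == "-":
        r = a - b
    elif symbol == "*":
        r = a * b
    elif symbol == "div":
        small = np.abs(b) < _DIV_EPS
        r = np.where(small, 1.0, a / np.where(small, 1.0, b))
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown function symbol {symbol!r}")
    return np.clip(r, -_CLIP, _CLIP)


def evaluate_matrix(tree: GPTree, X: np.ndarray, column_index: dict[str, int]) -> np.ndarray:
    """Vectorized evaluation over all rows of ``X``; output always finite."""
    return np.asarray(_eval(tree.root, X, column_index), dtype=float) * np.ones(X.shape[0])


def _eval(node: Node, X: np.ndarray, column_index: dict[str, int]):
    if isinstance(node, FeatureRef):
        try:
            return X[:, column_index[node.name]]
        except KeyError:
            raise KeyError(f"tree references unknown feature {node.name!r}") from None
    if isinstance(node, Constant):
        return node.value
    a = _eval(node.children[0], X, column_index)
    b = _eval(node.children[1], X, column_index)
    return _apply(node.symbol, a, b)


def evaluate_tree(tree: GPTree, sample: dict[str, float] | np.ndarray,
                  column_index: dict[str, int] | None = None) -> float:
    """Evaluate on a single sample (a name->value mapping or a row vector)."""
    if isinstance(sample, dict):
        names = list(sample)
        column_index = {n: j for j, n in enumerate(names)}
        row = np.array([[sample[n] for n in names]], dtype=float)
    else:
        if column_index is None:
            raise ValueError("column_index required for array samples")
        row = np.asarray(sample, dtype=float).reshape(1, -1)
    return float(evaluate_matrix(tree, row, column_index)[0])


def classify(tree: GPTree, sample, threshold: float = 0.0,
             column_index: dict[str, int] | None = None) -> int:
    """Class 1 (positive) iff the tree output is >= threshold, else class 0."""
    return int(evaluate_tree(tree, sample, column_index) >= threshold)


def predict_table(tree: GPTree, table: FeatureTable, threshold: float = 0.0) -> np.ndarray:
    """0/1 predictions for every row of a FeatureTable."""
    out = evaluate_matrix(tree, table.values, table.column_index())
    return (out >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Fitness (training accuracy) with budget accounting
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    tree: GPTree
    fitness: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass
class Population:
    individuals: list[Individual]
    generation_index: int = 0

    def __len__(self) -> int:
        return len(self.individuals)

    def best(self) -> Individual:
        return max(self.individuals, key=lambda ind: ind.fitness)

    def mean_fitness(self) -> float:
        return float(np.mean([ind.fitness for ind in self.individuals]))


class TrainingFitness:
    """Callable computing training accuracy; every call tallies one evaluation.

    The counter on this object records every actual fitness computation of
    a run — hill-climbing retries and replacement-mutation trials included —
    and is reported as ``total_evaluations``; the driver's stopping clock is
    the generational schedule, not this counter.
    """

    def __init__(self, train: FeatureTable, config: FSGPConfig):
        if train.n_samples == 0:
            raise ValueError("training table is empty")
        self.table = train
        self.threshold = config.classification_threshold
        self._index = train.column_index()
        self.evaluations = 0

    def __call__(self, tree: GPTree) -> float:
        self.evaluations += 1
        out = evaluate_matrix(tree, self.table.values, self._index)
        preds = (out >= self.threshold).astype(int)
        return float(np.mean(preds == self.table.labels))


def fitness(tree: GPTree, train: FeatureTable, config: FSGPConfig,
            counter: TrainingFitness | None = None) -> float:
    """Training classification accuracy in [0, 1] (one billed evaluation)."""
    fn = counter if counter is not None else TrainingFitness(train, config)
    return fn(tree)


# ---------------------------------------------------------------------------
# Random tree construction (grow / full) and ramped half-and-half init
# ---------------------------------------------------------------------------

def _random_terminal(config: FSGPConfig, feature_pool: list[str], rng) -> Node:
    if config.use_constants and rng.random() < config.constant_prob:
        lo, hi = config.constant_range
        return Constant(rng.uniform(lo, hi))
    return FeatureRef(feature_pool[rng.integers(len(feature_pool))])


def make_random_tree(method: str, min_depth: int, max_depth: int,
                     config: FSGPConfig, feature_pool: list[str], rng) -> GPTree:
    """Build a random tree by the grow or full method.

    ``full`` places terminals exactly at ``max_depth`` (``min_depth`` is
    ignored beyond validation); ``grow`` yields depth in
    ``[min_depth, max_depth]`` by forcing functions above ``min_depth``,
    terminals at ``max_depth``, and a 50/50 choice in between.
    """
    if not 1 <= min_depth <= max_depth:
        raise ValueError(f"need 1 <= min_depth <= max_depth, got {min_depth}/{max_depth}")
    if max_depth > 1 and not config.function_set:
        raise ConfigError("empty function set cannot build trees deeper than 1")
    if not feature_pool and not config.use_constants:
        raise ConfigError("no terminals available (empty feature pool, no constants)")
    if method not in ("grow", "full"):
        raise ValueError(f"method must be 'grow' or 'full', got {method!r}")

    def build(depth: int) -> Node:
        at_max = depth == max_depth
        if method == "full":
            make_function = not at_max
        else:
            if at_max:
                make_function = False
            elif depth < min_depth:
                make_function = True
            else:
                make_function = rng.random() < 0.5
        if not make_function:
            return _random_terminal(config, feature_pool, rng)
        symbol = config.function_set[rng.integers(len(config.function_set))]
        return FunctionNode(symbol, [build(depth + 1) for _ in range(_FUNCTIONS[symbol])])

    return GPTree(build(1))


def init_population(config: FSGPConfig, train: FeatureTable, rng,
                    feature_pool: list[str] | None = None) -> Population:
    """Ramped half-and-half initial population with enforced diversity.

    Target depths cycle over ``[init_min_depth, init_max_depth]`` while the
    construction method alternates grow/full.  No two individuals share a
    canonical serialization; if a structurally new tree cannot be found in
    ``MAX_INIT_RETRIES`` attempts a :class:`DiversityError` is raised.
    """
    config.validate()
    pool = feature_pool if feature_pool is not None else list(train.feature_names)
    depths = list(range(config.init_min_depth, config.init_max_depth + 1))
    seen: set[str] = set()
    individuals: list[Individual] = []
    for i in range(config.population_size):
        target = depths[i % len(depths)]
        method = "grow" if (i // len(depths)) % 2 == 0 else "full"
        for attempt in range(MAX_INIT_RETRIES):
            tree = make_random_tree(method, min(config.init_min_depth, target),
                                    target, config, pool, rng)
            key = tree.serialize()
            if key not in seen:
                seen.add(key)
                individuals.append(Individual(tree))
                break
            # alternate methods, then allow deeper targets, to widen the
            # reachable set when a shallow stratum is exhausted
            method = "full" if method == "grow" else "grow"
            if attempt >= MAX_INIT_RETRIES // 2:
                target = min(config.init_max_depth, target + 1)
        else:
            raise DiversityError(
                f"could not generate a structurally distinct tree for slot {i} "
                f"within {MAX_INIT_RETRIES} attempts"
            )
    return Population(individuals, generation_index=0)


# ---------------------------------------------------------------------------
# Selection and variation
# ---------------------------------------------------------------------------

def tournament_select(population: Population, k: int, rng) -> Individual:
    """Best of ``k`` uniform draws with replacement.

    Fitness ties break toward the smaller tree, then uniformly at random.
    """
    inds = population.individuals
    if not 1 <= k <= len(inds):
        raise ValueError(f"tournament size must be in [1, {len(inds)}], got {k}")
    picks = [inds[rng.integers(len(inds))] for _ in range(k)]
    for ind in picks:
        if not ind.evaluated:
            raise RuntimeError("tournament over unevaluated individuals")
    best_fit = max(ind.fitness for ind in picks)
    pool = [ind for ind in picks if ind.fitness == best_fit]
    if len(pool) > 1:
        smallest = min(ind.tree.size() for ind in pool)
        pool = [ind for ind in pool if ind.tree.size() == smallest]
    return pool[rng.integers(len(pool))]


def _random_subtree_index(tree: GPTree, rng) -> int:
    return int(rng.integers(tree.size()))


def _get_subtree(node: Node, index: int) -> tuple[Node, int]:
    """Prefix-order node lookup; returns (node, consumed)."""
    if index == 0:
        return node, 1
    consumed = 1
    if isinstance(node, FunctionNode):
        for c in node.children:
            found, used = _get_subtree(c, index - consumed)
            if found is not None:
                return found, consumed + used
            consumed += used
    return None, consumed


def _replace_subtree(node: Node, index: int, new: Node) -> tuple[Node, int]:
    """Return a copy of ``node`` with prefix-order node ``index`` replaced."""
    if index == 0:
        return _copy(new), 1
    consumed = 1
    if isinstance(node, FunctionNode):
        children = []
        replaced = False
        for c in node.children:
            if not replaced and index - consumed < _size(c):
                new_child, _ = _replace_subtree(c, index - consumed, new)
                children.append(new_child)
                replaced = True
            else:
                children.append(_copy(c))
            consumed += _size(c)
        return FunctionNode(node.symbol, children), consumed
    return _copy(node), consumed


def subtree(tree: GPTree, index: int) -> Node:
    node, _ = _get_subtree(tree.root, index)
    if node is None:
        raise IndexError(index)
    return node


def replace_subtree(tree: GPTree, index: int, new: Node) -> GPTree:
    if not 0 <= index < tree.size():
        raise IndexError(index)
    root, _ = _replace_subtree(tree.root, index, new)
    return GPTree(root)


def _crossover_once(a: GPTree, b: GPTree, rng) -> tuple[GPTree, GPTree]:
    ia = _random_subtree_index(a, rng)
    ib = _random_subtree_index(b, rng)
    sub_a = subtree(a, ia)
    sub_b = subtree(b, ib)
    return replace_subtree(a, ia, sub_b), replace_subtree(b, ib, sub_a)


def hc_crossover(parent_a: Individual, parent_b: Individual, config: FSGPConfig,
                 rng, fitness_fn) -> tuple[Individual, Individual]:
    """Hill-climbing subtree crossover.

    Up to ``hc_max_retries`` exchange attempts; a child takes its parent's
    slot only if strictly fitter and within ``max_tree_depth``.  Parents that
    are never beaten are returned unchanged.  Each admissible child costs one
    fitness evaluation.
    """
    out_a, out_b = parent_a, parent_b
    improved_a = improved_b = False
    for _ in range(config.hc_max_retries):
        if improved_a and improved_b:
            break
        child_a, child_b = _crossover_once(parent_a.tree, parent_b.tree, rng)
        if not improved_a and child_a.depth() <= config.max_tree_depth:
            f = fitness_fn(child_a)
            if f > parent_a.fitness:
                out_a, improved_a = Individual(child_a, f), True
        if not improved_b and child_b.depth() <= config.max_tree_depth:
            f = fitness_fn(child_b)
            if f > parent_b.fitness:
                out_b, improved_b = Individual(child_b, f), True
    return out_a, out_b


def hc_mutation(parent: Individual, config: FSGPConfig, rng, fitness_fn,
                feature_pool: list[str]) -> Individual:
    """Hill-climbing subtree mutation.

    Replaces a uniformly chosen subtree with a fresh grow-method subtree
    (depth budget respecting ``max_tree_depth``); the first strictly fitter
    child within ``hc_max_retries`` attempts is adopted, else the parent is
    returned.  New subtrees draw feature terminals from ``feature_pool``.
    """
    for _ in range(config.hc_max_retries):
        idx = _random_subtree_index(parent.tree, rng)
        node_depth = _node_depth_at(parent.tree.root, idx)
        budget = config.max_tree_depth - node_depth + 1
        sub = make_random_tree("grow", 1, max(1, min(budget, config.init_max_depth)),
                               config, feature_pool, rng)
        child = replace_subtree(parent.tree, idx, sub.root)
        if child.depth() > config.max_tree_depth:
            continue
        f = fitness_fn(child)
        if f > parent.fitness:
            return Individual(child, f)
    return parent


def _node_depth_at(node: Node, index: int, depth: int = 1) -> int:
    """Depth (root = 1) of the prefix-order node ``index``."""
    if index == 0:
        return depth
    consumed = 1
    if isinstance(node, FunctionNode):
        for c in node.children:
            sz = _size(c)
            if index - consumed < sz:
                return _node_depth_at(c, index - consumed, depth + 1)
            consumed += sz
    raise IndexError(index)


def next_generation(population: Population, config: FSGPConfig, rng, fitness_fn,
                    feature_pool: list[str]) -> Population:
    """One generational step: elitism, then operator-filled slots.

    The single best individual is copied in unchanged (elitism).  Remaining
    slots are filled by drawing an operator per slot — crossover consumes a
    pair of slots — with the configured probabilities; parents come from
    tournament selection.  Population size is invariant.
    """
    probs = (config.p_crossover, config.p_reproduction, config.p_mutation)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"operator probabilities must sum to 1, got {probs}")
    size = len(population)
    new: list[Individual] = [population.best()]
    k = config.tournament_size
    while len(new) < size:
        r = rng.random()
        if r < probs[0] and size - len(new) >= 2:
            pa = tournament_select(population, k, rng)
            pb = tournament_select(population, k, rng)
            ca, cb = hc_crossover(pa, pb, config, rng, fitness_fn)
            new.extend([ca, cb])
        elif r < probs[0] + probs[1]:
            new.append(tournament_select(population, k, rng))
        else:
            parent = tournament_select(population, k, rng)
            new.append(hc_mutation(parent, config, rng, fitness_fn, feature_pool))
    return Population(new[:size], generation_index=population.generation_index + 1)
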