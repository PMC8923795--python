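"""GP genotype, initialization, evaluation and operator behavior."""

import math

import numpy as np
import pytest

from fsgp.data_model import FeatureTable
from fsgp.gp_core import (
    Constant,
    DiversityError,
    FeatureRef,
    FSGPConfig,
    FunctionNode,
    GPTree,
    Individual,
    Population,
    TrainingFitness,
    classify,
    evaluate_tree,
    evaluate_matrix,
    hc_crossover,
    hc_mutation,
    init_population,
    make_random_tree,
    next_generation,
    parse_tree,
    serialize_tree,
    tournament_select,
)

# ---------------------------------------------------------------------------
# Independent oracle: naive scalar recursive interpreter of the same
# tree semantics (protected division -> 1, clipping at 1e12).
# ---------------------------------------------------------------------------

def naive_eval(node, sample: dict) -> float:
    if isinstance(node, FeatureRef):
        return sample[node.name]
    if isinstance(node, Constant):
        return node.value
    a = naive_eval(node.children[0], sample)
    b = naive_eval(node.children[1], sample)
    if node.symbol == "+":
        r = a + b
    elif node.symbol == "-":
        r = a - b
    elif node.symbol == "*":
        r = a * b
    elif node.symbol == "div":
        r = 1.0 if abs(b) < 1e-9 else a / b
    else:
        raise AssertionError(node.symbol)
    return max(-1e12, min(1e12, r))


FEATS = [f"f{i}" for i in range(6)]


def random_config(**kw):
    defaults = dict(init_min_depth=1, init_max_depth=6, max_tree_depth=10)
    defaults.update(kw)
    return FSGPConfig(**defaults)


class TestTreeConstruction:
    def test_full_method_puts_all_leaves_at_target_depth(self):
        rng = np.random.default_rng(0)
        cfg = random_config()
        for _ in range(20):
            tree = make_random_tree("full", 3, 3, cfg, FEATS, rng)
            assert tree.depth() == 3
            # every path from root to leaf has length exactly 3
            def leaf_depths(node, d=1):
                if isinstance(node, FunctionNode):
                    for c in node.children:
                        yield from leaf_depths(c, d + 1)
                else:
                    yield d
            assert set(leaf_depths(tree.root)) == {3}

    def test_depth_one_gives_single_terminal(self):
        rng = np.random.default_rng(1)
        cfg = random_config()
        tree = make_random_tree("grow", 1, 1, cfg, FEATS, rng)
        assert tree.size() == 1
        assert tree.depth() == 1

    def test_ramped_depth_range_and_both_methods(self):
        """1000 ramped trees with depths 5-10 stay in range, both methods occur."""
        rng = np.random.default_rng(2)
        cfg = FSGPConfig(population_size=1000, init_min_depth=5, init_max_depth=10)
        train = FeatureTable(FEATS, np.zeros((4, 6)), np.array([0, 1, 0, 1]))
        pop = init_population(cfg, train, rng)
        depths = [ind.tree.depth() for ind in pop.individuals]
        assert min(depths) >= 5 and max(depths) <= 10
        assert all(d in range(5, 11) for d in depths)
        # full-method trees of depth d are perfect-arity; grow trees generally not:
        # with 1000 trees both shapes must be present
        sizes_at = {}
        for ind, d in zip(pop.individuals, depths):
            sizes_at.setdefault(d, set()).add(ind.tree.size())
        assert any(len(s) > 1 for s in sizes_at.values())

    def test_bad_depth_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            make_random_tree("grow", 3, 2, random_config(), FEATS, rng)
        with pytest.raises(ValueError):
            make_random_tree("bogus", 1, 2, random_config(), FEATS, rng)


class TestEvaluation:
    def test_arithmetic_example(self):
        tree = parse_tree("(+ f1 (* 2.0 f2))")
        assert evaluate_tree(tree, {"f1": 1.0, "f2": 2.0}) == 5.0

    def test_protected_division_convention(self):
        tree = parse_tree("(div f1 f2)")
        assert evaluate_tree(tree, {"f1": 3.0, "f2": 0.0}) == 1.0

    def test_lone_terminal_identity(self):
        tree = parse_tree("f3")
        assert evaluate_tree(tree, {"f3": -0.4}) == -0.4

    def test_vectorized_matches_naive_oracle(self):
        """Random trees x random inputs agree with the scalar interpreter."""
        rng = np.random.default_rng(42)
        cfg = random_config()
        for _ in range(300):
            tree = make_random_tree("grow", 1, 5, cfg, FEATS, rng)
            X = rng.normal(scale=5.0, size=(4, len(FEATS)))
            idx = {n: j for j, n in enumerate(FEATS)}
            got = evaluate_matrix(tree, X, idx)
            for i in range(X.shape[0]):
                sample = dict(zip(FEATS, X[i]))
                expected = naive_eval(tree.root, sample)
                assert got[i] == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_output_always_finite_under_extreme_inputs(self):
        rng = np.random.default_rng(3)
        cfg = random_config()
        idx = {n: j for j, n in enumerate(FEATS)}
        X = rng.normal(scale=1e9, size=(8, len(FEATS)))
        for _ in range(100):
            tree = make_random_tree("full", 6, 6, cfg, FEATS, rng)
            assert np.isfinite(evaluate_matrix(tree, X, idx)).all()


class TestClassify:
    @pytest.mark.parametrize("output,expected", [(0.7, 1), (0.0, 1), (-3.0, 0)])
    def test_sign_threshold_rule(self, output, expected):
        tree = GPTree(Constant(output))
        assert classify(tree, {"f1": 0.0}) == expected


class TestSerialization:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        cfg = random_config()
        for _ in range(200):
            tree = make_random_tree("grow", 1, 6, cfg, FEATS, rng)
            text = serialize_tree(tree)
            assert serialize_tree(parse_tree(text)) == text

    def test_canonical_example(self):
        text = "(+ AF3_theta (div F7_alpha 0.25))"
        assert serialize_tree(parse_tree(text)) == text

    def test_injective_on_distinct_structures(self):
        a = parse_tree("(+ f1 f2)")
        b = parse_tree("(+ f2 f1)")
        assert serialize_tree(a) != serialize_tree(b)

    def test_malformed_input_rejected(self):
        for bad in ["(+ f1", "(+ f1 f2 f3)", "(what f1 f2)", "f1 f2"]:
            with pytest.raises(ValueError):
                parse_tree(bad)


class TestFitness:
    def test_constant_tree_scores_positive_fraction(self):
        values = np.zeros((10, 1))
        labels = np.array([1] * 6 + [0] * 4)
        table = FeatureTable(["f0"], values, labels)
        fn = TrainingFitness(table, FSGPConfig())
        assert fn(GPTree(Constant(1.0))) == 0.6

    def test_perfect_tree_scores_one(self, toy_table):
        # tree that outputs +1 on class-1 rows: use labels directly via f1 sign
        values = np.where(toy_table.labels == 1, 1.0, -1.0).reshape(-1, 1)
        table = FeatureTable(["s"], values, toy_table.labels)
        fn = TrainingFitness(table, FSGPConfig())
        assert fn(GPTree(FeatureRef("s"))) == 1.0

    def test_hand_enumerated_accuracy_on_toy_table(self, toy_table):
        """(- f1 f2) with threshold 0: prediction positive iff f1 >= f2."""
        tree = parse_tree("(- f1 f2)")
        fn = TrainingFitness(toy_table, FSGPConfig())
        # hand enumeration over the 5 rows
        correct = 0
        for row, label in zip(toy_table.values, toy_table.labels):
            pred = 1 if row[0] - row[1] >= 0 else 0
            correct += pred == label
        assert fn(tree) == correct / 5

    def test_counter_increments_per_call(self, toy_table):
        fn = TrainingFitness(toy_table, FSGPConfig())
        tree = parse_tree("f1")
        for expected in (1, 2, 3):
            fn(tree)
            assert fn.evaluations == expected


class TestInitPopulation:
    def test_all_trees_structurally_distinct(self):
        rng = np.random.default_rng(7)
        cfg = FSGPConfig(population_size=100, init_min_depth=5, init_max_depth=10)
        train = FeatureTable(FEATS, np.zeros((4, 6)), np.array([0, 1, 0, 1]))
        pop = init_population(cfg, train, rng)
        serials = {ind.tree.serialize() for ind in pop.individuals}
        assert len(serials) == 100
        assert all(ind.fitness is None for ind in pop.individuals)

    def test_two_terminal_trees_distinct(self):
        rng = np.random.default_rng(8)
        cfg = FSGPConfig(population_size=2, init_min_depth=1, init_max_depth=1,
                         max_tree_depth=1, use_constants=False)
        names = [f"f{i}" for i in range(70)]
        train = FeatureTable(names, np.zeros((2, 70)), np.array([0, 1]))
        pop = init_population(cfg, train, rng)
        a, b = (ind.tree.serialize() for ind in pop.individuals)
        assert a != b

    def test_pigeonhole_diversity_error(self):
        rng = np.random.default_rng(9)
        cfg = FSGPConfig(population_size=5, init_min_depth=1, init_max_depth=1,
                         max_tree_depth=1, use_constants=False)
        train = FeatureTable(["only"], np.zeros((2, 1)), np.array([0, 1]))
        with pytest.raises(DiversityError, match="200"):
            init_population(cfg, train, rng)


class TestTournament:
    def make_pop(self, fitnesses):
        inds = [Individual(GPTree(Constant(float(i))), f)
                for i, f in enumerate(fitnesses)]
        return Population(inds)

    def test_k_equal_size_usually_returns_best(self):
        """k = n with replacement: P(best sampled) = 1 - (2/3)^3 ~ 0.704."""
        pop = self.make_pop([0.3, 0.9, 0.5])
        rng = np.random.default_rng(0)
        wins = sum(tournament_select(pop, 3, rng).fitness == 0.9
                   for _ in range(3000))
        assert abs(wins - 3000 * (1 - (2 / 3) ** 3)) <= 100

    def test_k_one_is_uniform(self):
        pop = self.make_pop([0.1, 0.9])
        rng = np.random.default_rng(1)
        picks = {tournament_select(pop, 1, rng).fitness for _ in range(100)}
        assert picks == {0.1, 0.9}

    def test_selection_probability_matches_closed_form(self):
        """fitnesses {0.9, 0.1}, k=2: P(best) = 1 - (1/2)^2 = 0.75."""
        pop = self.make_pop([0.9, 0.1])
        rng = np.random.default_rng(2)
        wins = sum(tournament_select(pop, 2, rng).fitness == 0.9
                   for _ in range(10000))
        assert abs(wins - 7500) <= 150

    def test_unevaluated_individual_rejected(self):
        pop = Population([Individual(GPTree(Constant(0.0))),
                          Individual(GPTree(Constant(1.0)), 0.5)])
        rng = np.random.default_rng(3)
        with pytest.raises(RuntimeError):
            tournament_select(pop, 2, rng)

    def test_fitness_tie_prefers_smaller_tree(self):
        """Tied fitness: the smaller tree wins whenever it is in the pool.

        With k=2 draws over {big, small}, the small tree misses the pool
        with probability 1/4, so it should win ~75% of draws (a uniform
        tie-break would win only ~50%).
        """
        small = Individual(GPTree(Constant(1.0)), 0.5)
        big = Individual(parse_tree("(+ 1.0 (+ 1.0 1.0))"), 0.5)
        pop = Population([big, small])
        rng = np.random.default_rng(4)
        wins = sum(tournament_select(pop, 2, rng) is small for _ in range(4000))
        assert abs(wins - 3000) <= 110  # ~4 sd of Binomial(4000, 0.75)


def two_feature_table():
    # f0 predicts the label perfectly by sign; f1 is useless
    values = np.array([[1.0, -1.0], [2.0, -1.0], [-1.0, -1.0], [-2.0, -1.0]])
    labels = np.array([1, 1, 0, 0])
    return FeatureTable(["f0", "f1"], values, labels)


class TestHillClimbingOperators:
    def setup_method(self):
        self.table = two_feature_table()
        self.cfg = FSGPConfig(init_min_depth=1, init_max_depth=3,
                              max_tree_depth=6, hc_max_retries=10,
                              use_constants=False)
        self.fn = TrainingFitness(self.table, self.cfg)

    def test_perfect_parents_returned_unchanged(self):
        rng = np.random.default_rng(0)
        a = Individual(parse_tree("f0"), 1.0)
        b = Individual(parse_tree("(+ f0 f0)"), 1.0)
        ra, rb = hc_crossover(a, b, self.cfg, rng, self.fn)
        assert ra is a and rb is b

    def test_zero_retries_is_identity(self):
        cfg = FSGPConfig(hc_max_retries=0, use_constants=False)
        rng = np.random.default_rng(1)
        a = Individual(parse_tree("f1"), 0.5)
        b = Individual(parse_tree("f0"), 1.0)
        ra, rb = hc_crossover(a, b, cfg, rng, self.fn)
        assert ra is a and rb is b
        assert hc_mutation(a, cfg, rng, self.fn, ["f0", "f1"]) is a

    def test_crossover_finds_reachable_improvement(self):
        """Swapping subtrees of (f1) and (f0) can only yield the perfect f0 child."""
        rng = np.random.default_rng(2)
        a = Individual(parse_tree("f1"), self.fn(parse_tree("f1")))
        b = Individual(parse_tree("f0"), 1.0)
        assert a.fitness < 1.0
        ra, _ = hc_crossover(a, b, self.cfg, rng, self.fn)
        assert ra.fitness == 1.0
        assert ra.tree.serialize() == "f0"

    def test_mutation_cannot_improve_perfect_parent(self):
        rng = np.random.default_rng(3)
        parent = Individual(parse_tree("f0"), 1.0)
        assert hc_mutation(parent, self.cfg, rng, self.fn, ["f0", "f1"]) is parent

    def test_mutation_improvement_rate_matches_terminal_odds(self):
        """Single-terminal parent, 2-terminal pool, only f0 improves.

        Each attempt rewrites the lone node with a fresh grow tree; when that
        tree is the single terminal f0 the child is perfect.  With depth-1
        subtrees forced, per-attempt success probability is 1/2, so 3
        retries succeed with p = 1 - (1/2)^3 = 7/8.  1000 seeded trials must
        land near 875.
        """
        cfg = FSGPConfig(init_min_depth=1, init_max_depth=1, max_tree_depth=1,
                         hc_max_retries=3, use_constants=False)
        fn = TrainingFitness(self.table, cfg)
        base = Individual(parse_tree("f1"), fn(parse_tree("f1")))
        rng = np.random.default_rng(4)
        wins = sum(
            hc_mutation(base, cfg, rng, fn, ["f0", "f1"]).fitness == 1.0
            for _ in range(1000)
        )
        assert abs(wins - 875) <= 40  # ~4 sd of Binomial(1000, 7/8)

    def test_depth_cap_respected(self):
        rng = np.random.default_rng(5)
        cfg = FSGPConfig(init_min_depth=1, init_max_depth=3, max_tree_depth=4,
                         hc_max_retries=20, use_constants=False)
        fn = TrainingFitness(self.table, cfg)
        deep = parse_tree("(+ (+ (+ f1 f1) f1) f1)")
        a = Individual(deep, fn(deep))
        b = Individual(parse_tree("(+ (+ (+ f0 f0) f0) f0)"), 1.0)
        for _ in range(20):
            ra, rb = hc_crossover(a, b, cfg, rng, fn)
            assert ra.tree.depth() <= 4 and rb.tree.depth() <= 4


class TestNextGeneration:
    def evaluated_population(self, cfg, seed=0):
        table = two_feature_table()
        fn = TrainingFitness(table, cfg)
        rng = np.random.default_rng(seed)
        pop = init_population(cfg, table, rng)
        for ind in pop.individuals:
            ind.fitness = fn(ind.tree)
        return pop, fn, rng

    def test_size_invariant_and_generation_bump(self, small_config):
        pop, fn, rng = self.evaluated_population(small_config)
        nxt = next_generation(pop, small_config, rng, fn, ["f0", "f1"])
        assert len(nxt) == len(pop)
        assert nxt.generation_index == 1

    def test_best_fitness_never_decreases(self, small_config):
        pop, fn, rng = self.evaluated_population(small_config, seed=3)
        for _ in range(5):
            prev_best = pop.best().fitness
            pop = next_generation(pop, small_config, rng, fn, ["f0", "f1"])
            assert pop.best().fitness >= prev_best

    def test_pure_reproduction_only_copies_existing_individuals(self):
        cfg = FSGPConfig(population_size=10, p_crossover=0.0, p_reproduction=1.0,
                         p_mutation=0.0, init_min_depth=2, init_max_depth=3,
                         tournament_size=10, use_constants=False)
        pop, fn, rng = self.evaluated_population(cfg, seed=4)
        best = pop.best()
        originals = {ind.tree.serialize() for ind in pop.individuals}
        nxt = next_generation(pop, cfg, rng, fn, ["f0", "f1"])
        assert all(ind.tree.serialize() in originals for ind in nxt.individuals)
        assert nxt.best().fitness == best.fitness  # elitism keeps the best

    def test_depth_safety_across_generations(self, small_config):
        pop, fn, rng = self.evaluated_population(small_config, seed=5)
        for _ in range(5):
            pop = next_generation(pop, small_config, rng, fn, ["f0", "f1"])
            assert all(ind.tree.depth() <= small_config.max_tree_depth
                       for ind in pop.individuals)
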