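"""Embedded feature selection inside a single GP life cycle (FSGP).

The idea: while the population evolves, features that keep appearing in
above-average classifiers are probably the informative ones.  During the
first half of the run, every generation's above-mean-fitness individuals
("Cgaa" classifiers) vote for the features they contain — each feature
terminal occurrence adds one to that feature's weight.  At the midpoint the
features split into Fso (weight strictly above the average weight) and Fno
(the rest); a replacement mutation then purges every Fno terminal from every
tree, substituting randomly drawn Fso features and keeping the best variant
found.  Evolution continues on the purged population, whose fresh mutation
subtrees draw terminals from Fso only, so the purge is never undone.  The
features present in the best classifier at the end are the selected set —
feature selection and classification in one GP run.

All replacement-trial evaluations are billed to the same budget as ordinary
fitness evaluations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_model import FeatureTable
from .gp_core import (
    Constant,
    FeatureRef,
    FSGPConfig,
    GPTree,
    Individual,
    Population,
    TrainingFitness,
    init_population,
    next_generation,
    replace_subtree,
    subtree,
    _iter_nodes,
)

__all__ = [
    "FeatureWeightLedger",
    "FeaturePartition",
    "GenerationRecord",
    "FSGPResult",
    "DegenerateLedgerError",
    "select_cgaa",
    "accumulate_weights",
    "partition_features",
    "replace_fno",
    "run_fsgp",
]

log = logging.getLogger("fsgp")


class DegenerateLedgerError(RuntimeError):
    """No above-average classifier ever contributed a feature occurrence."""


@dataclass
class FeatureWeightLedger:
    """Per-feature accumulated occurrence counts over Cgaa classifiers."""

    weights: dict[str, int]
    generations_accumulated: int = 0

    @classmethod
    def empty(cls, feature_names: list[str]) -> "FeatureWeightLedger":
        return cls({name: 0 for name in feature_names})

    def total(self) -> int:
        return sum(self.weights.values())

    def snapshot(self) -> dict[str, int]:
        return dict(self.weights)


@dataclass
class FeaturePartition:
    """Fso = above-average-weight features; Fno = the complement."""

    fso: set[str]
    fno: set[str]


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_so_far: float
    evaluations: int
    diversity: int
    replacement_applied: bool = False


@dataclass
class FSGPResult:
    best: Individual
    selected_features: list[str]
    history: list[GenerationRecord]
    partition: FeaturePartition | None
    ledger: FeatureWeightLedger | None
    total_evaluations: int
    generations_run: int
    terminated_early: bool
    config: FSGPConfig


def select_cgaa(population: Population) -> list[Individual]:
    """Individuals whose fitness is strictly above the population mean.

    Empty when all fitnesses are equal (strict inequality).
    """
    for ind in population.individuals:
        if not ind.evaluated:
            raise RuntimeError("select_cgaa requires a fully evaluated population")
    mean = population.mean_fitness()
    return [ind for ind in population.individuals if ind.fitness > mean]


def accumulate_weights(ledger: FeatureWeightLedger, cgaa: list[Individual],
                       per_tree_presence: bool = False) -> FeatureWeightLedger:
    """Add one generation's Cgaa feature occurrences to the ledger (in place).

    By default a feature occurring twice in one tree adds 2; with
    ``per_tree_presence`` each tree contributes at most 1 per feature.
    Constants contribute nothing.
    """
    for ind in cgaa:
        counts = ind.tree.feature_counts()
        for name, count in counts.items():
            if name not in ledger.weights:
                raise KeyError(f"tree references unknown feature {name!r}")
            ledger.weights[name] += 1 if per_tree_presence else count
    ledger.generations_accumulated += 1
    return ledger


def partition_features(ledger: FeatureWeightLedger,
                       average_over_nonzero: bool = False) -> FeaturePartition:
    """Split features at the average weight: Fso strictly above, Fno the rest.

    The average is taken over the full feature set by default (zero-weight
    features included); ``average_over_nonzero`` restricts the denominator to
    features with positive weight.  If every feature ties (Fso would be
    empty) the maximal-weight features become Fso.
    """
    if ledger.generations_accumulated < 1:
        raise RuntimeError("ledger has accumulated no generations")
    total = ledger.total()
    if total == 0:
        raise DegenerateLedgerError(
            "no feature occurrences accumulated; skip the replacement step"
        )
    if average_over_nonzero:
        denom = sum(1 for w in ledger.weights.values() if w > 0)
    else:
        denom = len(ledger.weights)
    mean = total / denom
    fso = {name for name, w in ledger.weights.items() if w > mean}
    if not fso:
        top = max(ledger.weights.values())
        fso = {name for name, w in ledger.weights.items() if w == top}
    fno = set(ledger.weights) - fso
    return FeaturePartition(fso=fso, fno=fno)


def _fno_positions(tree: GPTree, fno: set[str]) -> list[int]:
    """Prefix-order indices of terminals referencing Fno features."""
    positions = []
    for i, node in enumerate(_iter_nodes(tree.root)):
        if isinstance(node, FeatureRef) and node.name in fno:
            positions.append(i)
    return positions


def replace_fno(individual: Individual, partition: FeaturePartition,
                config: FSGPConfig, rng, fitness_fn) -> Individual:
    """Purge every Fno feature terminal from a tree via replacement mutation.

    Each Fno occurrence is rewritten to a randomly drawn Fso feature; per
    occurrence up to ``hc_max_retries`` draws are evaluated and the first
    strictly-improving one is adopted, else the best-scoring draw.  The Fno
    terminal is replaced regardless, so the returned tree contains no Fno
    references; its fitness reflects a fresh evaluation.
    """
    if not partition.fso:
        raise ValueError("replace_fno requires a non-empty Fso set")
    if not individual.evaluated:
        raise RuntimeError("replace_fno requires an evaluated individual")
    fso = sorted(partition.fso)
    current = individual
    while True:
        positions = _fno_positions(current.tree, partition.fno)
        if not positions:
            return current
        pos = positions[0]
        best_child: Individual | None = None
        for _ in range(max(1, config.hc_max_retries)):
            name = fso[rng.integers(len(fso))]
            candidate = replace_subtree(current.tree, pos, FeatureRef(name))
            f = fitness_fn(candidate)
            if best_child is None or f > best_child.fitness:
                best_child = Individual(candidate, f)
            if f > current.fitness:
                break
        current = best_child


# ---------------------------------------------------------------------------
# Full driver
# ---------------------------------------------------------------------------

def _diversity(population: Population) -> int:
    return len({ind.tree.serialize() for ind in population.individuals})


def run_fsgp(train: FeatureTable, config: FSGPConfig, use_fs: bool = True,
             inspector=None) -> FSGPResult:
    """Run the full FSGP life cycle (or plain GP with ``use_fs=False``).

    Schedule: G = floor(evaluation_budget / population_size) generations —
    the classic generational accounting where one budget unit is one
    individual slot per generation.  The weighting phase covers generations
    1..ceil(G/2); the Fno purge fires once, at generation ceil(G/2); plain
    evolution continues to generation G.  The run stops early the moment
    any individual reaches training accuracy 1.0.

    The hill-climbing operators evaluate candidate children internally;
    those trials are tallied on the run's fitness-call counter
    (``total_evaluations`` reports every actual fitness computation) but
    the generational schedule, not the trial count, is the budget clock —
    otherwise the retry traffic would exhaust the budget long before the
    midpoint and the selection phase could never run.

    ``inspector``, if given, is called after every generation with a dict
    (keys: ``generation``, ``population``, ``cgaa``, ``ledger``,
    ``replacement_applied``) — a read-only hook for auditing runs.

    The result's ``best`` is the best individual seen since the purge
    (the purge re-baselines the population; elitism preserves that best to
    the end), and ``selected_features`` are exactly the distinct features in
    its tree.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fitness_fn = TrainingFitness(train, config)
    budget = config.evaluation_budget
    G = budget // config.population_size
    mid_gen = math.ceil(G / 2)
    feature_pool = list(train.feature_names)

    population = init_population(config, train, rng, feature_pool)
    for ind in population.individuals:
        ind.fitness = fitness_fn(ind.tree)

    ledger = FeatureWeightLedger.empty(train.feature_names) if use_fs else None
    partition: FeaturePartition | None = None
    replaced = not use_fs
    history: list[GenerationRecord] = []
    best_ever = population.best()
    best_so_far = best_ever.fitness

    def record(gen: int, replacement_applied: bool) -> None:
        nonlocal best_ever, best_so_far
        gen_best = population.best()
        if gen_best.fitness > best_ever.fitness:
            best_ever = gen_best
        best_so_far = max(best_so_far, gen_best.fitness)
        history.append(GenerationRecord(
            generation=gen,
            best_fitness=gen_best.fitness,
            mean_fitness=population.mean_fitness(),
            best_so_far=best_so_far,
            evaluations=fitness_fn.evaluations,
            diversity=_diversity(population),
            replacement_applied=replacement_applied,
        ))

    record(0, False)
    if inspector is not None:
        inspector({"generation": 0, "population": population, "cgaa": None,
                   "ledger": ledger, "replacement_applied": False})

    gen = 0
    while gen < G and best_ever.fitness < 1.0:
        population = next_generation(population, config, rng, fitness_fn, feature_pool)
        gen += 1
        cgaa = None
        replacement_applied = False
        if use_fs and not replaced:
            cgaa = select_cgaa(population)
            accumulate_weights(ledger, cgaa, config.per_tree_presence)
            if gen >= mid_gen:
                try:
                    partition = partition_features(ledger, config.average_over_nonzero)
                except DegenerateLedgerError:
                    log.warning(
                        "degenerate feature-weight ledger at generation %d; "
                        "skipping the replacement step (plain GP from here)", gen)
                else:
                    population = Population(
                        [replace_fno(ind, partition, config, rng, fitness_fn)
                         for ind in population.individuals],
                        generation_index=population.generation_index,
                    )
                    feature_pool = sorted(partition.fso)
                    # the purge re-baselines the run: best is tracked from here
                    best_ever = population.best()
                    replacement_applied = True
                replaced = True
        record(gen, replacement_applied)
        if inspector is not None:
            inspector({"generation": gen, "population": population, "cgaa": cgaa,
                       "ledger": ledger, "replacement_applied": replacement_applied})

    terminated_early = best_ever.fitness >= 1.0 and gen < G
    best = Individual(best_ever.tree.copy(), best_ever.fitness)
    return FSGPResult(
        best=best,
        selected_features=best.tree.features(),
        history=history,
        partition=partition,
        ledger=ledger,
        total_evaluations=fitness_fn.evaluations,
        generations_run=gen,
        terminated_early=terminated_early,
        config=config,
    )
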