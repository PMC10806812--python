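"""Genetic algorithm over ligand graphs.

Evolves populations of fragment-space ligands under an arbitrary
fitness callback.  Mutation (substitute / extend / trim a substituent
subtree) and crossover (exchange of subtrees rooted at sites of the
same attachment-point class) operate on the slot-group representation,
so symmetry constraints are preserved by construction.  Evaluations are
cached by canonical key; a not-determinable (ND) fitness ranks below
every numeric fitness, mirroring the discarding of candidates outside a
prediction model's domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .fragments import (
    FragmentSpace,
    FragmentSpaceError,
    LigandGraph,
    Subtree,
    canonical_key,
    enumerate_space,
    prune,
    random_ligand,
    random_subtree,
)
from .prediction import ND

__all__ = [
    "GAConfig",
    "Individual",
    "RunResult",
    "init_population",
    "mutate",
    "crossover",
    "evolve",
    "collect_fittest",
]

Fitness = Callable[[LigandGraph], object]  # float or ND


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    generations: int = 25
    mutation_probability: float = 0.9
    mutation_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)  # sub/extend/trim
    crossover_probability: float = 0.4
    tournament_size: int = 2
    elite_count: int = 1
    seed: int = 0
    duplicate_retry_cap: int = 20

    def __post_init__(self) -> None:
        for p in (self.mutation_probability, self.crossover_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for n in (self.population_size, self.generations, self.tournament_size):
            if n < 1:
                raise ValueError("sizes must be >= 1")
        if self.elite_count < 0 or self.elite_count > self.population_size:
            raise ValueError("elite count must be in [0, population_size]")
        if any(w < 0 for w in self.mutation_weights) or sum(self.mutation_weights) == 0:
            raise ValueError("mutation weights must be non-negative, not all zero")


@dataclass(frozen=True)
class Individual:
    ligand: LigandGraph
    key: str
    fitness: object = None  # float | ND | None before evaluation
    generation: int = 0
    operation: str = "init"
    parents: tuple[str, ...] = ()


def _fitness_sort_key(ind: Individual):
    """ND (and unevaluated) rank below every numeric fitness; ties break
    on the key for determinism."""
    f = ind.fitness
    numeric = isinstance(f, (int, float)) and not (isinstance(f, float) and math.isnan(f))
    return (0 if numeric else 1, -(f if numeric else 0.0), ind.key)


@dataclass
class RunResult:
    config: GAConfig
    snapshots: list[list[Individual]] = field(default_factory=list)
    evaluations: int = 0
    cache: dict[str, object] = field(default_factory=dict)
    best_trajectory: list[object] = field(default_factory=list)

    @property
    def best(self) -> Individual:
        pool = [i for snap in self.snapshots for i in snap]
        return min(pool, key=_fitness_sort_key)


# ---------------------------------------------------------------------- #
# Sites eligible for editing
# ---------------------------------------------------------------------- #


def _assigned_slots(ligand: LigandGraph):
    """(site, ap_class, is_capping) for every assigned slot, where a
    "slot" is a scaffold group (path ()) or any subtree AP."""
    space = ligand.space
    out = []

    def walk(st: Subtree, group: str, path: tuple[int, ...]) -> None:
        frag = space.fragment(st.fragment)
        for ap_index, child in st.children:
            ap_class = frag.aps[ap_index].ap_class
            caps = space.cappings_for(ap_class)
            is_cap = any(c.name == child.fragment for c in caps) and not child.children
            out.append(((group, path + (ap_index,)), ap_class, is_cap))
            walk(child, group, path + (ap_index,))

    for group, st in ligand.assignments:
        if st is None:
            continue
        ap_class = space.group_class(ligand.scaffold, group)
        caps = space.cappings_for(ap_class)
        is_cap = any(c.name == st.fragment for c in caps) and not st.children
        out.append(((group, ()), ap_class, is_cap))
        walk(st, group, ())
    return out


def _replace_subtree(ligand: LigandGraph, site, st: Subtree) -> LigandGraph:
    from .fragments import _install  # shared tree editing

    group, path = site
    if not path:
        return ligand.with_assignment(group, st)
    pruned = prune(ligand, site)
    root = pruned.assignment(group)
    return pruned.with_assignment(group, _install(root, path, st))


# ---------------------------------------------------------------------- #
# Genetic operators
# ---------------------------------------------------------------------- #


def init_population(space: FragmentSpace, n: int, rng) -> list[Individual]:
    """``n`` distinct random ligands; errors if the space is smaller."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    probe = enumerate_space(space, limit=n)
    if not probe.truncated and probe.count < n:
        raise FragmentSpaceError(
            f"space holds only {probe.count} constitutions, {n} requested "
            f"(shortfall {n - probe.count})"
        )
    out: list[Individual] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        lig = random_ligand(space, rng)
        key = canonical_key(lig)
        attempts += 1
        if key in seen:
            if attempts > 200 * n:
                # rare corner: random draws keep colliding; fall back to
                # the deterministic enumeration stream
                for cand in probe.ligands:
                    k = canonical_key(cand)
                    if k not in seen:
                        seen.add(k)
                        out.append(Individual(ligand=cand, key=k))
                        if len(out) == n:
                            break
                break
            continue
        seen.add(key)
        out.append(Individual(ligand=lig, key=key))
    return out


_MUTATION_KINDS = ("substitute", "extend", "trim")


def mutate(
    individual: Individual,
    space: FragmentSpace,
    rng,
    weights: Sequence[float] = (0.6, 0.2, 0.2),
) -> Individual:
    """Mutate one slot; returns a no-change copy when no edit is legal.

    substitute: replace a substituent subtree with a fresh random one;
    extend: replace a capping with a substituent subtree;
    trim: replace a substituent subtree with the default capping.
    The slot is drawn uniformly among those eligible for the kind.
    """
    slots = _assigned_slots(individual.ligand)
    subst_slots = [s for s in slots if not s[2] and space.substituents_for(s[1])]
    cap_slots = [s for s in slots if s[2] and space.substituents_for(s[1])]
    trim_slots = [s for s in slots if not s[2] and space.cappings_for(s[1])]
    eligible = {
        "substitute": subst_slots,
        "extend": cap_slots,
        "trim": trim_slots,
    }
    kinds = [k for k, w in zip(_MUTATION_KINDS, weights) if w > 0 and eligible[k]]
    if not kinds:
        return replace(individual, operation="no-change", parents=(individual.key,))
    w = np.array([weights[_MUTATION_KINDS.index(k)] for k in kinds], float)
    kind = str(rng.choice(kinds, p=w / w.sum()))
    pool = eligible[kind]
    site, ap_class, _is_cap = pool[int(rng.integers(len(pool)))]

    if kind == "trim":
        cap = space.cappings_for(ap_class)[0]
        new_st = Subtree(fragment=cap.name, root_ap=0)
    elif kind == "extend":
        new_st = random_subtree(space, ap_class, rng, p_substituent=1.0)
    else:
        new_st = random_subtree(space, ap_class, rng)
    child = _replace_subtree(individual.ligand, site, new_st)
    child.validate()
    site_tag = site[0] + ("." + ".".join(map(str, site[1])) if site[1] else "")
    return Individual(
        ligand=child,
        key=canonical_key(child),
        operation=f"mutate:{kind}@{site_tag}",
        parents=(individual.key,),
    )


def crossover(
    a: Individual, b: Individual, space: FragmentSpace, rng
) -> tuple[Individual, Individual]:
    """Exchange subtrees rooted at sites of one shared attachment class.

    Returns no-change copies when the parents expose no common class.
    Swapping a scaffold-group slot exchanges the whole (symmetry-shared)
    assignment, so offspring remain symmetry-consistent.
    """
    slots_a = [s for s in _assigned_slots(a.ligand) if not s[2]]
    slots_b = [s for s in _assigned_slots(b.ligand) if not s[2]]
    classes = sorted({c for _s, c, _ in slots_a} & {c for _s, c, _ in slots_b})
    if not classes:
        return (
            replace(a, operation="no-change", parents=(a.key, b.key)),
            replace(b, operation="no-change", parents=(a.key, b.key)),
        )
    cls = str(rng.choice(classes))
    pa = [s for s in slots_a if s[1] == cls]
    pb = [s for s in slots_b if s[1] == cls]
    site_a, _, _ = pa[int(rng.integers(len(pa)))]
    site_b, _, _ = pb[int(rng.integers(len(pb)))]
    st_a = _subtree_at(a.ligand, site_a)
    st_b = _subtree_at(b.ligand, site_b)
    child_a = _replace_subtree(a.ligand, site_a, st_b)
    child_b = _replace_subtree(b.ligand, site_b, st_a)
    child_a.validate()
    child_b.validate()
    return (
        Individual(
            ligand=child_a, key=canonical_key(child_a),
            operation="crossover", parents=(a.key, b.key),
        ),
        Individual(
            ligand=child_b, key=canonical_key(child_b),
            operation="crossover", parents=(a.key, b.key),
        ),
    )


def _subtree_at(ligand: LigandGraph, site) -> Subtree:
    group, path = site
    st = ligand.assignment(group)
    for ap_index in path:
        st = st.child(ap_index)
    return st


# ---------------------------------------------------------------------- #
# Evolution loop
# ---------------------------------------------------------------------- #


class FitnessError(RuntimeError):
    pass


def evolve(space: FragmentSpace, config: GAConfig, fitness: Fitness) -> RunResult:
    """Run the evolutionary loop.

    Tournament selection, elitism, per-population duplicate rejection up
    to the retry cap, and a canonical-key evaluation cache.  The next
    generation is the fittest ``population_size`` of (elites + offspring),
    so with ``elite_count >= 1`` the best-so-far trajectory is monotone.
    One seeded RNG stream is split deterministically per operation.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_init, rng_sel, rng_mut, rng_x = (np.random.default_rng(s) for s in seq.spawn(4))
    result = RunResult(config=config)

    def evaluate(ind: Individual) -> Individual:
        if ind.key in result.cache:
            return replace(ind, fitness=result.cache[ind.key])
        try:
            f = fitness(ind.ligand)
        except Exception as exc:
            raise FitnessError(f"fitness callback failed for {ind.key!r}: {exc}") from exc
        result.cache[ind.key] = f
        result.evaluations += 1
        return replace(ind, fitness=f)

    population = [evaluate(i) for i in init_population(space, config.population_size, rng_init)]
    population.sort(key=_fitness_sort_key)
    result.snapshots.append(population)
    result.best_trajectory.append(population[0].fitness)

    def tournament(pop: list[Individual]) -> Individual:
        picks = [pop[int(rng_sel.integers(len(pop)))] for _ in range(config.tournament_size)]
        return min(picks, key=_fitness_sort_key)

    for gen in range(1, config.generations + 1):
        offspring: list[Individual] = []
        taken = set()
        retries = 0
        while len(offspring) < config.population_size:
            p1 = tournament(population)
            child = p1
            if rng_x.random() < config.crossover_probability:
                p2 = tournament(population)
                child, _sib = crossover(p1, p2, space, rng_x)
            if rng_mut.random() < config.mutation_probability:
                child = mutate(child, space, rng_mut, config.mutation_weights)
            if child.key in taken and retries < config.duplicate_retry_cap:
                retries += 1
                continue
            taken.add(child.key)
            child = replace(child, generation=gen)
            offspring.append(evaluate(child))
        elites = population[: config.elite_count]
        merged: dict[str, Individual] = {}
        for ind in sorted(elites + offspring, key=_fitness_sort_key):
            merged.setdefault(ind.key, ind)
        population = sorted(merged.values(), key=_fitness_sort_key)[: config.population_size]
        result.snapshots.append(population)
        best = population[0].fitness
        result.best_trajectory.append(best)
    return result


# ---------------------------------------------------------------------- #
# Fittest set
# ---------------------------------------------------------------------- #


@dataclass
class FittestSet:
    members: list[Individual]
    requested: int
    shortfall: bool = False


def collect_fittest(runs: Sequence[RunResult], k: int) -> FittestSet:
    """Global top-k across runs after key-deduplication.

    Ties break on (fitness, key) so the output is deterministic; when
    fewer than ``k`` distinct candidates exist, all are returned and the
    shortfall flagged.
    """
    pool: dict[str, Individual] = {}
    for run in runs:
        for snap in run.snapshots:
            for ind in snap:
                cur = pool.get(ind.key)
                if cur is None or _fitness_sort_key(ind) < _fitness_sort_key(cur):
                    pool[ind.key] = ind
    ranked = sorted(pool.values(), key=_fitness_sort_key)
    return FittestSet(members=ranked[:k], requested=k, shortfall=len(ranked) < k)
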