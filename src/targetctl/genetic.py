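"""Genetic search over per-target input assignments.

A chromosome assigns each target one input node drawn from the target's
backward-reachable ancestors within the path-length cap ``L``.  Decoding
builds one shortest walk per (input, target) pair and scores the layer
condition: the number of residual node/layer conflicts after a single
repair pass (re-routing a conflicting path through the next feasible walk
length).  Fitness is the lexicographic triple

    (conflicts ascending, |I| ascending, |I ∩ S| descending)

so any feasible assignment dominates every infeasible one, smaller input
sets dominate larger ones, and preferred (drug-targetable) inputs break
the remaining ties.  Infeasible chromosomes stay in the population, graded
by conflict count, which keeps the search space connected.

The population is seeded half at random and half from greedy solutions,
then evolved by tournament selection, uniform crossover, per-gene
mutation and elitism until the generation cap or a stagnation limit.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .greedy import GreedyParams, greedy_once
from .model import (
    ControlPath,
    ControlProblem,
    ControlSolution,
    check_path_compatibility,
    predecessor_map,
    successor_map,
)

__all__ = [
    "GAParams",
    "GAResult",
    "ancestors_within",
    "build_walk",
    "decode",
    "fitness",
    "ga_control",
]


@dataclass(frozen=True)
class GAParams:
    population_size: int = 100
    elite_fraction: float = 0.1
    mutation_rate: float = 0.05
    tournament_size: int = 3
    max_generations: int = 200
    stagnation_limit: int = 50
    max_solutions: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


Chromosome = tuple[tuple[str, str], ...]
"""Sorted tuple of (target, chosen input) pairs — hashable gene map."""


@functools.lru_cache(maxsize=4096)
def ancestors_within(
    network, target: str, L: int
) -> dict[str, frozenset[int]]:
    """Backward-reachability layers: node -> {d <= L : some walk node->target of length d}.

    Computed by iterating predecessor sets: ``reach[0] = {target}`` and
    ``reach[d]`` = predecessors of ``reach[d-1]``; a node's feasible layer
    set collects every depth at which it appears (walks, not simple paths,
    so cycles contribute periodic layers).
    """
    if target not in network.nodes:
        raise ValueError(f"target {target!r} not in network")
    if L < 0:
        raise ValueError("L must be >= 0")
    pred = predecessor_map(network)
    layers: dict[str, set[int]] = {target: {0}}
    frontier = {target}
    for d in range(1, L + 1):
        nxt = {u for v in frontier for u in pred[v]}
        for u in nxt:
            layers.setdefault(u, set()).add(d)
        frontier = nxt
        if not frontier:
            break
    return {u: frozenset(ds) for u, ds in layers.items()}


@functools.lru_cache(maxsize=65536)
def build_walk(network, source: str, target: str, length: int) -> ControlPath:
    """The canonical walk source -> target of exactly ``length`` steps.

    At each step the lexicographically smallest successor that still admits
    a walk of the remaining length is chosen, so the result is unique and
    deterministic.  Raises if no such walk exists.
    """
    layers = ancestors_within(network, target, length)
    if length not in layers.get(source, frozenset()):
        raise ValueError(f"no walk of length {length} from {source!r} to {target!r}")
    succ = successor_map(network)
    walk = [source]
    node, remaining = source, length
    while remaining > 0:
        for w in succ[node]:  # sorted: smallest id wins
            if (remaining - 1) in layers.get(w, frozenset()):
                walk.append(w)
                node, remaining = w, remaining - 1
                break
        else:  # pragma: no cover - contradicts the feasibility precondition
            raise RuntimeError("walk construction failed despite feasible layer")
    return ControlPath(tuple(walk))


def _gene_pool(problem: ControlProblem, target: str) -> list[str]:
    anc = ancestors_within(problem.network, target, problem.max_path_length)
    pool = sorted(anc)
    if not problem.allow_self_inputs:
        pool = [u for u in pool if u != target]
    return pool


def decode(
    chromosome: Chromosome, problem: ControlProblem
) -> Union[ControlSolution, int]:
    """Decode a gene map into a solution, or the residual conflict count.

    Each target gets the shortest canonical walk from its gene node; if the
    layer condition fails, one repair pass re-routes each conflicting path
    through its gene's next-larger feasible walk length.  Returns the
    :class:`ControlSolution` when conflict-free, else the number of
    remaining conflicts (an ``int`` >= 1).
    """
    net = problem.network
    L = problem.max_path_length
    genes = dict(chromosome)
    paths: dict[str, ControlPath] = {}
    feas: dict[str, list[int]] = {}
    for target in sorted(problem.targets):
        g = genes[target]
        anc = ancestors_within(net, target, L)
        if g not in anc:
            raise ValueError(f"gene {g!r} is not an ancestor of target {target!r} within L={L}")
        feas[target] = sorted(anc[g])
        paths[target] = build_walk(net, g, target, feas[target][0])

    def conflicts_of(pths: dict[str, ControlPath]) -> list:
        sol = ControlSolution(problem, tuple(pths[t] for t in sorted(pths)))
        return check_path_compatibility(sol)

    confs = conflicts_of(paths)
    if confs:
        # one repair pass: bump each conflicting path to its next feasible length
        conflicted = sorted({t for c in confs for t in c.targets})
        for target in conflicted:
            used = paths[target].length
            later = [d for d in feas[target] if d > used]
            if not later:
                continue
            trial = dict(paths)
            trial[target] = build_walk(net, genes[target], target, later[0])
            if len(conflicts_of(trial)) < len(confs):
                paths = trial
                confs = conflicts_of(paths)
                if not confs:
                    break
    if confs:
        return len(confs)
    return ControlSolution(problem, tuple(paths[t] for t in sorted(paths)))


def fitness(
    decoded: Union[ControlSolution, int], problem: ControlProblem
) -> tuple[int, int, int]:
    """Lexicographic score, smaller is better; infeasibles rank below all feasibles."""
    if isinstance(decoded, int):
        return (decoded, len(problem.targets) + len(problem.network.nodes), 0)
    return (0, len(decoded.inputs), -len(decoded.preferred_inputs))


@dataclass
class GAResult:
    """Outcome of :func:`ga_control`."""

    solutions: list[ControlSolution]
    best_history: list[tuple[int, int, int]] = field(default_factory=list)
    generations: int = 0

    @property
    def controllable(self) -> bool:
        return bool(self.solutions)


def ga_control(problem: ControlProblem, params: GAParams = GAParams()) -> GAResult:
    """Evolve input assignments; returns de-duplicated feasible solutions.

    An empty ``solutions`` list signals that no feasible assignment was
    found — "uncontrollable under constraints", not an exception.
    Reproducible: identical seeds give identical populations.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    targets = sorted(problem.targets)
    pools = {t: _gene_pool(problem, t) for t in targets}
    if any(not pool for pool in pools.values()):
        # a target with no admissible input: uncontrollable under constraints
        return GAResult(solutions=[], best_history=[], generations=0)

    def random_chromosome() -> Chromosome:
        return tuple((t, pools[t][rng.integers(len(pools[t]))]) for t in targets)

    # Half random, half seeded from greedy passes (when greedy paths respect
    # the gene constraint, which they do by construction).
    population: list[Chromosome] = []
    n_seeded = params.population_size // 2
    greedy_streams = np.random.SeedSequence(params.rng_seed + 1).spawn(max(n_seeded, 1))
    for ss in greedy_streams[:n_seeded]:
        sol = greedy_once(problem, GreedyParams(), np.random.default_rng(ss))
        genes = []
        ok = True
        for path in sorted(sol.paths, key=lambda p: p.target):
            if path.input not in pools[path.target]:
                ok = False
                break
            genes.append((path.target, path.input))
        population.append(tuple(genes) if ok else random_chromosome())
    while len(population) < params.population_size:
        population.append(random_chromosome())

    decode_cache: dict[Chromosome, Union[ControlSolution, int]] = {}

    def eval_chrom(ch: Chromosome) -> tuple[tuple[int, int, int], Union[ControlSolution, int]]:
        if ch not in decode_cache:
            decode_cache[ch] = decode(ch, problem)
        d = decode_cache[ch]
        return fitness(d, problem), d

    archive: dict[frozenset[str], ControlSolution] = {}
    best_history: list[tuple[int, int, int]] = []
    best_fit: Optional[tuple[int, int, int]] = None
    stagnant = 0
    n_elite = max(1, int(params.elite_fraction * params.population_size))
    generations = 0

    for gen in range(params.max_generations):
        generations = gen + 1
        scored = []
        for ch in population:
            fit, d = eval_chrom(ch)
            scored.append((fit, ch))
            if isinstance(d, ControlSolution):
                key = d.inputs
                if key not in archive or d.sort_key() < archive[key].sort_key():
                    archive[key] = d
        scored.sort(key=lambda x: (x[0], x[1]))
        gen_best = scored[0][0]
        best_history.append(gen_best if best_fit is None else min(best_fit, gen_best))
        if best_fit is None or gen_best < best_fit:
            best_fit = gen_best
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= params.stagnation_limit:
            break

        def tournament() -> Chromosome:
            picks = rng.integers(len(scored), size=params.tournament_size)
            return min((scored[i] for i in picks), key=lambda x: (x[0], x[1]))[1]

        next_pop = [ch for _, ch in scored[:n_elite]]
        while len(next_pop) < params.population_size:
            pa, pb = dict(tournament()), dict(tournament())
            mask = rng.random(len(targets))
            child = []
            for i, t in enumerate(targets):
                g = pa[t] if mask[i] < 0.5 else pb[t]
                if rng.random() < params.mutation_rate:
                    g = pools[t][rng.integers(len(pools[t]))]
                child.append((t, g))
            next_pop.append(tuple(child))
        population = next_pop

    ranked = sorted(archive.values(), key=lambda s: s.sort_key())
    return GAResult(
        solutions=ranked[: params.max_solutions],
        best_history=best_history,
        generations=generations,
    )
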