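"""Core domain types for structural target controllability.

The dynamics behind every operation in this package are the usual linear
time-invariant system dx/dt = A x + B u on a directed network: ``A[i][j]``
is generically nonzero iff the edge ``j -> i`` exists, and ``B`` has one
unit column per input (driver) node.  A *control path* is a directed walk
from an input node to a target; a set of paths, one per target, certifies
generic controllability of the target rows whenever no node is occupied by
two different paths at the same backward distance from their respective
targets (the layer condition).  This module holds the data model and that
compatibility check; the solvers and the rank oracle live elsewhere.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DirectedNetwork",
    "ControlProblem",
    "ControlPath",
    "ControlSolution",
    "GenerationRequest",
    "ValidationReport",
    "Conflict",
    "validate_problem",
    "check_path_compatibility",
    "predecessor_map",
    "successor_map",
]


def _clean_id(node: str) -> str:
    if not isinstance(node, str):
        raise TypeError(f"node identifier must be a string, got {type(node).__name__}")
    stripped = node.strip()
    if not stripped:
        raise ValueError("node identifier must be a non-empty string")
    return stripped


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed graph over opaque string node identifiers.

    ``edges`` is a set of ordered pairs ``(source, target)``; parallel
    duplicates collapse, self-loops are permitted.  Instances are immutable
    and hashable, so adjacency maps are memoised at module level.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for n in self.nodes:
            if not isinstance(n, str) or n != n.strip() or not n:
                raise ValueError(f"invalid node identifier: {n!r}")
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint outside the node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "DirectedNetwork":
        """Build a network from an edge iterable, adding isolated ``extra_nodes``."""
        cleaned = frozenset((_clean_id(u), _clean_id(v)) for u, v in edges)
        nodes = frozenset(n for e in cleaned for n in e) | frozenset(
            _clean_id(n) for n in extra_nodes
        )
        return cls(nodes=nodes, edges=cleaned)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges


@functools.lru_cache(maxsize=256)
def predecessor_map(network: DirectedNetwork) -> Mapping[str, tuple[str, ...]]:
    """Node -> sorted tuple of predecessors (u such that u -> v exists)."""
    pred: dict[str, list[str]] = {n: [] for n in network.nodes}
    for u, v in network.edges:
        pred[v].append(u)
    return {n: tuple(sorted(ps)) for n, ps in pred.items()}


@functools.lru_cache(maxsize=256)
def successor_map(network: DirectedNetwork) -> Mapping[str, tuple[str, ...]]:
    """Node -> sorted tuple of successors (v such that u -> v exists)."""
    succ: dict[str, list[str]] = {n: [] for n in network.nodes}
    for u, v in network.edges:
        succ[u].append(v)
    return {n: tuple(sorted(ss)) for n, ss in succ.items()}


@dataclass(frozen=True)
class ControlProblem:
    """A target-controllability instance.

    Parameters
    ----------
    network:
        The directed interaction network (state space of the dynamics).
    targets:
        Nonempty set ``T`` of nodes whose states must be steerable.
    preferred_sources:
        Possibly empty set ``S`` of nodes preferred as inputs (e.g. drug
        targetable proteins); solutions are ranked by ``(|I|, -|I ∩ S|)``.
    max_path_length:
        Cap ``L >= 1`` on the number of backward extension layers, i.e. on
        the length of any control path.
    allow_self_inputs:
        Whether a target may act as its own input via a length-0 path.
    """

    network: DirectedNetwork
    targets: frozenset[str]
    preferred_sources: frozenset[str] = frozenset()
    max_path_length: int = 10
    allow_self_inputs: bool = True

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("target set must be nonempty")
        unknown_t = self.targets - self.network.nodes
        if unknown_t:
            raise ValueError(f"targets not in network: {sorted(unknown_t)}")
        unknown_s = self.preferred_sources - self.network.nodes
        if unknown_s:
            raise ValueError(f"preferred sources not in network: {sorted(unknown_s)}")
        if self.max_path_length < 1:
            raise ValueError("max_path_length must be >= 1")


@dataclass(frozen=True)
class ControlPath:
    """A directed walk ``u_0 -> u_1 -> ... -> u_m`` with ``u_m`` the target.

    The *backward layer* of ``u_i`` is ``m - i``: the target sits at layer 0
    and the input ``u_0`` at layer ``m``.  Node repeats within one walk are
    allowed (they occur at different layers).
    """

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a control path has at least one node")

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def input(self) -> str:
        return self.nodes[0]

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    def layer_of_index(self, i: int) -> int:
        return self.length - i

    def occupancy(self) -> Iterable[tuple[str, int]]:
        """Yield ``(node, backward layer)`` for every position on the walk."""
        m = self.length
        for i, n in enumerate(self.nodes):
            yield n, m - i

    def validate_steps(self, network: DirectedNetwork) -> None:
        """Raise if any consecutive pair is not an edge of ``network``."""
        for u, v in zip(self.nodes, self.nodes[1:]):
            if (u, v) not in network.edges:
                raise ValueError(f"path step {u!r} -> {v!r} is not an edge of the network")


@dataclass(frozen=True)
class ControlSolution:
    """One control path per target; valid iff the layer condition holds."""

    problem: ControlProblem
    paths: tuple[ControlPath, ...]

    def __post_init__(self) -> None:
        covered = [p.target for p in self.paths]
        if len(set(covered)) != len(covered):
            raise ValueError("each target must be covered by exactly one path")
        if set(covered) != set(self.problem.targets):
            missing = self.problem.targets - set(covered)
            extra = set(covered) - self.problem.targets
            raise ValueError(
                f"path targets do not match problem targets (missing {sorted(missing)}, extra {sorted(extra)})"
            )

    @property
    def inputs(self) -> frozenset[str]:
        return frozenset(p.input for p in self.paths)

    @property
    def preferred_inputs(self) -> frozenset[str]:
        return self.inputs & self.problem.preferred_sources

    @property
    def objective(self) -> tuple[int, int]:
        """Lexicographic objective: smaller is better."""
        return (len(self.inputs), -len(self.preferred_inputs))

    def sort_key(self) -> tuple[int, int, tuple[str, ...]]:
        return (*self.objective, tuple(sorted(self.inputs)))


@dataclass(frozen=True)
class GenerationRequest:
    """Request to carve a subnetwork out of a full interaction universe.

    ``mode`` selects the construction: *neighbors* keeps every interaction
    touching a seed, *direct* keeps seed-to-seed interactions only, and
    *gap* keeps interactions lying on a directed seed-to-seed walk with at
    most ``k`` intermediary (non-seed) nodes, ``0 <= k <= 4``.
    """

    interactions: DirectedNetwork
    seeds: frozenset[str]
    mode: str = "neighbors"
    k: int = 1

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seed set must be nonempty")
        if self.mode not in ("neighbors", "direct", "gap"):
            raise ValueError(f"unknown generation mode: {self.mode!r}")
        if self.mode == "gap" and not (0 <= self.k <= 4):
            raise ValueError("gap mode requires 0 <= k <= 4 intermediaries")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_problem`.

    ``unknown_targets`` and ``unknown_sources`` are identifier-resolution
    errors; ``only_self_controllable`` lists targets with in-degree 0, which
    can only ever be controlled by driving them directly.
    """

    unknown_targets: list[str] = field(default_factory=list)
    unknown_sources: list[str] = field(default_factory=list)
    only_self_controllable: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unknown_targets and not self.unknown_sources

    @property
    def is_empty(self) -> bool:
        return self.ok and not self.only_self_controllable


def validate_problem(
    network: DirectedNetwork,
    targets: Iterable[str],
    preferred_sources: Iterable[str] = (),
) -> ValidationReport:
    """Check identifier resolution and flag structurally isolated targets.

    Unlike the :class:`ControlProblem` constructor (which rejects unknown
    identifiers outright), this reports them, so loaders can warn-and-drop.
    An empty target set is a hard error.
    """
    targets = set(targets)
    sources = set(preferred_sources)
    if not targets:
        raise ValueError("target set must be nonempty")
    report = ValidationReport(
        unknown_targets=sorted(targets - network.nodes),
        unknown_sources=sorted(sources - network.nodes),
    )
    pred = predecessor_map(network)
    report.only_self_controllable = sorted(
        t for t in targets & network.nodes if not pred[t]
    )
    return report


@dataclass(frozen=True)
class Conflict:
    """Two paths occupying ``node`` at the same backward ``layer``."""

    node: str
    layer: int
    targets: tuple[str, str]  # the two paths, identified by their targets


def check_path_compatibility(solution: ControlSolution) -> list[Conflict]:
    """Return every violation of the layer condition, deterministically ordered.

    The layer condition: no node may be occupied by two *distinct* paths at
    the same backward layer.  (One input node may start several paths only
    if their lengths all differ.)  An empty list certifies the solution; the
    rank oracle provides the independent ground truth for that claim.
    """
    for p in solution.paths:
        p.validate_steps(solution.problem.network)

    occupants: dict[tuple[str, int], list[str]] = {}
    for p in solution.paths:
        for node, layer in set(p.occupancy()):
            occupants.setdefault((node, layer), []).append(p.target)

    conflicts = []
    for (node, layer), tgts in occupants.items():
        if len(tgts) > 1:
            tgts = sorted(tgts)
            for i in range(len(tgts)):
                for j in range(i + 1, len(tgts)):
                    conflicts.append(Conflict(node, layer, (tgts[i], tgts[j])))
    conflicts.sort(key=lambda c: (c.node, c.layer, c.targets))
    return conflicts
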