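"""Deterministic fixtures and random digraph generators.

Everything the other modules need for testing is generated here, with no
external data: named toy instances whose optimal driver sets are known in
closed form, Erdős–Rényi directed graphs, and a preferential-attachment
growth model whose heavy-tailed in-degrees crudely emulate the hub
structure of protein-protein interaction networks (no claim of matching
any curated interactome's topology).
"""

from __future__ import annotations

import numpy as np

from .model import ControlProblem, DirectedNetwork

__all__ = ["toy_fixture", "random_digraph", "sample_problem", "TOY_NAMES"]

TOY_NAMES = ("chain", "star", "diamond", "unequal", "cycle")

_TOYS: dict[str, tuple[tuple[tuple[str, str], ...], tuple[str, ...]]] = {
    # name -> (edges, targets)
    "chain": ((("a", "b"), ("b", "c")), ("b", "c")),
    "star": ((("a", "b"), ("a", "c")), ("b", "c")),
    "diamond": ((("u", "x"), ("x", "t1"), ("u", "y"), ("y", "t2")), ("t1", "t2")),
    "unequal": ((("u", "t1"), ("u", "x"), ("x", "t2")), ("t1", "t2")),
    "cycle": ((("a", "b"), ("b", "a")), ("a", "b")),
}


def toy_fixture(name: str, max_path_length: int = 10) -> tuple[DirectedNetwork, ControlProblem]:
    """Return one of the named toy instances used throughout the test suite.

    * ``chain``   a→b→c,               T={b,c}: one input {a} suffices.
    * ``star``    a→b, a→c,            T={b,c}: two inputs are necessary.
    * ``diamond`` u→x→t1, u→y→t2,      T={t1,t2}: two inputs are necessary.
    * ``unequal`` u→t1, u→x→t2,        T={t1,t2}: {u} suffices (path lengths differ).
    * ``cycle``   a→b→a,               T={a,b}.
    """
    if name not in _TOYS:
        raise ValueError(f"unknown fixture {name!r}; choose from {TOY_NAMES}")
    edges, targets = _TOYS[name]
    net = DirectedNetwork.from_edges(edges)
    problem = ControlProblem(
        network=net, targets=frozenset(targets), max_path_length=max_path_length
    )
    return net, problem


def random_digraph(
    n: int, model: str, param: float, rng_seed: int = 0
) -> DirectedNetwork:
    """Seed-deterministic random directed graph.

    ``model='er'``: every ordered pair (u != v) is an edge independently
    with probability ``param`` (no self-loops).

    ``model='pa'``: preferential attachment — start from ``max(2, param)``
    isolated core nodes; each subsequent node sends ``param`` directed
    edges to distinct existing nodes sampled proportionally to
    in-degree + 1, giving ``param * (n - max(2, param))`` edges in total.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    names = [f"n{i:04d}" for i in range(n)]
    if model == "er":
        if not 0.0 <= param <= 1.0:
            raise ValueError("er edge probability must be in [0, 1]")
        edges = []
        mask = rng.random((n, n)) < param
        np.fill_diagonal(mask, False)
        us, vs = np.nonzero(mask)
        edges = [(names[u], names[v]) for u, v in zip(us, vs)]
        return DirectedNetwork.from_edges(edges, extra_nodes=names)
    if model == "pa":
        m = int(param)
        if m < 1 or m != param:
            raise ValueError("pa out-degree must be a positive integer")
        core = max(2, m)
        if n <= core:
            raise ValueError(f"pa model needs n > {core} for param={m}")
        # repeated-node list: node i appears in-degree(i)+1 times
        attachment = list(range(core))
        in_deg = [0] * n
        edges = []
        for new in range(core, n):
            chosen: set[int] = set()
            while len(chosen) < m:
                chosen.add(attachment[rng.integers(len(attachment))])
            for tgt in sorted(chosen):
                edges.append((names[new], names[tgt]))
                in_deg[tgt] += 1
                attachment.append(tgt)
            attachment.append(new)
        return DirectedNetwork.from_edges(edges, extra_nodes=names)
    raise ValueError(f"unknown model {model!r}; choose 'er' or 'pa'")


def sample_problem(
    network: DirectedNetwork,
    n_targets: int,
    n_preferred: int = 0,
    rng_seed: int = 0,
    max_path_length: int = 10,
) -> ControlProblem:
    """Uniformly sample targets, then preferred sources from the rest."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_targets > network.n_nodes:
        raise ValueError("n_targets exceeds the number of nodes")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    nodes = sorted(network.nodes)
    targets = rng.choice(nodes, size=n_targets, replace=False)
    remaining = sorted(set(nodes) - set(targets))
    n_preferred = min(n_preferred, len(remaining))
    preferred = (
        rng.choice(remaining, size=n_preferred, replace=False) if n_preferred else []
    )
    return ControlProblem(
        network=network,
        targets=frozenset(str(t) for t in targets),
        preferred_sources=frozenset(str(s) for s in preferred),
        max_path_length=max_path_length,
    )
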