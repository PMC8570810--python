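"""Seed-based subnetwork extraction from a directed interaction universe.

Three constructions are supported, mirroring how interaction subnetworks
are typically carved out around a set of seed proteins of interest:

* ``neighbors`` — every interaction with at least one seed endpoint;
* ``direct``    — interactions with both endpoints in the seed set;
* ``gap(k)``    — interactions lying on a directed walk between seeds with
  at most ``k`` intermediary (non-seed) nodes, 0 <= k <= 4.

gap(k) is computed by the distance sandwich: with ``d_out(x)`` the minimum
BFS distance from any seed to ``x`` and ``d_in(x)`` the minimum distance
from ``x`` to any seed, an edge ``(u, v)`` is kept iff
``d_out(u) + 1 + d_in(v) <= k + 1``.  The seed-to-seed walk may start and
end at the same seed, so cycles through a single seed qualify.  gap(0) is
exactly ``direct``.
"""

from __future__ import annotations

import logging

import networkx as nx

from .model import DirectedNetwork, GenerationRequest

__all__ = ["generate_network"]

logger = logging.getLogger(__name__)


def _to_digraph(network: DirectedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges)
    return g


def generate_network(request: GenerationRequest) -> DirectedNetwork:
    """Build the subnetwork around ``request.seeds`` per ``request.mode``.

    Seeds absent from the interaction universe are logged and ignored (not
    fatal).  The result's node set consists exactly of the endpoints of the
    kept edges: seeds that end up incident to no kept edge are dropped.
    """
    universe = request.interactions
    seeds = request.seeds & universe.nodes
    missing = request.seeds - universe.nodes
    if missing:
        logger.warning(
            "%d seed id(s) absent from the interaction universe: %s",
            len(missing),
            ", ".join(sorted(missing)),
        )

    if request.mode == "neighbors":
        kept = {e for e in universe.edges if e[0] in seeds or e[1] in seeds}
    elif request.mode == "direct":
        kept = {e for e in universe.edges if e[0] in seeds and e[1] in seeds}
    else:  # gap(k)
        kept = _gap_edges(universe, seeds, request.k)

    return DirectedNetwork.from_edges(kept)


def _gap_edges(
    universe: DirectedNetwork, seeds: set[str] | frozenset[str], k: int
) -> set[tuple[str, str]]:
    if not seeds:
        return set()
    g = _to_digraph(universe)
    # d_out: distance seed -> x in g; d_in: distance x -> seed, i.e. BFS on the reverse.
    d_out = nx.multi_source_dijkstra_path_length(g, seeds, weight=None)
    d_in = nx.multi_source_dijkstra_path_length(g.reverse(copy=False), seeds, weight=None)
    budget = k + 1
    return {
        (u, v)
        for u, v in universe.edges
        if u in d_out and v in d_in and d_out[u] + 1 + d_in[v] <= budget
    }
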