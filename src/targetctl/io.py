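"""Readers and writers for networks, node sets and solution JSON.

File conventions (the directed-edge orientation is "first column drives
second column" throughout):

* edge-list TSV — two tab-separated identifier columns per line, ``#``
  comment lines skipped, duplicate edges collapsed;
* SIF — three whitespace-separated columns ``source relation target``;
  the relation label is read and ignored by the control semantics;
* node sets — one identifier per line, trimmed, blanks and ``#`` comments
  skipped;
* solutions — versioned JSON with per-solution inputs (each flagged
  ``is_preferred`` when it belongs to the preferred-source set), explicit
  control paths, and the objective.  Output is byte-stable for identical
  runs: keys are sorted and no timestamps are embedded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import ControlPath, ControlProblem, ControlSolution, DirectedNetwork

__all__ = [
    "read_network",
    "write_network",
    "read_node_set",
    "write_solutions",
    "read_solutions",
    "SOLUTION_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

SOLUTION_SCHEMA_VERSION = 1


def _data_lines(path: Union[str, Path]) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(
    path: Union[str, Path],
    format: str = "tsv",
    undirected_as_bidirectional: bool = False,
) -> DirectedNetwork:
    """Read a directed network from edge-list TSV or SIF.

    ``undirected_as_bidirectional`` adds the reverse of every edge, for
    interaction files that record undirected binary interactions.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t") if format == "tsv" else line.split()
        if format == "tsv" and len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        if format == "sif" and len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'source relation target'")
        u = cols[0]
        v = cols[1] if format == "tsv" else cols[2]
        edges.append((u, v))
        if undirected_as_bidirectional:
            edges.append((v, u))
    if not edges:
        raise ValueError(f"{path}: no interactions found (empty network)")
    return DirectedNetwork.from_edges(edges)


def write_network(
    network: DirectedNetwork, path: Union[str, Path], format: str = "tsv"
) -> None:
    """Write a network as edge-list TSV or SIF (relation label ``interacts``)."""
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n" if format == "tsv" else f"{u} interacts {v}\n")


def read_node_set(path: Union[str, Path]) -> frozenset[str]:
    """Read a newline-delimited identifier set (deduplicated)."""
    ids = frozenset(line for _, line in _data_lines(path))
    if not ids:
        raise ValueError(f"{path}: no identifiers found")
    return ids


def filter_known(
    ids: frozenset[str], network: DirectedNetwork, what: str, strict: bool = False
) -> frozenset[str]:
    """Drop (or, with ``strict``, reject) identifiers absent from the network."""
    unknown = ids - network.nodes
    if unknown:
        msg = f"{len(unknown)} {what} id(s) not in the network: {', '.join(sorted(unknown))}"
        if strict:
            raise ValueError(msg)
        logger.warning("%s (dropped)", msg)
    return ids & network.nodes


def write_solutions(
    solutions: Sequence[ControlSolution],
    path: Union[str, Path],
    parameters: Optional[dict] = None,
) -> None:
    """Serialize solutions to versioned JSON (deterministic byte output)."""
    if not solutions:
        raise ValueError("no solutions to write")
    problem = solutions[0].problem
    doc = {
        "schema_version": SOLUTION_SCHEMA_VERSION,
        "objective": "(|inputs| ascending, |preferred inputs| descending)",
        "problem": {
            "targets": sorted(problem.targets),
            "preferred_sources": sorted(problem.preferred_sources),
            "max_path_length": problem.max_path_length,
            "allow_self_inputs": problem.allow_self_inputs,
        },
        "parameters": parameters or {},
        "solutions": [
            {
                "inputs": [
                    {"id": i, "is_preferred": i in sol.preferred_inputs}
                    for i in sorted(sol.inputs)
                ],
                "paths": [
                    {"target": p.target, "input": p.input, "nodes": list(p.nodes)}
                    for p in sorted(sol.paths, key=lambda p: p.target)
                ],
                "objective": list(sol.objective),
            }
            for sol in solutions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_solutions(
    path: Union[str, Path], network: DirectedNetwork
) -> list[ControlSolution]:
    """Rebuild :class:`ControlSolution` objects from a solution JSON file.

    The problem is reconstructed from the file's embedded targets, sources
    and path-length cap, against the supplied network.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SOLUTION_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported solution schema version")
    meta = doc["problem"]
    problem = ControlProblem(
        network=network,
        targets=frozenset(meta["targets"]),
        preferred_sources=frozenset(meta["preferred_sources"]),
        max_path_length=meta["max_path_length"],
        allow_self_inputs=meta.get("allow_self_inputs", True),
    )
    return [
        ControlSolution(
            problem,
            tuple(ControlPath(tuple(p["nodes"])) for p in entry["paths"]),
        )
        for entry in doc["solutions"]
    ]
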