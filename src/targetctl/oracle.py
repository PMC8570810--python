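"""Ground-truth verification of target controllability by generic rank.

For linear dynamics dx/dt = A x + B u on a directed network, the target
rows T are controllable iff the rows T of the Kalman matrix
``[B, AB, A^2 B, ..., A^(n-1) B]`` have rank |T|.  Structural (generic)
controllability asks whether this holds for almost every assignment of
nonzero weights to the edges of A.  We test it exactly: edge weights are
drawn uniformly from the nonzero residues of a large prime field GF(p) and
the rank is computed by modular Gaussian elimination, so there is no
floating-point rank threshold to tune.  By the Schwartz-Zippel lemma a
random draw underestimates the generic rank with probability at most
n^2 / p; taking the maximum over a few independent draws makes a false
negative negligible.

Convention fixed project-wide: ``A[i][j]`` is nonzero iff the edge
``j -> i`` exists (column = interaction source, row = interaction target).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .model import DirectedNetwork

__all__ = [
    "RankTestParams",
    "target_generic_rank",
    "is_controllable",
    "brute_force_minimum_inputs",
    "UNCONTROLLABLE",
]

#: Sentinel minimum size returned when no input subset achieves full target rank.
UNCONTROLLABLE = math.inf


@dataclass(frozen=True)
class RankTestParams:
    """Parameters of the randomized exact rank test.

    ``prime`` is the field modulus (must exceed ``|nodes|**2`` for the
    Schwartz-Zippel bound to bite); ``draws`` independent weight
    assignments are tried and the maximum rank kept.
    """

    prime: int = 2_147_483_647
    draws: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.prime < 5:
            raise ValueError("prime too small")


def _matmul_mod(a: np.ndarray, b: np.ndarray, p: int) -> np.ndarray:
    """(a @ b) mod p without int64 overflow, via a 16-bit hi/lo split of a."""
    a_hi, a_lo = np.divmod(a, 1 << 16)
    return ((a_hi @ b % p) * ((1 << 16) % p) + a_lo @ b) % p


def _rank_mod(mat: np.ndarray, p: int) -> int:
    """Rank of an integer matrix over GF(p) by Gaussian elimination."""
    m = mat % p
    rows, cols = m.shape
    rank = 0
    for col in range(cols):
        if rank == rows:
            break
        pivots = np.nonzero(m[rank:, col])[0]
        if pivots.size == 0:
            continue
        piv = rank + pivots[0]
        if piv != rank:
            m[[rank, piv]] = m[[piv, rank]]
        inv = pow(int(m[rank, col]), p - 2, p)
        m[rank] = m[rank] * inv % p
        factors = m[:, col].copy()
        factors[rank] = 0
        # factor * pivot-row stays below p^2 < 2^63, safe in int64 elementwise
        m = (m - factors[:, None] * m[rank][None, :]) % p
        rank += 1
    return rank


def target_generic_rank(
    network: DirectedNetwork,
    inputs: Iterable[str],
    targets: Iterable[str],
    params: RankTestParams = RankTestParams(),
) -> int:
    """Generic rank of the target rows of the Kalman matrix for input set B.

    Returns the maximum over ``params.draws`` random weight draws of
    ``rank(C_T)`` where ``C_T`` collects the rows of
    ``[B, AB, ..., A^(n-1) B]`` indexed by the targets.  The input set
    controls the targets iff the returned value equals ``len(targets)``.
    """
    inputs = sorted(set(inputs))
    targets = sorted(set(targets))
    if not inputs:
        raise ValueError("input set must be nonempty")
    nodes = sorted(network.nodes)
    if not set(inputs) <= set(nodes) or not set(targets) <= set(nodes):
        raise ValueError("inputs and targets must be nodes of the network")
    n = len(nodes)
    p = params.prime
    if p <= n * n:
        raise ValueError("prime must exceed |nodes|^2")
    idx = {v: i for i, v in enumerate(nodes)}
    edge_rows = np.array([idx[v] for (_, v) in sorted(network.edges)], dtype=np.int64)
    edge_cols = np.array([idx[u] for (u, _) in sorted(network.edges)], dtype=np.int64)
    t_idx = np.array([idx[t] for t in targets], dtype=np.int64)

    b = np.zeros((n, len(inputs)), dtype=np.int64)
    for j, s in enumerate(inputs):
        b[idx[s], j] = 1

    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    best = 0
    for _ in range(params.draws):
        a = np.zeros((n, n), dtype=np.int64)
        if edge_rows.size:
            a[edge_rows, edge_cols] = rng.integers(1, p, size=edge_rows.size)
        blocks = [b[t_idx]]
        power = b
        for _ in range(1, n):
            power = _matmul_mod(a, power, p)
            blocks.append(power[t_idx])
        c_t = np.hstack(blocks)
        best = max(best, _rank_mod(c_t, p))
        if best == len(targets):
            break
    return best


def is_controllable(
    network: DirectedNetwork,
    inputs: Iterable[str],
    targets: Iterable[str],
    params: RankTestParams = RankTestParams(),
) -> bool:
    """True iff the input set generically controls the target set."""
    targets = set(targets)
    return target_generic_rank(network, inputs, targets, params) == len(targets)


def brute_force_minimum_inputs(
    network: DirectedNetwork,
    targets: Iterable[str],
    allow_self_inputs: bool = True,
    restrict_to: Optional[Iterable[str]] = None,
    params: RankTestParams = RankTestParams(),
) -> tuple[float, frozenset[str]]:
    """Exhaustive minimal driver-set search on tiny networks (|nodes| <= 12).

    Candidate input subsets are enumerated in increasing size, lexicographic
    within size; the first subset whose generic target rank equals |T| is
    returned as ``(size, witness)``.  If none works the result is
    ``(UNCONTROLLABLE, frozenset())`` — generic uncontrollability under the
    given constraints.
    """
    targets = frozenset(targets)
    if network.n_nodes > 12:
        raise ValueError("brute force is guarded to networks with at most 12 nodes")
    candidates = set(network.nodes) if restrict_to is None else set(restrict_to)
    if not allow_self_inputs:
        candidates -= targets
    pool = sorted(candidates)
    for size in range(1, len(pool) + 1):
        for subset in itertools.combinations(pool, size):
            if target_generic_rank(network, subset, targets, params) == len(targets):
                return (size, frozenset(subset))
    return (UNCONTROLLABLE, frozenset())
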