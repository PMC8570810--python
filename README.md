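# targetctl

Structural target controllability of directed protein–protein interaction
networks: build subnetworks around seed proteins, find small sets of input
(driver) nodes — preferentially drug-targetable ones — that control a
prescribed set of target proteins, and verify every answer with an exact
generic-rank test.

## Who this is for

Disease genomics keeps producing lists of survivability-essential proteins
and infection-critical host factors, but few of them are directly
druggable. An alternative is to steer them *indirectly*: treat the
directed interaction network as a linear system dx/dt = A·x + B·u
(`A[i][j]` generically nonzero iff the interaction `j → i` exists) and
look for a small set of source nodes `I` — columns of `B` — whose signals
can drive the target set `T` to arbitrary states. Target controllability
holds generically iff the rows `T` of the Kalman matrix
`[B, AB, A²B, …, A^{n−1}B]` have rank |T|. When a set `S` of
drug-targetable proteins is supplied, solutions are ranked by the
lexicographic objective **(|I| ascending, |I ∩ S| descending)** and the
drug-targetable inputs are distinctly marked in the output.

Two solvers are provided, both returning explicit control paths (one
directed walk per target, input → target) that certify the answer via the
*layer condition* — no node occupied by two paths at the same backward
distance from their targets:

* **greedy** — backward layer-by-layer chain extension, keeping chains
  node-disjoint per layer with a preference-guided maximum bipartite
  matching; randomized restarts, de-duplicated and ranked.
* **ga** — a genetic algorithm over per-target input assignments with
  decode-and-repair, tournament selection, uniform crossover, mutation
  and elitism.

An exact oracle (`verify`, `targetctl.oracle`) re-checks any solution by
computing the generic rank over the prime field GF(2³¹ − 1), so no
floating-point rank threshold is involved. See `docs/methods.md` for the
model, parameters and limitations.

## Worked example

A six-protein network in which targets `c` and `e` are reachable from the
drug-targetable protein `a`:

```
$ cat interactions.tsv        # one directed edge per line: source <TAB> target
a	b
b	c
c	d
d	e
a	f
f	e
$ printf 'e\nc\n' > targets.txt
$ printf 'a\n'   > sources.txt
$ targetctl analyze greedy --network interactions.tsv \
    --targets targets.txt --sources sources.txt --seed 1 --out solution.json
3 solution(s) -> solution.json; best |I|=1
```

The best solution drives both targets from `a` alone — possible because
the two control paths `a→b→c` (length 2) and `a→b→c→d→e` (length 4) have
different lengths, so `a` and the shared prefix nodes occupy different
backward layers in each path. In `solution.json`:

```json
"inputs": [{"id": "a", "is_preferred": true}],
"paths": [
  {"input": "a", "nodes": ["a", "b", "c"], "target": "c"},
  {"input": "a", "nodes": ["a", "b", "c", "d", "e"], "target": "e"}
]
```

`is_preferred: true` marks `a` as one of the supplied drug-targetable
sources; the runner-up solutions use two inputs each. The exact rank test
confirms all of them:

```
$ targetctl verify --network interactions.tsv --solution solution.json
solution 0: |I|=1 rank=2/2 conflicts=0 OK
solution 1: |I|=2 rank=2/2 conflicts=0 OK
solution 2: |I|=2 rank=2/2 conflicts=0 OK
```

`rank=2/2` is the generic rank of the target rows of the Kalman matrix
against the required |T| = 2, and `conflicts=0` means the layer condition
holds.

Other subcommands: `targetctl generate` extracts a subnetwork around seed
proteins (`neighbors`, `direct`, or `gap` with up to four intermediaries),
`targetctl analyze ga` runs the genetic solver, and `targetctl simulate`
produces random benchmark networks. All accept `--config file.yaml` for
flag defaults and are fully seed-deterministic.

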