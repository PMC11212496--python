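"""Leiden community detection with generalized (resolution-scaled) modularity.

The quality function is the weighted modularity

    Q = sum_c [ w_in(c)/m  -  gamma * (s_c / 2m)^2 ]

with m the total edge weight of the graph, w_in(c) the weight of edges inside
module c (self-loops of aggregate graphs counted once at full weight), s_c the
summed vertex strengths of c (a self-loop contributes twice to its vertex's
strength), and gamma the resolution parameter.  gamma = 1 recovers Newman–
Girvan modularity; larger gamma favours more, smaller modules.

One run proceeds from the singleton partition through the three Leiden
phases — queue-based local movement with randomized-proportional target
selection, randomized refinement restricted to well-connected
sub-communities, and aggregation seeded with the non-refined partition —
with the whole cascade restarted from the resulting flat partition until Q
stops improving.  Because runs are stochastic (tie-breaks and refinement are
random), the production protocol performs many independent seeded runs and
keeps the partition with the highest Q.

For graphs with at most 10 vertices an exhaustive Bell-number enumeration of
all set partitions is provided as the ground-truth optimum for testing.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, ParseError, SizeGuardError
from .graph import ComplexGraph

__all__ = [
    "Partition",
    "ModularityParams",
    "ClusteringResult",
    "modularity",
    "leiden_once",
    "cluster_best_of",
    "exhaustive_best_partition",
    "iter_set_partitions",
    "write_partition_tsv",
    "read_partition_tsv",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """Total assignment of vertex labels to module ids 0..k-1."""

    membership: Mapping[str, int]

    def __post_init__(self) -> None:
        memb = dict(self.membership)
        ids = sorted(set(memb.values()))
        if ids and ids != list(range(len(ids))):
            raise ValueError("module ids must be contiguous from 0")
        object.__setattr__(self, "membership", memb)

    @property
    def k(self) -> int:
        return len(set(self.membership.values()))

    def __getitem__(self, label: str) -> int:
        return self.membership[label]

    def __contains__(self, label: str) -> bool:
        return label in self.membership

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.membership))

    def modules(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.k)]
        for v, c in self.membership.items():
            out[c].add(v)
        return out

    def canonicalized(self) -> "Partition":
        """Renumber modules by their smallest contained vertex label."""
        remap: dict[int, int] = {}
        for v in sorted(self.membership):
            c = self.membership[v]
            if c not in remap:
                remap[c] = len(remap)
        return Partition({v: remap[c] for v, c in self.membership.items()})

    @classmethod
    def from_modules(cls, modules: Iterable[Iterable[str]]) -> "Partition":
        memb: dict[str, int] = {}
        for i, module in enumerate(modules):
            for v in module:
                if v in memb:
                    raise ValueError(f"vertex {v!r} assigned to two modules")
                memb[v] = i
        return cls(memb).canonicalized()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return dict(self.canonicalized().membership) == dict(other.canonicalized().membership)


@dataclass(frozen=True)
class ModularityParams:
    """gamma: resolution (dimensionless); theta: refinement randomness temperature."""

    gamma: float = 1.0
    theta: float = 0.01

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class ClusteringResult:
    best: Partition
    best_q: float
    run_qs: tuple[float, ...]
    n_runs: int
    base_seed: int

    def __post_init__(self) -> None:
        if len(self.run_qs) != self.n_runs:
            raise ValueError("run_qs length must equal n_runs")
        if self.run_qs and abs(self.best_q - max(self.run_qs)) > 1e-9:
            raise ValueError("best_q must equal max(run_qs)")


def modularity(g: ComplexGraph, p: Partition, gamma: float = 1.0) -> float:
    """Generalized weighted modularity Q of partition ``p`` on graph ``g``.

    Returns 0.0 for graphs without edges (m = 0).
    """
    missing = [v for v in g.vertices if v not in p]
    if missing:
        raise ValueError(f"partition does not cover vertices: {missing[:5]}")
    m = g.total_weight
    if m == 0:
        return 0.0
    k = p.k
    w_in = [0.0] * k
    s = [0.0] * k
    for (u, v), w in g.edges.items():
        cu, cv = p[u], p[v]
        s[cu] += w
        s[cv] += w
        if cu == cv:
            w_in[cu] += w
    return sum(w_in[c] / m - gamma * (s[c] / (2.0 * m)) ** 2 for c in range(k))


# ---------------------------------------------------------------------------
# internal working representation (supports self-loops for aggregate graphs)


class _WGraph:
    __slots__ = ("n", "adj", "self_w", "strength", "m")

    def __init__(self, n: int, adj: list[dict[int, float]], self_w: list[float]):
        self.n = n
        self.adj = adj
        self.self_w = self_w
        self.strength = [sum(a.values()) + 2.0 * self_w[i] for i, a in enumerate(adj)]
        self.m = sum(sum(a.values()) for a in adj) / 2.0 + sum(self_w)

    @classmethod
    def from_complex_graph(cls, g: ComplexGraph) -> tuple["_WGraph", list[str]]:
        order = list(g.vertices)
        index = {v: i for i, v in enumerate(order)}
        adj: list[dict[int, float]] = [dict() for _ in order]
        for (u, v), w in g.edges.items():
            adj[index[u]][index[v]] = float(w)
            adj[index[v]][index[u]] = float(w)
        return cls(len(order), adj, [0.0] * len(order)), order


def _quality(g: _WGraph, comm: list[int], gamma: float) -> float:
    if g.m == 0:
        return 0.0
    k = max(comm) + 1
    w_in = [0.0] * k
    s = [0.0] * k
    for i in range(g.n):
        c = comm[i]
        s[c] += g.strength[i]
        w_in[c] += g.self_w[i]
        for j, w in g.adj[i].items():
            if j > i and comm[j] == c:
                w_in[c] += w
    return sum(w_in[c] / g.m - gamma * (s[c] / (2.0 * g.m)) ** 2 for c in range(k))


def _local_move(g: _WGraph, comm: list[int], gamma: float, rng: np.random.Generator) -> bool:
    """Queue-based local movement with randomized-proportional selection.

    Each dequeued vertex may move to a neighbouring community that strictly
    increases Q; the target is drawn with probability proportional to its Q
    gain (larger gain, more likely).  Neighbours left outside the chosen
    community re-enter the queue.  Every executed move strictly improves Q,
    so the pass terminates and Q is monotone.  Returns True if any vertex
    moved.
    """
    if g.m == 0:
        return False
    s_comm: dict[int, float] = {}
    for i in range(g.n):
        s_comm[comm[i]] = s_comm.get(comm[i], 0.0) + g.strength[i]
    queue = deque(int(i) for i in rng.permutation(g.n))
    in_queue = [True] * g.n
    moved_any = False
    two_m = 2.0 * g.m
    while queue:
        v = queue.popleft()
        in_queue[v] = False
        cur = comm[v]
        k_v = g.strength[v]
        w_to: dict[int, float] = {}
        for u, w in g.adj[v].items():
            w_to[comm[u]] = w_to.get(comm[u], 0.0) + w
        s_cur_rest = s_comm[cur] - k_v

        def gain(c: int) -> float:
            s_rest = s_cur_rest if c == cur else s_comm.get(c, 0.0)
            return w_to.get(c, 0.0) / g.m - gamma * k_v * s_rest / (two_m * g.m)

        stay = gain(cur)
        improving: list[int] = []
        dqs: list[float] = []
        for c in w_to:
            if c == cur:
                continue
            dq = gain(c) - stay
            if dq > _EPS:
                improving.append(c)
                dqs.append(dq)
        if not improving:
            continue
        if len(improving) == 1:
            target = improving[0]
        else:
            p = np.asarray(dqs, dtype=float)
            target = int(improving[int(rng.choice(len(improving), p=p / p.sum()))])
        comm[v] = target
        s_comm[cur] -= k_v
        s_comm[target] = s_comm.get(target, 0.0) + k_v
        moved_any = True
        for u in g.adj[v]:
            if comm[u] != target and not in_queue[u]:
                queue.append(u)
                in_queue[u] = True
    return moved_any


def _refine(
    g: _WGraph, comm: list[int], gamma: float, theta: float, rng: np.random.Generator
) -> list[int]:
    """Refinement phase: merge singletons within their community.

    Starts from singletons; each vertex that is still alone and
    well-connected within its local-move community may merge into a
    well-connected sub-community of that community, sampled with probability
    proportional to exp(dQ / theta) among non-decreasing-Q candidates.
    """
    ref = list(range(g.n))
    if g.m == 0:
        return ref
    s_ref = list(g.strength)  # summed strength per refined community
    size_ref = [1] * g.n
    # weight from each refined community to the rest of its local community
    ext = [0.0] * g.n
    s_comm: dict[int, float] = {}
    for v in range(g.n):
        s_comm[comm[v]] = s_comm.get(comm[v], 0.0) + g.strength[v]
        ext[v] = sum(w for u, w in g.adj[v].items() if comm[u] == comm[v])
    two_m = 2.0 * g.m
    for v in (int(i) for i in rng.permutation(g.n)):
        if size_ref[ref[v]] != 1:
            continue
        c = comm[v]
        k_v = g.strength[v]
        # vertex well-connectedness within its community
        if ext[v] < gamma * k_v * (s_comm[c] - k_v) / two_m - _EPS:
            continue
        w_to: dict[int, float] = {}
        for u, w in g.adj[v].items():
            if comm[u] == c and ref[u] != ref[v]:
                w_to[ref[u]] = w_to.get(ref[u], 0.0) + w
        cand: list[int] = []
        gains: list[float] = []
        for rc, w in w_to.items():
            # candidate sub-community must itself be well-connected
            if ext[rc] < gamma * s_ref[rc] * (s_comm[c] - s_ref[rc]) / two_m - _EPS:
                continue
            dq = w / g.m - gamma * k_v * s_ref[rc] / (two_m * g.m)
            if dq >= -_EPS:
                cand.append(rc)
                gains.append(dq)
        if not cand:
            continue
        cand.append(ref[v])  # staying singleton is always an option, dQ = 0
        gains.append(0.0)
        arr = np.asarray(gains, dtype=float)
        weights = np.exp((arr - arr.max()) / theta)
        probs = weights / weights.sum()
        target = int(cand[int(rng.choice(len(cand), p=probs))])
        if target == ref[v]:
            continue
        old = ref[v]
        ref[v] = target
        size_ref[target] += size_ref[old]
        size_ref[old] = 0
        s_ref[target] += s_ref[old]
        s_ref[old] = 0.0
        ext[target] += ext[old] - 2.0 * w_to[target]
        ext[old] = 0.0
    return ref


def _aggregate(g: _WGraph, ref: list[int], comm: list[int]) -> tuple[_WGraph, list[int], list[int]]:
    """Collapse refined communities into vertices.

    Returns (aggregate graph, mapping old vertex -> new vertex, initial
    community of each new vertex taken from the non-refined partition).
    """
    ids = sorted(set(ref))
    remap = {old: new for new, old in enumerate(ids)}
    mapping = [remap[ref[v]] for v in range(g.n)]
    n_new = len(ids)
    adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
    self_w = [0.0] * n_new
    for v in range(g.n):
        nv = mapping[v]
        self_w[nv] += g.self_w[v]
        for u, w in g.adj[v].items():
            if u > v:
                continue
            nu = mapping[u]
            if nu == nv:
                self_w[nv] += w
            else:
                adj[nv][nu] = adj[nv].get(nu, 0.0) + w
                adj[nu][nv] = adj[nu].get(nv, 0.0) + w
    new_comm = [0] * n_new
    for v in range(g.n):
        new_comm[mapping[v]] = comm[v]
    # make community ids contiguous for the next level
    cids = sorted(set(new_comm))
    cmap = {c: i for i, c in enumerate(cids)}
    new_comm = [cmap[c] for c in new_comm]
    return _WGraph(n_new, adj, self_w), mapping, new_comm


def _cascade(
    wg0: _WGraph,
    start: list[int],
    params: ModularityParams,
    rng: np.random.Generator,
    audit: bool,
) -> list[int]:
    """One move/refine/aggregate cascade; returns flat membership per vertex."""
    wg = wg0
    flat = list(range(wg0.n))  # original vertex -> current aggregate vertex
    comm = list(start)
    prev_q = _quality(wg, comm, params.gamma) if audit else -math.inf
    while True:
        _local_move(wg, comm, params.gamma, rng)
        # normalize community ids
        cids = sorted(set(comm))
        cmap = {c: i for i, c in enumerate(cids)}
        comm = [cmap[c] for c in comm]
        if audit:
            q_now = _quality(wg, comm, params.gamma)
            assert q_now >= prev_q - 1e-9, "Q decreased across a local-move pass"
            prev_q = q_now
        if len(cids) == wg.n:
            break  # every aggregate vertex is its own community: converged
        ref = _refine(wg, comm, params.gamma, params.theta, rng)
        new_wg, mapping, new_comm = _aggregate(wg, ref, comm)
        if new_wg.n == wg.n:
            break  # refinement kept all singletons: no further progress
        if audit:
            q_agg = _quality(new_wg, new_comm, params.gamma)
            assert abs(q_agg - prev_q) <= 1e-9, "aggregation changed Q"
        flat = [mapping[flat[v]] for v in range(len(flat))]
        wg, comm = new_wg, new_comm
    return [comm[flat[v]] for v in range(wg0.n)]


def leiden_once(
    g: ComplexGraph,
    params: ModularityParams | None = None,
    seed: int = 0,
    audit: bool = False,
) -> Partition:
    """One seeded Leiden run from the singleton partition.

    The three-phase cascade (local movement, refinement, aggregation) shrinks
    the graph until no further merge is possible; the whole cascade is then
    restarted from the resulting flat partition on the original graph and
    repeated until a full restart no longer improves Q ("until no further
    improvement can be obtained").

    With ``audit=True`` two internal invariants are asserted on every
    iteration: Q never decreases, and the aggregate graph under the induced
    partition scores the same Q as the original graph under the flat
    partition (aggregation invariance).
    """
    params = params or ModularityParams()
    if g.n_vertices == 0:
        raise DegenerateInputError("cannot cluster an empty graph")
    rng = np.random.default_rng(seed)
    wg0, order = _WGraph.from_complex_graph(g)
    memb = list(range(wg0.n))  # singleton start
    prev_q = _quality(wg0, memb, params.gamma)
    while True:
        memb = _cascade(wg0, memb, params, rng, audit)
        q = _quality(wg0, memb, params.gamma)
        if q <= prev_q + _EPS:
            break
        prev_q = q
    final = {order[v]: memb[v] for v in range(len(order))}
    return Partition(_contiguous(final)).canonicalized()


def _contiguous(memb: dict[str, int]) -> dict[str, int]:
    ids = sorted(set(memb.values()))
    remap = {c: i for i, c in enumerate(ids)}
    return {v: remap[c] for v, c in memb.items()}


def cluster_best_of(
    g: ComplexGraph,
    params: ModularityParams | None = None,
    n_runs: int = 2000,
    base_seed: int = 0,
) -> ClusteringResult:
    """Best-of-N protocol: independent seeded runs, keep the max-Q partition.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1``.  Ties on Q are
    broken in favour of the earliest seed; the winning partition is returned
    with canonical module numbering (modules ordered by their smallest
    vertex label).
    """
    params = params or ModularityParams()
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    run_qs: list[float] = []
    best: Partition | None = None
    best_q = -math.inf
    for i in range(n_runs):
        p = leiden_once(g, params, seed=base_seed + i)
        q = modularity(g, p, params.gamma)
        run_qs.append(q)
        if q > best_q + _EPS:
            best_q = q
            best = p
    assert best is not None
    best_q = max(run_qs)  # remove _EPS slack from the reported value
    return ClusteringResult(
        best=best.canonicalized(),
        best_q=best_q,
        run_qs=tuple(run_qs),
        n_runs=n_runs,
        base_seed=base_seed,
    )


def iter_set_partitions(items: Sequence[str]) -> Iterator[list[list[str]]]:
    """All set partitions of ``items`` in restricted-growth-string order."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    maxes = [0] * n
    while True:
        k = max(rgs) + 1
        blocks: list[list[str]] = [[] for _ in range(k)]
        for i, c in enumerate(rgs):
            blocks[c].append(items[i])
        yield blocks
        i = n - 1
        while i > 0 and rgs[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        maxes[i] = max(maxes[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[i]


def exhaustive_best_partition(g: ComplexGraph, gamma: float = 1.0, max_vertices: int = 10) -> Partition:
    """Global Q maximizer by Bell-number enumeration of all set partitions.

    A testing oracle, guarded to at most ``max_vertices`` (default 10)
    vertices.  Ties are resolved to the lexicographically smallest canonical
    form, which the enumeration order supplies for free.  Graphs without
    edges have Q = 0 for every partition; by convention the all-singleton
    partition is returned for them.
    """
    if g.n_vertices > max_vertices:
        raise SizeGuardError(
            f"exhaustive enumeration limited to {max_vertices} vertices, graph has {g.n_vertices}"
        )
    labels = list(g.vertices)
    m = g.total_weight
    if m == 0:
        return Partition({v: i for i, v in enumerate(labels)})
    index = {v: i for i, v in enumerate(labels)}
    edge_list = [(index[u], index[v], w) for (u, v), w in g.edges.items()]
    strengths = [0.0] * len(labels)
    for u, v, w in edge_list:
        strengths[u] += w
        strengths[v] += w
    best_q = -math.inf
    best: list[list[str]] | None = None
    for blocks in iter_set_partitions(labels):
        memb = [0] * len(labels)
        for c, block in enumerate(blocks):
            for v in block:
                memb[index[v]] = c
        w_in = [0.0] * len(blocks)
        for u, v, w in edge_list:
            if memb[u] == memb[v]:
                w_in[memb[u]] += w
        s = [0.0] * len(blocks)
        for i, st in enumerate(strengths):
            s[memb[i]] += st
        q = sum(w_in[c] / m - gamma * (s[c] / (2.0 * m)) ** 2 for c in range(len(blocks)))
        if q > best_q + _EPS:
            best_q = q
            best = blocks
    assert best is not None
    return Partition.from_modules(best)


def write_partition_tsv(
    p: Partition,
    path: str | Path,
    q: float | None = None,
    gamma: float = 1.0,
    n_runs: int | None = None,
    base_seed: int | None = None,
) -> Path:
    """Two-column TSV ``chain_id<TAB>module_id`` with a metadata header comment."""
    path = Path(path)
    with path.open("w") as fh:
        meta = []
        if q is not None:
            meta.append(f"Q={q:.6f}")
        meta.append(f"gamma={gamma:g}")
        if n_runs is not None:
            meta.append(f"runs={n_runs}")
        if base_seed is not None:
            meta.append(f"seed={base_seed}")
        fh.write("# " + " ".join(meta) + "\n")
        for v in sorted(p.membership):
            fh.write(f"{v}\t{p[v]}\n")
    return path


def read_partition_tsv(path: str | Path) -> Partition:
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"{path}: no such file")
    memb: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        try:
            memb[parts[0]] = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: module id must be an integer") from None
    return Partition(_contiguous(memb))
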