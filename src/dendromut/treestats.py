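"""Positive-control tree statistics.

For small leaf counts every unrooted binary topology can be enumerated
((2n-5)!! of them), so the parsimony landscape and the topological
path-difference (PD) null distribution are computed exactly rather than
sampled.  Fitch parsimony, PD, Robinson-Foulds distances, an equal-rates
likelihood scan with bootstrap support, and the branch-length regression of
mutation counts on metres complete the positive-control toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm


class TreeStatsError(ValueError):
    pass


@dataclass(frozen=True)
class Topology:
    """Unrooted binary topology over labelled leaves.

    Leaves are ids 0..n_leaves-1 (with an optional label list); internal
    nodes continue the numbering.  Edges are undirected pairs.
    """

    n_leaves: int
    edges: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(self, "labels",
                               tuple(str(i + 1) for i in range(self.n_leaves)))

    @property
    def n_nodes(self) -> int:
        return 1 + max(max(e) for e in self.edges)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def leaf_distance_vector(self) -> np.ndarray:
        """Pairwise leaf-to-leaf path lengths in edges, condensed ordering."""
        adj = self.adjacency()
        n = self.n_leaves
        D = np.zeros((n, n), dtype=np.int32)
        for src in range(n):
            dist = {src: 0}
            stack = [src]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        stack.append(w)
            for dst in range(src + 1, n):
                D[src, dst] = dist[dst]
        return D[np.triu_indices(n, k=1)].astype(float)

    def splits(self) -> frozenset[frozenset[int]]:
        """Non-trivial bipartitions, each canonicalised to the side not
        containing leaf 0."""
        adj = self.adjacency()
        out = set()
        for a, b in self.edges:
            side = self._side(adj, a, b)
            if 0 in side:
                side = frozenset(range(self.n_leaves)) - side
            if 2 <= len(side) <= self.n_leaves - 2:
                out.add(frozenset(side))
        return frozenset(out)

    def _side(self, adj, a: int, b: int) -> frozenset[int]:
        """Leaves on b's side of edge (a, b)."""
        seen = {a, b}
        stack = [b]
        leaves = set()
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                leaves.add(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(leaves)

    def relabel(self, perm: dict[int, int]) -> "Topology":
        """Permute leaf ids (labels keep their positional meaning)."""
        remap = {old: new for old, new in perm.items()}
        edges = tuple(tuple(sorted((remap.get(a, a), remap.get(b, b))))
                      for a, b in self.edges)
        return Topology(self.n_leaves, edges, self.labels)

    def newick(self) -> str:
        adj = self.adjacency()
        root = self.n_leaves  # arbitrary internal node
        if self.n_nodes == self.n_leaves:
            raise TreeStatsError("degenerate topology")

        def rec(v: int, parent: int) -> str:
            kids = [w for w in adj[v] if w != parent]
            if not kids:
                return self.labels[v]
            return "(" + ",".join(rec(w, v) for w in kids) + ")"

        return rec(root, -1) + ";"


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def enumerate_topologies(n: int, labels: tuple[str, ...] = ()) -> list[Topology]:
    """All (2n-5)!! unrooted binary topologies on n labelled leaves, by
    successive insertion of each new leaf into every edge."""
    if not 3 <= n <= 10:
        raise TreeStatsError("n must be between 3 and 10")
    labels = labels or tuple(str(i + 1) for i in range(n))
    if len(labels) != n:
        raise TreeStatsError("label count mismatch")
    base = [((0, n), (1, n), (2, n))]  # star on leaves 0,1,2 with hub n
    trees = base
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        hub = next_internal
        for edges in trees:
            for ei, (a, b) in enumerate(edges):
                rest = edges[:ei] + edges[ei + 1:]
                new_trees.append(rest + ((a, hub), (b, hub), (leaf, hub)))
        trees = new_trees
        next_internal += 1
    return [Topology(n, t, labels) for t in trees]


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def fitch_score(topology: Topology, alignment) -> int:
    """Minimum number of state changes over all sites (Fitch set-intersection
    dynamic programming, vectorised over sites).

    ``alignment`` maps leaf label -> sequence of hashable states (all the
    same length), or is an (n_leaves, n_sites) array of small ints.
    """
    states = _encode_alignment(topology, alignment)  # (n_leaves, S) bitmasks
    n_sites = states.shape[1]
    adj = topology.adjacency()
    root = topology.n_leaves
    order: list[tuple[int, int]] = []  # (node, parent) postorder
    stack = [(root, -1, False)]
    while stack:
        v, p, done = stack.pop()
        if done:
            order.append((v, p))
            continue
        stack.append((v, p, True))
        for w in adj[v]:
            if w != p:
                stack.append((w, v, False))
    masks = {v: states[v] for v in range(topology.n_leaves)}
    changes = np.zeros(n_sites, dtype=np.int64)
    for v, p in order:
        kids = [w for w in adj[v] if w != p]
        if not kids:
            continue
        acc = masks[kids[0]]
        for w in kids[1:]:
            inter = acc & masks[w]
            union = acc | masks[w]
            miss = inter == 0
            changes += miss
            acc = np.where(miss, union, inter)
        masks[v] = acc
    return int(changes.sum())


def _encode_alignment(topology: Topology, alignment) -> np.ndarray:
    if isinstance(alignment, np.ndarray):
        arr = alignment
        if arr.shape[0] != topology.n_leaves:
            raise TreeStatsError("alignment rows do not match leaves")
        return (1 << arr.astype(np.int64))
    try:
        rows = [alignment[lbl] for lbl in topology.labels]
    except KeyError as e:
        raise TreeStatsError(f"alignment missing leaf {e}") from None
    n_sites = len(rows[0])
    if any(len(r) != n_sites for r in rows):
        raise TreeStatsError("ragged alignment")
    out = np.zeros((topology.n_leaves, n_sites), dtype=np.int64)
    for s in range(n_sites):
        coding: dict = {}
        for li, row in enumerate(rows):
            st = row[s]
            if st not in coding:
                coding[st] = len(coding)
            out[li, s] = 1 << coding[st]
    return out


def max_parsimony_trees(topologies: list[Topology], alignment):
    scores = np.array([fitch_score(t, alignment) for t in topologies])
    best = int(scores.min())
    return [t for t, s in zip(topologies, scores) if s == best], best, scores


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def path_difference(a: Topology, b: Topology) -> float:
    """Euclidean distance between pairwise leaf path-length vectors, all
    edges counted as length 1 (topology-only PD)."""
    if a.n_leaves != b.n_leaves or a.labels != b.labels:
        raise TreeStatsError("leaf sets differ")
    return float(np.linalg.norm(a.leaf_distance_vector() - b.leaf_distance_vector()))


def pd_null_test(observed: Topology, reference: Topology,
                 topologies: list[Topology] | None = None):
    """p-value of the observed topology's PD to the reference against the
    exhaustive all-topologies null; ties count as at-least-as-close."""
    if topologies is None:
        topologies = enumerate_topologies(reference.n_leaves, reference.labels)
    null = np.array([path_difference(reference, t) for t in topologies])
    obs = path_difference(reference, observed)
    p = float((null <= obs).mean())
    return p, obs, null


def rf_distance(a: Topology, b: Topology) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    if a.n_leaves != b.n_leaves:
        raise TreeStatsError("leaf sets differ")
    return len(a.splits() ^ b.splits())


def max_rf(n_leaves: int) -> int:
    return 2 * (n_leaves - 3)


# ---------------------------------------------------------------------------
# equal-rates likelihood scan
# ---------------------------------------------------------------------------

def _jc_transition(t: float, r: int) -> np.ndarray:
    """r-state equal-rates (Jukes-Cantor-like) transition matrix."""
    same = 1.0 / r + (1.0 - 1.0 / r) * np.exp(-r / (r - 1.0) * t)
    diff = (1.0 - same) / (r - 1.0)
    P = np.full((r, r), diff)
    np.fill_diagonal(P, same)
    return P


def _topology_loglik(topology: Topology, states: np.ndarray, lengths: np.ndarray,
                     r: int) -> float:
    """Pruning likelihood with one length per edge; states (n_leaves, S)."""
    S = states.shape[1]
    adj = topology.adjacency()
    root = topology.n_leaves
    edge_index = {frozenset(e): i for i, e in enumerate(topology.edges)}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(S)
    order = []
    stack = [(root, -1, False)]
    while stack:
        v, p, done = stack.pop()
        if done:
            order.append((v, p))
            continue
        stack.append((v, p, True))
        for w in adj[v]:
            if w != p:
                stack.append((w, v, False))
    for v, p in order:
        kids = [w for w in adj[v] if w != p]
        if not kids:
            m = np.zeros((S, r))
            m[np.arange(S), states[v]] = 1.0
            partial[v] = m
            continue
        acc = np.ones((S, r))
        for w in kids:
            P = _jc_transition(lengths[edge_index[frozenset((v, w))]], r)
            acc = acc * (partial.pop(w) @ P.T)
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        logscale += np.log(mx)
        partial[v] = acc / mx[:, None]
    lik = partial[root].mean(axis=1)  # uniform root frequencies
    return float((np.log(lik) + logscale).sum())


def ml_tree_scan(alignment, topologies: list[Topology], n_bootstrap: int = 100,
                 seed: int = 0):
    """Equal-rates ML over the supplied topologies with per-edge length
    optimisation; nonparametric bootstrap over sites gives split support.

    Returns dict with best topology, per-topology log-likelihoods, tied-best
    list, and bootstrap support percentages for the best tree's splits.
    """
    from scipy.optimize import minimize

    states, r = _integer_states(topologies[0], alignment)
    if states.max() == states.min():
        raise TreeStatsError("alignment is invariant; likelihood scan is degenerate")

    def score(topology: Topology, st: np.ndarray) -> float:
        n_e = len(topology.edges)

        def nll(logx):
            return -_topology_loglik(topology, st, np.exp(logx), r)

        x0 = np.full(n_e, np.log(0.1))
        opt = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(1e-6), np.log(20.0))] * n_e)
        return -float(opt.fun)

    logliks = np.array([score(t, states) for t in topologies])
    best_i = int(logliks.argmax())
    ties = [t for t, v in zip(topologies, logliks)
            if v >= logliks[best_i] - 1e-6]
    best = topologies[best_i]

    support: dict[frozenset[int], float] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        best_splits = best.splits()
        hit = {sp: 0 for sp in best_splits}
        S = states.shape[1]
        for _ in range(n_bootstrap):
            idx = rng.integers(0, S, size=S)
            st = states[:, idx]
            ll = np.array([score(t, st) for t in topologies])
            bt = topologies[int(ll.argmax())]
            for sp in bt.splits():
                if sp in hit:
                    hit[sp] += 1
        support = {sp: 100.0 * h / n_bootstrap for sp, h in hit.items()}
    return {"best": best, "logliks": logliks, "ties": ties, "support": support}


def _integer_states(topology: Topology, alignment):
    if isinstance(alignment, np.ndarray):
        arr = alignment.astype(np.int64)
    else:
        rows = [alignment[lbl] for lbl in topology.labels]
        coding: dict = {}
        arr = np.zeros((len(rows), len(rows[0])), dtype=np.int64)
        for li, row in enumerate(rows):
            for s, st in enumerate(row):
                if st not in coding:
                    coding[st] = len(coding)
                arr[li, s] = coding[st]
    r = int(arr.max()) + 1
    return arr, max(r, 2)


# ---------------------------------------------------------------------------
# branch-length regression
# ---------------------------------------------------------------------------

def branch_length_regression(metres: np.ndarray, counts: np.ndarray):
    """No-intercept least squares of per-edge mutation counts on metres.

    Returns (slope, R^2, p-value) for the through-origin model, as used to
    ask whether mutations accumulate in proportion to physical growth.
    """
    metres = np.asarray(metres, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if metres.shape != counts.shape or metres.ndim != 1:
        raise TreeStatsError("metres/counts must be matching 1-d vectors")
    if np.all(counts == 0):
        raise TreeStatsError("all mutation counts are zero")
    model = sm.OLS(counts, metres[:, None]).fit()
    return float(model.params[0]), float(model.rsquared), float(model.pvalues[0])


def tree_edge_vectors(tree, calls_per_edge: dict[str, int]):
    """Align a physical tree's edge lengths with per-edge mutation counts."""
    metres, counts = [], []
    for _, child in tree.edges:
        metres.append(tree.length[child])
        counts.append(calls_per_edge.get(child, 0))
    return np.array(metres), np.array(counts, dtype=float)


def topology_from_physical(tree) -> Topology:
    """Unrooted leaf topology of a PhysicalTree (root of degree 2 suppressed)."""
    leaves = tree.leaves
    lbl = {lf: i for i, lf in enumerate(leaves)}
    next_id = [len(leaves)]
    ids: dict[str, int] = {}

    def node_id(name: str) -> int:
        if name in lbl:
            return lbl[name]
        if name not in ids:
            ids[name] = next_id[0]
            next_id[0] += 1
        return ids[name]

    edges = [(node_id(p), node_id(c)) for p, c in tree.edges]
    # suppress a degree-2 root
    root_id = node_id(tree.root)
    incident = [e for e in edges if root_id in e]
    if len(incident) == 2:
        (a,), (b,) = ([x for x in e if x != root_id] for e in incident)
        edges = [e for e in edges if root_id not in e] + [(a, b)]
    edges = [tuple(sorted(e)) for e in edges]
    # compact ids
    used = sorted({x for e in edges for x in e})
    remap = {x: i for i, x in enumerate(used)}
    edges = tuple(tuple(sorted((remap[a], remap[b]))) for a, b in edges)
    return Topology(len(leaves), edges, tuple(leaves))
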