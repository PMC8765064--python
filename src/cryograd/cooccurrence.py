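"""Thresholded positive-Spearman co-occurrence network and Louvain modules.

An edge joins two ASVs whose abundances have Spearman rho strictly above the
threshold (default 0.75); only positive associations are kept.  Modules are
communities found by weighted Louvain modularity maximization; communities
with a single member are dropped from the partition (and counted), since a
lone ASV carries no co-occurrence signal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AsvTable

__all__ = [
    "CooccurrenceNetwork",
    "ModulePartition",
    "correlation_network",
    "louvain_partition",
    "partition_modularity",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected weighted network; edges carry the Spearman rho."""

    edges: pd.DataFrame  # columns: asv_i, asv_j, rho
    rho_min: float

    @property
    def nodes(self) -> list[str]:
        if self.edges.empty:
            return []
        return sorted(set(self.edges["asv_i"]) | set(self.edges["asv_j"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_igraph(self) -> ig.Graph:
        nodes = self.nodes
        index = {n: i for i, n in enumerate(nodes)}
        g = ig.Graph(
            n=len(nodes),
            edges=[(index[a], index[b])
                   for a, b in zip(self.edges["asv_i"], self.edges["asv_j"])],
        )
        g.vs["name"] = nodes
        g.es["weight"] = list(self.edges["rho"].astype(float))
        return g


@dataclass
class ModulePartition:
    """Disjoint modules of co-occurring ASVs (each with >= 2 members)."""

    modules: dict[str, list[str]]
    modularity: float
    n_singletons_dropped: int = 0

    def membership(self) -> pd.Series:
        pairs = [(asv, mod) for mod, members in self.modules.items()
                 for asv in members]
        if not pairs:
            return pd.Series(dtype=object, name="module_id")
        asvs, mods = zip(*pairs)
        return pd.Series(mods, index=list(asvs), name="module_id")

    def sizes(self) -> pd.Series:
        return pd.Series({m: len(v) for m, v in self.modules.items()},
                         name="n_asvs").sort_values(ascending=False)


def correlation_network(table: AsvTable, rho_min: float = 0.75) -> CooccurrenceNetwork:
    """All ASV pairs with Spearman rho strictly greater than ``rho_min``.

    The input should already be prevalence-filtered; correlations are
    computed on the table as given (relative abundances by convention).
    """
    data = table.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = data.to_numpy(dtype=float)
    if data.shape[1] < 2:
        return CooccurrenceNetwork(
            edges=pd.DataFrame(columns=["asv_i", "asv_j", "rho"]),
            rho_min=rho_min,
        )
    rho = stats.spearmanr(values).statistic
    if data.shape[1] == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    iu = np.triu_indices(data.shape[1], k=1)
    mask = rho[iu] > rho_min
    cols = np.asarray(data.columns)
    edges = pd.DataFrame({
        "asv_i": cols[iu[0][mask]],
        "asv_j": cols[iu[1][mask]],
        "rho": rho[iu][mask],
    })
    return CooccurrenceNetwork(edges=edges, rho_min=rho_min)


def partition_modularity(net: CooccurrenceNetwork,
                         membership: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of an arbitrary node->community map."""
    g = net.to_igraph()
    labels = [membership[name] for name in g.vs["name"]]
    return float(g.modularity(labels, weights="weight"))


class _LocalSearch:
    """Incremental-modularity bookkeeping for move-based refinement.

    Maintains, for the current labelling, each community's total strength
    S_c and internal weight In_c (full symmetric sum), so that single-node
    moves evaluate in O(deg v).  Modularity convention:
    Q = sum_c (In_c / T - (S_c / T)^2) with T the total adjacency weight.
    """

    def __init__(self, adj: list[dict[int, float]], labels: list[int]):
        self.adj = adj
        self.k = np.array([sum(nbrs.values()) for nbrs in adj])
        self.T = float(self.k.sum())
        self.labels = list(labels)
        self.S: dict[int, float] = {}
        self.In: dict[int, float] = {}
        for v, c in enumerate(self.labels):
            self.S[c] = self.S.get(c, 0.0) + self.k[v]
        for v, nbrs in enumerate(adj):
            for u, w in nbrs.items():
                if self.labels[u] == self.labels[v]:
                    self.In[self.labels[v]] = self.In.get(self.labels[v], 0.0) + w
        for c in self.S:
            self.In.setdefault(c, 0.0)

    def w_to(self, v: int, c: int) -> float:
        """Weight from v to community c (v's own membership ignored)."""
        return sum(w for u, w in self.adj[v].items() if self.labels[u] == c)

    def delta(self, v: int, target: int) -> float:
        a = self.labels[v]
        if target == a:
            return 0.0
        kv = self.k[v]
        w_a = self.w_to(v, a)
        w_b = self.w_to(v, target)
        s_a, s_b = self.S[a], self.S.get(target, 0.0)
        d_in = 2.0 * (w_b - w_a) / self.T
        d_deg = ((s_a - kv) ** 2 + (s_b + kv) ** 2 - s_a**2 - s_b**2) / self.T**2
        return d_in - d_deg

    def apply(self, v: int, target: int) -> None:
        a = self.labels[v]
        if target == a:
            return
        kv = self.k[v]
        self.In[a] = self.In.get(a, 0.0) - 2.0 * self.w_to(v, a)
        self.S[a] -= kv
        if self.S[a] <= 0 and a in self.In and abs(self.In[a]) < 1e-12:
            self.S.pop(a), self.In.pop(a)
        self.labels[v] = target
        self.In[target] = self.In.get(target, 0.0) + 2.0 * self.w_to(v, target)
        self.S[target] = self.S.get(target, 0.0) + kv

    def modularity(self) -> float:
        return sum(self.In[c] / self.T - (self.S[c] / self.T) ** 2
                   for c in self.S)

    def candidate_targets(self, v: int) -> set[int]:
        cands = {self.labels[u] for u in self.adj[v]}
        cands.add(self._fresh_label())
        return cands

    def _fresh_label(self) -> int:
        return max(self.S) + 1


def _refine_partition(adj: list[dict[int, float]], labels: list[int],
                      max_passes: int = 100) -> list[int]:
    """Hill-climb on modularity with single-node and adjacent-pair moves.

    Louvain's greedy phase cannot realize every partition (a move that only
    pays off for two nodes jointly is never taken); this polish accepts the
    best positive-gain single move per node, then joint moves of adjacent
    node pairs, until neither improves.  Deterministic given its input.
    """
    ls = _LocalSearch(adj, labels)
    edges = [(u, v) for u, nbrs in enumerate(adj) for v in nbrs if u < v]
    for _ in range(max_passes):
        improved = False
        for v in range(len(adj)):
            best_gain, best_target = 1e-12, None
            for target in ls.candidate_targets(v):
                gain = ls.delta(v, target)
                if gain > best_gain:
                    best_gain, best_target = gain, target
            if best_target is not None:
                ls.apply(v, best_target)
                improved = True
        for u, v in edges:
            targets = ls.candidate_targets(u) | ls.candidate_targets(v)
            undo_u, undo_v = ls.labels[u], ls.labels[v]
            best = None
            for target in targets:
                d1 = ls.delta(u, target)
                ls.apply(u, target)
                d2 = ls.delta(v, target)
                ls.apply(u, undo_u)
                if d1 + d2 > 1e-12 and (best is None or d1 + d2 > best[0]):
                    best = (d1 + d2, target)
            if best is not None:
                ls.apply(u, best[1])
                ls.apply(v, best[1])
                improved = True
        if not improved:
            break
    return ls.labels


def _exact_max_modularity(w: np.ndarray) -> tuple[float, list[int]]:
    """Global modularity optimum by enumerating every partition (tiny n)."""
    n = w.shape[0]
    T = w.sum()
    deg = w.sum(axis=1)

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best_q, best_groups = -np.inf, None
    for groups in partitions(list(range(n))):
        q = sum(
            w[np.ix_(grp, grp)].sum() / T - (deg[grp].sum() / T) ** 2
            for grp in groups
        )
        if q > best_q:
            best_q, best_groups = q, groups
    labels = [0] * n
    for c, grp in enumerate(best_groups):
        for v in grp:
            labels[v] = c
    return float(best_q), labels


#: Largest network solved by exhaustive enumeration instead of the heuristic.
EXACT_PARTITION_MAX_NODES = 9


def louvain_partition(
    net: CooccurrenceNetwork, seed: int = 0, n_restarts: int = 20
) -> ModulePartition:
    """Modularity-maximizing module detection on the weighted network.

    Networks small enough to enumerate every partition (at most
    ``EXACT_PARTITION_MAX_NODES`` nodes) are solved exactly.  Larger
    networks use Louvain (igraph's multilevel heuristic): per restart the
    vertex order is randomized from ``seed`` and the multilevel pass is
    followed by a move-based refinement (single-node and adjacent-pair
    moves) that repairs small local optima the greedy phase cannot escape;
    the highest-modularity partition over ``n_restarts`` runs is returned.
    Deterministic given the seed.  Communities with one member are dropped
    from the partition and counted.
    """
    if net.n_edges == 0:
        raise ValueError("cannot partition an empty network")
    g = net.to_igraph()
    n = g.vcount()
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    wmat = np.zeros((n, n))
    for e, w in zip(g.es, g.es["weight"]):
        a, b = e.tuple
        adj[a][b] = adj[b][a] = float(w)
        wmat[a, b] = wmat[b, a] = float(w)
    if n <= EXACT_PARTITION_MAX_NODES:
        q, membership = _exact_max_modularity(wmat)
    else:
        py_rng = random.Random(seed)
        old_state = random.getstate()
        best = None
        try:
            for _ in range(max(1, n_restarts)):
                perm = list(range(n))
                py_rng.shuffle(perm)
                gp = g.permute_vertices(perm)
                random.seed(py_rng.randrange(2**31))
                clustering = gp.community_multilevel(weights="weight")
                # map back: vertex v of g is vertex perm[v] of gp
                labels = [clustering.membership[perm[v]] for v in range(n)]
                labels = _refine_partition(adj, labels)
                q = float(g.modularity(labels, weights="weight"))
                if best is None or q > best[0] + 1e-12:
                    best = (q, labels)
        finally:
            random.setstate(old_state)
        q, membership = best
    groups: dict[int, list[str]] = {}
    for name, comm in zip(g.vs["name"], membership):
        groups.setdefault(comm, []).append(name)
    # stable module numbering: by descending size, then first member name
    ordered = sorted(
        (members for members in groups.values() if len(members) >= 2),
        key=lambda m: (-len(m), sorted(m)[0]),
    )
    n_singletons = sum(1 for m in groups.values() if len(m) < 2)
    modules = {f"module_{i + 1:03d}": sorted(m) for i, m in enumerate(ordered)}
    return ModulePartition(modules=modules, modularity=q,
                           n_singletons_dropped=n_singletons)
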