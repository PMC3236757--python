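"""Cost-thresholded binary graphs and the economical small-world metric family.

An association matrix is thresholded at a network *cost* C — the fraction of
the N(N-1)/2 possible edges that are kept — by retaining the K = round(C *
N(N-1)/2) strongest pairs.  On the resulting binary undirected graph we
compute:

- global efficiency  Eglob  = mean over ordered pairs i != j of 1/L(i,j)
- nodal efficiency   Enodal(i) = (1/(N-1)) * sum_{j != i} 1/L(i,j)
- local efficiency   Elocal = mean over i of Eglob of the subgraph induced
  by i's neighbors (nodes with < 2 neighbors contribute 0)
- clustering Cp and characteristic path length Lp (mean finite shortest
  path over connected ordered pairs)
- cost-efficiency    CE(C) = Eglob(C) - C, and its maximum maxCE

with the convention 1/inf = 0 for disconnected pairs, so every quantity is
well defined on disconnected graphs.  Small-worldness is assessed against
ensembles of random and ring-lattice ("regular") null graphs matched in
node and edge count: sigma = (Cp/<Cp_rand>) / (Lp/<Lp_rand>) > 1 indicates
small-world organization, and the small-world *regime* is the contiguous
cost interval on which the empirical Eglob lies strictly between the
regular and random null means while Elocal lies strictly between the random
and regular null means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .connectivity import MIMatrix

__all__ = [
    "AdjacencyGraph",
    "MetricCurve",
    "NullEnsemble",
    "RegimeInterval",
    "default_cost_grid",
    "threshold_by_cost",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "clustering_and_pathlength",
    "cost_efficiency_curve",
    "random_graph_matched",
    "regular_lattice_matched",
    "watts_strogatz_matched",
    "build_null_ensemble",
    "sigma_small_worldness",
    "small_world_regime",
    "metric_curves",
]


def default_cost_grid(start: float = 0.16, stop: float = 0.50, step: float = 0.02) -> np.ndarray:
    """Cost grid 0.16..0.50 in steps of 0.02 by default (extensible to 1.0)."""
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return np.round(grid, 10)


@dataclass
class AdjacencyGraph:
    """Binary undirected graph, no self-loops, stored as a dense 0/1 matrix."""

    adj: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adj)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        a = (a != 0).astype(np.uint8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adj = a

    @property
    def n(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    @property
    def cost(self) -> float:
        npairs = self.n * (self.n - 1) // 2
        return self.n_edges / npairs if npairs else 0.0

    @property
    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adj)

    @classmethod
    def from_edges(cls, n: int, edges) -> "AdjacencyGraph":
        a = np.zeros((n, n), dtype=np.uint8)
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        return cls(a)

    def to_edgelist(self, path, labels=None) -> None:
        """Write a one-based (i, j) edge-list text file, one edge per line."""
        labels = labels or tuple(str(i + 1) for i in range(self.n))
        iu, ju = np.nonzero(np.triu(self.adj, k=1))
        with open(path, "w") as fh:
            fh.write(f"# n={self.n}\n")
            for i, j in zip(iu, ju):
                fh.write(f"{labels[i]}\t{labels[j]}\n")

    @classmethod
    def from_edgelist(cls, path) -> "AdjacencyGraph":
        n = None
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    n = int(line.split("n=")[1])
                    continue
                if line:
                    i, j = line.split("\t")
                    edges.append((int(i) - 1, int(j) - 1))
        if n is None:
            n = 1 + max(max(e) for e in edges) if edges else 0
        return cls.from_edges(n, edges)

    def to_csv(self, path, labels=None) -> None:
        """Write the 0/1 adjacency matrix as labeled CSV."""
        import pandas as pd

        labels = list(labels or (f"ch{i}" for i in range(self.n)))
        pd.DataFrame(self.adj, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AdjacencyGraph":
        import pandas as pd

        return cls(pd.read_csv(path, index_col=0, comment="#").to_numpy())


@dataclass
class MetricCurve:
    """A scalar network metric on a shared cost grid, with provenance tags."""

    name: str
    costs: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.costs.shape != self.values.shape:
            raise ValueError("costs and values must be aligned")


def threshold_by_cost(mi: MIMatrix | np.ndarray, cost: float) -> AdjacencyGraph:
    """Keep the K = round(cost * N(N-1)/2) strongest pairs as edges.

    Ties at the cutoff are broken by ascending (row, column) index, so the
    result is deterministic.  A 58-node matrix at cost 0.16 yields exactly
    264 edges.
    """
    values = mi.values if isinstance(mi, MIMatrix) else np.asarray(mi, dtype=float)
    n = values.shape[0]
    if not (0 < cost <= 1):
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    iu, ju = np.triu_indices(n, k=1)
    npairs = iu.size
    k = int(round(cost * npairs))
    adj = np.zeros((n, n), dtype=np.uint8)
    if k > 0:
        # primary key: descending value; ties: ascending (row, col)
        order = np.lexsort((ju, iu, -values[iu, ju]))[:k]
        adj[iu[order], ju[order]] = 1
        adj = adj | adj.T
    return AdjacencyGraph(adj)


def shortest_path_lengths(g: AdjacencyGraph) -> np.ndarray:
    """All-pairs BFS hop counts; inf for disconnected pairs, 0 on the diagonal."""
    if g.n_edges == 0:
        d = np.full((g.n, g.n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    sp = scipy.sparse.csr_matrix(g.adj)
    return scipy.sparse.csgraph.shortest_path(sp, method="D", unweighted=True, directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: AdjacencyGraph) -> float:
    """Mean over ordered pairs of inverse shortest path length (1/inf = 0)."""
    if g.n < 2:
        return 0.0
    return _efficiency_from_distances(shortest_path_lengths(g))


def nodal_efficiency(g: AdjacencyGraph) -> np.ndarray:
    """Enodal(i) = (1/(N-1)) sum_{j != i} 1/L(i, j); its mean equals Eglob."""
    if g.n < 2:
        return np.zeros(g.n)
    d = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (g.n - 1)


def local_efficiency(g: AdjacencyGraph) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph.

    Nodes with fewer than 2 neighbors contribute 0 (their neighbor subgraph
    has no pairs).
    """
    if g.n < 1:
        return 0.0
    total = 0.0
    for i in range(g.n):
        nbrs = np.flatnonzero(g.adj[i])
        if nbrs.size < 2:
            continue
        sub = AdjacencyGraph(g.adj[np.ix_(nbrs, nbrs)])
        total += global_efficiency(sub)
    return total / g.n


def clustering_and_pathlength(g: AdjacencyGraph) -> tuple[float, float]:
    """Watts-Strogatz mean clustering Cp and characteristic path length Lp.

    Cp averages per-node triangle density (degree < 2 contributes 0).  Lp is
    the mean *finite* shortest path over connected ordered pairs; a graph
    with no connected pair has undefined Lp (NaN, with a warning).
    """
    if g.n < 3:
        raise ValueError("clustering requires at least 3 nodes")
    a = g.adj.astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    cp = float(c.mean())

    d = shortest_path_lengths(g)
    off = ~np.eye(g.n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        warnings.warn("fully disconnected graph: Lp is undefined")
        return cp, float("nan")
    lp = float(d[finite].mean())
    return cp, lp


def cost_efficiency_curve(eglob: MetricCurve) -> tuple[MetricCurve, float, float]:
    """CE(C) = Eglob(C) - C pointwise; returns (curve, maxCE, argmax cost).

    Ties in the maximum resolve to the lowest cost.
    """
    ce = eglob.values - eglob.costs
    curve = MetricCurve(
        "CE", eglob.costs, ce, eglob.subject_id, eglob.condition, eglob.band
    )
    imax = int(np.argmax(ce))  # argmax returns the first (lowest-cost) maximum
    return curve, float(ce[imax]), float(eglob.costs[imax])


def random_graph_matched(n: int, m: int, seed: int | None = None) -> AdjacencyGraph:
    """Uniform simple graph with exactly n nodes and m edges (G(n, m))."""
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"edge count {m} outside [0, {max_m}] for n={n}")
    gx = nx.gnm_random_graph(n, m, seed=seed)
    return AdjacencyGraph(nx.to_numpy_array(gx, nodelist=range(n)))


def regular_lattice_matched(n: int, m: int) -> AdjacencyGraph:
    """Ring lattice with exactly m edges.

    Each node is connected to its k/2 nearest neighbors on each side, where
    k = floor(2m/n) rounded down to even; the remaining edges are placed
    deterministically at the next-nearest free ring distance in node-index
    order, so the construction is fully reproducible.
    """
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"edge count {m} outside [0, {max_m}] for n={n}")
    adj = np.zeros((n, n), dtype=np.uint8)

    def add(i: int, j: int) -> bool:
        if i == j or adj[i, j]:
            return False
        adj[i, j] = adj[j, i] = 1
        return True

    count = 0
    k = (2 * m // n) // 2 * 2  # floor to even
    half = k // 2
    for d in range(1, half + 1):
        for i in range(n):
            if count < m and add(i, (i + d) % n):
                count += 1
    d = half + 1
    while count < m and d < n:
        for i in range(n):
            if count >= m:
                break
            if add(i, (i + d) % n):
                count += 1
        d += 1
    return AdjacencyGraph(adj)


def watts_strogatz_matched(n: int, m: int, p: float, seed: int | None = None) -> AdjacencyGraph:
    """Watts-Strogatz small-world graph with exactly m edges.

    Starts from :func:`regular_lattice_matched` and rewires each edge with
    probability ``p``: the edge (u, v) is replaced by (u, w) with w drawn
    uniformly among non-neighbors of u.  Edge count is preserved exactly.
    """
    if not (0 <= p <= 1):
        raise ValueError("rewiring probability must be in [0, 1]")
    g = regular_lattice_matched(n, m)
    adj = g.adj.copy()
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    for u, v in zip(iu.tolist(), ju.tolist()):
        if rng.random() >= p:
            continue
        candidates = np.flatnonzero((adj[u] == 0))
        candidates = candidates[candidates != u]
        if candidates.size == 0:
            continue
        w = int(rng.choice(candidates))
        adj[u, v] = adj[v, u] = 0
        adj[u, w] = adj[w, u] = 1
    return AdjacencyGraph(adj)


@dataclass
class NullEnsemble:
    """Matched random and regular null graphs for one (n, m), with summaries."""

    n: int
    m: int
    random_graphs: list = field(default_factory=list)
    regular_graphs: list = field(default_factory=list)
    mean_eglob_random: float = np.nan
    mean_elocal_random: float = np.nan
    mean_cp_random: float = np.nan
    mean_lp_random: float = np.nan
    mean_eglob_regular: float = np.nan
    mean_elocal_regular: float = np.nan
    mean_cp_regular: float = np.nan
    mean_lp_regular: float = np.nan


def build_null_ensemble(
    n: int, m: int, n_draws: int = 20, seed: int | None = None
) -> NullEnsemble:
    """Generate ``n_draws`` random and regular matched nulls and summarize.

    The regular (ring-lattice) construction is deterministic, so its members
    are identical; the ensemble still carries ``n_draws`` of them to mirror
    the random side.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_draws)]
    randoms = [random_graph_matched(n, m, s) for s in child_seeds]
    regular = regular_lattice_matched(n, m)
    regulars = [regular] * n_draws

    def summarize(graphs):
        eg, el, cp, lp = [], [], [], []
        for g in graphs:
            eg.append(global_efficiency(g))
            el.append(local_efficiency(g))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c, l = clustering_and_pathlength(g)
            cp.append(c)
            lp.append(l)
        return (float(np.mean(eg)), float(np.mean(el)), float(np.mean(cp)), float(np.mean(lp)))

    er, lr, cr, pr = summarize(randoms)
    ee, le, ce_, pe = summarize([regular])
    return NullEnsemble(
        n=n,
        m=m,
        random_graphs=randoms,
        regular_graphs=regulars,
        mean_eglob_random=er,
        mean_elocal_random=lr,
        mean_cp_random=cr,
        mean_lp_random=pr,
        mean_eglob_regular=ee,
        mean_elocal_regular=le,
        mean_cp_regular=ce_,
        mean_lp_regular=pe,
    )


def sigma_small_worldness(g: AdjacencyGraph, nulls: NullEnsemble) -> float:
    """sigma = (Cp/<Cp_rand>) / (Lp/<Lp_rand>), means over the random nulls.

    Greater than 1 for small-world organization.  NaN if the random
    clustering is zero or any path length is undefined.
    """
    if (nulls.n, nulls.m) != (g.n, g.n_edges):
        raise ValueError(
            f"null ensemble (n={nulls.n}, m={nulls.m}) does not match graph "
            f"(n={g.n}, m={g.n_edges})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cp, lp = clustering_and_pathlength(g)
    if not np.isfinite(lp) or nulls.mean_cp_random == 0 or not np.isfinite(nulls.mean_lp_random):
        warnings.warn("sigma undefined: zero random clustering or undefined path length")
        return float("nan")
    gamma = cp / nulls.mean_cp_random
    lam = lp / nulls.mean_lp_random
    return float(gamma / lam)


@dataclass
class RegimeInterval:
    """Contiguous cost interval on which a band shows small-world behavior."""

    band: str
    c_low: float
    c_high: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not (self.c_low < self.c_high or self.c_low == self.c_high):
            raise ValueError("invalid regime bounds")


def small_world_regime(
    eglob: MetricCurve,
    elocal: MetricCurve,
    nulls_per_cost: list[NullEnsemble],
    band: str = "",
) -> RegimeInterval:
    """Maximal contiguous cost interval of small-world behavior.

    At each grid cost the empirical curves must satisfy, strictly,
    ``<Eglob_regular> < Eglob < <Eglob_random>`` and
    ``<Elocal_random> < Elocal < <Elocal_regular>``.  The interval starts at
    the lowest qualifying cost and extends while the criteria hold;
    ``valid=False`` when no grid point qualifies (the rule under which a
    band is excluded from further analysis).
    """
    costs = eglob.costs
    if len(nulls_per_cost) != costs.size or not np.array_equal(costs, elocal.costs):
        raise ValueError("curves and null ensembles must share the cost grid")
    ok = np.zeros(costs.size, dtype=bool)
    for idx, nl in enumerate(nulls_per_cost):
        ok[idx] = (
            nl.mean_eglob_regular < eglob.values[idx] < nl.mean_eglob_random
            and nl.mean_elocal_random < elocal.values[idx] < nl.mean_elocal_regular
        )
    if not ok.any():
        return RegimeInterval(band=band, c_low=float("nan"), c_high=float("nan"), valid=False)
    start = int(np.argmax(ok))
    end = start
    while end + 1 < costs.size and ok[end + 1]:
        end += 1
    return RegimeInterval(band=band, c_low=float(costs[start]), c_high=float(costs[end]), valid=True)


def metric_curves(
    mi: MIMatrix | np.ndarray,
    costs: np.ndarray,
    subject_id: str = "",
    condition: str = "",
    band: str = "",
) -> dict[str, MetricCurve]:
    """Threshold one association matrix over a cost grid and compute curves.

    Returns Eglob, Elocal, Cp, Lp and CE curves aligned to ``costs``; the
    thresholded graphs are nested, so Eglob and Elocal are non-decreasing in
    cost.
    """
    costs = np.asarray(costs, dtype=float)
    eg = np.empty(costs.size)
    el = np.empty(costs.size)
    cp = np.empty(costs.size)
    lp = np.empty(costs.size)
    for idx, c in enumerate(costs):
        g = threshold_by_cost(mi, float(c))
        eg[idx] = global_efficiency(g)
        el[idx] = local_efficiency(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cp[idx], lp[idx] = clustering_and_pathlength(g)
    tags = dict(subject_id=subject_id, condition=condition, band=band)
    eglob = MetricCurve("Eglob", costs, eg, **tags)
    ce_curve, _, _ = cost_efficiency_curve(eglob)
    return {
        "Eglob": eglob,
        "Elocal": MetricCurve("Elocal", costs, el, **tags),
        "Cp": MetricCurve("Cp", costs, cp, **tags),
        "Lp": MetricCurve("Lp", costs, lp, **tags),
        "CE": ce_curve,
    }
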