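"""Topological metrics on binary brain networks.

Global metrics: clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc, and the small-world triplet
gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>, sigma = gamma / lambda,
where <.>_rand averages over an ensemble of degree-preserving random
networks (Maslov-Sneppen double-edge swaps). Nodal metrics: degree, nodal
global efficiency and nodal local efficiency.

Every metric is computed across the sparsity grid and summarised by the
area under the metric-versus-sparsity curve (trapezoidal rule), yielding
one threshold-independent scalar per metric (aCp, aLp, anodalEloc, ...).

Distances are hop counts from breadth-first search. Pairs left disconnected
by thresholding are excluded from Lp by default (the count is recorded);
a harmonic-mean variant is available. Efficiencies treat 1/infinity as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .connectivity import ConnectivityMatrix
from .network import BinaryNetwork, SparsityGrid, check_admissibility, largest_component_fraction, threshold_by_sparsity

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc")
NODAL_METRICS = ("nodalDeg", "nodalEglob", "nodalEloc")


# ---------------------------------------------------------------------------
# elementary metrics


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp.

    C_i = 2 e_i / (k_i (k_i - 1)) where e_i counts edges among the
    neighbours of i; nodes with degree < 2 get C_i = 0. The triangle count
    e_i is diag(A^3)/2.
    """
    a = net.adjacency.astype(float)
    k = a.sum(axis=0)
    closed_walks = ((a @ a) * a).sum(axis=1)  # diag(A^3) = 2 * e_i per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed_walks / denom, 0.0)
    return c, float(c.mean())


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances of a dense 0/1 adjacency by simultaneous BFS.

    Each iteration advances every source's frontier by one hop via a single
    matrix product; unreachable pairs stay +inf.
    """
    a = adj.astype(float)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.astype(float)
    d = 0
    while True:
        d += 1
        new = ((frontier @ a) > 0) & ~reached
        if not new.any():
            break
        dist[new] = d
        reached |= new
        frontier = new.astype(float)
    return dist


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs hop distances by BFS; unreachable pairs are +inf."""
    return _hop_distances(net.adjacency)


def characteristic_path_length(
    dist: np.ndarray, disconnected: str = "exclude"
) -> tuple[float, int]:
    """Mean shortest path length Lp and the number of excluded ordered pairs.

    ``disconnected='exclude'`` averages the finite off-diagonal distances
    only; ``'harmonic'`` returns the harmonic mean of all off-diagonal
    distances (1/inf = 0), which penalises disconnection instead of
    ignoring it.
    """
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    n_excluded = int((~finite).sum())
    if disconnected == "exclude":
        if not finite.any():
            raise ValueError("no finite distances: graph has no edges")
        return float(d[finite].mean()), n_excluded
    if disconnected == "harmonic":
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
        mean_inv = inv.mean()
        if mean_inv == 0:
            raise ValueError("no finite distances: graph has no edges")
        return float(1.0 / mean_inv), n_excluded
    raise ValueError(f"disconnected must be 'exclude' or 'harmonic', got {disconnected!r}")


def nodal_global_efficiency(dist: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes (1/inf = 0)."""
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(dist: np.ndarray) -> float:
    """Network global efficiency: mean of the nodal global efficiencies."""
    return float(nodal_global_efficiency(dist).mean())


def local_efficiency(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean Eloc.

    The local efficiency of node i is the global efficiency of the subgraph
    induced on i's neighbours (0 when i has fewer than 2 neighbours).
    """
    a = net.adjacency
    n = a.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        e[i] = global_efficiency(_hop_distances(a[np.ix_(nbrs, nbrs)]))
    return e, float(e.mean())


# ---------------------------------------------------------------------------
# degree-preserving null model


def _swap_chunk(adj, edges, buf_idx, buf_flip, need):
    """Apply one chunk of pre-drawn swap proposals sequentially, in place.

    Returns (successes, attempts consumed). Kept numba-compatible; the
    JIT and pure-Python paths produce identical results because all
    randomness is drawn by the caller.
    """
    success = 0
    used = 0
    for t in range(buf_idx.shape[0]):
        used += 1
        e1 = buf_idx[t, 0]
        e2 = buf_idx[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if buf_flip[t]:
            c, d = d, c
        # proposed replacement edges: (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        success += 1
        if success == need:
            break
    return success, used


try:  # optional JIT; results are identical either way
    from numba import njit

    _swap_chunk = njit(cache=True)(_swap_chunk)
except ImportError:  # pragma: no cover - depends on environment
    pass


def _double_edge_swaps(
    adj: np.ndarray, edges: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> bool:
    """In-place Maslov-Sneppen rewiring; returns False if the swap budget
    could not be met (e.g. star graphs admit no legal swap)."""
    n_edges = len(edges)
    success = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    # draw randomness in chunks to keep the rejection loop cheap
    chunk = 4096
    while success < n_swaps and attempts < max_attempts:
        buf_idx = rng.integers(0, n_edges, size=(chunk, 2))
        buf_flip = rng.random(chunk) < 0.5
        got, used = _swap_chunk(
            adj, edges, buf_idx[: max_attempts - attempts], buf_flip, n_swaps - success
        )
        success += got
        attempts += used
    return success >= n_swaps


def degree_preserving_randomize(
    net: BinaryNetwork,
    n_nets: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    swap_factor: int = 10,
) -> list[BinaryNetwork]:
    """Ensemble of random networks with the input's exact degree sequence.

    Each network starts from the input and applies ``swap_factor *
    edge_count`` successful double-edge swaps. Graphs admitting no legal
    swap (e.g. stars) are returned as copies with a warning.
    """
    if net.edge_count < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    base_edges = np.stack(
        [iu[net.adjacency[iu, ju] > 0], ju[net.adjacency[iu, ju] > 0]], axis=1
    )
    n_swaps = swap_factor * net.edge_count
    ensemble = []
    exhausted = 0
    for _ in range(n_nets):
        adj = net.adjacency.copy()
        edges = base_edges.copy()
        if not _double_edge_swaps(adj, edges, n_swaps, rng):
            exhausted += 1
        ensemble.append(BinaryNetwork(adjacency=adj, sparsity=net.sparsity))
    if exhausted:
        warnings.warn(
            f"{exhausted}/{n_nets} null networks did not reach the swap budget "
            "(few or no legal swaps); they may retain input structure",
            stacklevel=2,
        )
    return ensemble


def normalized_smallworld(
    net: BinaryNetwork,
    ensemble: list[BinaryNetwork],
    disconnected: str = "exclude",
) -> tuple[float, float, float]:
    """gamma, lambda, sigma of a network against its null ensemble."""
    if not ensemble:
        raise ValueError("null ensemble is empty")
    _, cp = clustering(net)
    lp, _ = characteristic_path_length(shortest_paths(net), disconnected)
    cp_rand = np.mean([clustering(g)[1] for g in ensemble])
    lp_rand = np.mean(
        [characteristic_path_length(shortest_paths(g), disconnected)[0] for g in ensemble]
    )
    if cp_rand <= 0 or lp_rand <= 0:
        raise ValueError("null ensemble mean Cp/Lp must be positive")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return float(gamma), float(lam), float(gamma / lam)


# ---------------------------------------------------------------------------
# curves across the sparsity grid


@dataclass
class MetricCurve:
    """One metric's values across the sparsity grid (optionally per node)."""

    grid: SparsityGrid
    values: np.ndarray
    metric_name: str
    node_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("curve length must match grid length")


@dataclass
class AucSummary:
    """Area under a metric curve over the sparsity grid."""

    metric_name: str
    auc_value: float
    node_index: int | None = None


def auc_of_curve(curve: MetricCurve) -> AucSummary:
    """Trapezoidal area under the curve; exact for piecewise-linear curves."""
    s = curve.grid.values
    if len(s) < 2:
        raise ValueError("AUC needs at least 2 grid points")
    auc = float(np.trapezoid(curve.values, s))
    return AucSummary(
        metric_name=f"a{curve.metric_name}", auc_value=auc, node_index=curve.node_index
    )


@dataclass
class SubjectCurves:
    """All metric curves for one subject across the sparsity grid."""

    grid: SparsityGrid
    global_values: dict[str, np.ndarray]  # metric -> (n_sparsity,)
    nodal_values: dict[str, np.ndarray]  # metric -> (n_sparsity, n_nodes)
    component_fraction: np.ndarray
    admissible_degree: np.ndarray
    admissible_smallworld: np.ndarray
    edge_counts: np.ndarray
    lp_excluded_pairs: np.ndarray

    def global_curve(self, metric: str) -> MetricCurve:
        return MetricCurve(self.grid, self.global_values[metric], metric)

    def nodal_curve(self, metric: str, node: int) -> MetricCurve:
        return MetricCurve(self.grid, self.nodal_values[metric][:, node], metric, node)

    def iter_curves(self) -> Iterator[MetricCurve]:
        for m in self.global_values:
            yield self.global_curve(m)
        for m, vals in self.nodal_values.items():
            for node in range(vals.shape[1]):
                yield self.nodal_curve(m, node)

    def auc(self) -> dict[str, float | np.ndarray]:
        """AUC of every curve: scalars for global metrics, length-N arrays
        for nodal metrics, keyed 'aCp', 'anodalDeg', ..."""
        s = self.grid.values
        out: dict[str, float | np.ndarray] = {
            f"a{m}": float(np.trapezoid(v, s)) for m, v in self.global_values.items()
        }
        for m, v in self.nodal_values.items():
            out[f"a{m}"] = np.trapezoid(v, s, axis=0)
        return out


def metric_curves(
    cm: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    n_null: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    disconnected: str = "exclude",
    degree_log_base: str = "e",
    swap_factor: int = 10,
    metrics_subset: tuple[str, ...] | None = None,
) -> SubjectCurves:
    """Threshold one connectivity matrix across the grid and compute all
    global and nodal metrics (with null-model normalization when
    ``n_null`` > 0; with ``n_null=0`` gamma/lambda/sigma are skipped and the
    small-world admissibility flag is left false).

    ``metrics_subset`` restricts the computation to the named metrics (from
    GLOBAL_METRICS and NODAL_METRICS), e.g. ``("Cp", "Lp")`` for
    simulation studies that only need the two small-world headline curves.
    """
    grid = grid or SparsityGrid()
    svals = grid.values
    n_s = len(svals)
    n = cm.n_rois
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    null_seeds = seed_seq.spawn(n_s)

    if metrics_subset is None:
        want = set(GLOBAL_METRICS) | set(NODAL_METRICS)
    else:
        unknown = set(metrics_subset) - set(GLOBAL_METRICS) - set(NODAL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        want = set(metrics_subset)
    if n_null == 0:
        want -= {"gamma", "lambda", "sigma"}
    need_null = bool(want & {"gamma", "lambda", "sigma"})
    need_dist = bool(want & {"Lp", "Eglob", "nodalEglob"})
    need_eloc = bool(want & {"Eloc", "nodalEloc"})

    g: dict[str, np.ndarray] = {m: np.zeros(n_s) for m in GLOBAL_METRICS if m in want}
    nod = {m: np.zeros((n_s, n)) for m in NODAL_METRICS if m in want}
    comp = np.zeros(n_s)
    adm_deg = np.zeros(n_s, dtype=bool)
    adm_sw = np.zeros(n_s, dtype=bool)
    ecount = np.zeros(n_s, dtype=int)
    excl = np.zeros(n_s, dtype=int)

    for k, s in enumerate(svals):
        net = threshold_by_sparsity(cm, float(s))
        if "Cp" in want or need_null:
            _, cp = clustering(net)
            if "Cp" in want:
                g["Cp"][k] = cp
        if need_dist or need_null:
            dist = shortest_paths(net)
            lp, n_excl = characteristic_path_length(dist, disconnected)
            excl[k] = n_excl
            if "Lp" in want:
                g["Lp"][k] = lp
            if "Eglob" in want or "nodalEglob" in want:
                eglob_i = nodal_global_efficiency(dist)
                if "Eglob" in want:
                    g["Eglob"][k] = eglob_i.mean()
                if "nodalEglob" in want:
                    nod["nodalEglob"][k] = eglob_i
        if need_eloc:
            eloc_i, eloc = local_efficiency(net)
            if "Eloc" in want:
                g["Eloc"][k] = eloc
            if "nodalEloc" in want:
                nod["nodalEloc"][k] = eloc_i
        if "nodalDeg" in want:
            nod["nodalDeg"][k] = net.degrees
        sigma = 0.0
        if need_null:
            ensemble = degree_preserving_randomize(
                net, n_nets=n_null, seed=null_seeds[k], swap_factor=swap_factor
            )
            gamma, lam, sigma = normalized_smallworld(net, ensemble, disconnected)
            if "gamma" in want:
                g["gamma"][k] = gamma
            if "lambda" in want:
                g["lambda"][k] = lam
            if "sigma" in want:
                g["sigma"][k] = sigma
        comp[k] = largest_component_fraction(net)
        adm_deg[k], adm_sw[k] = check_admissibility(net, sigma, degree_log_base)
        ecount[k] = net.edge_count

    return SubjectCurves(
        grid=grid,
        global_values=g,
        nodal_values=nod,
        component_fraction=comp,
        admissible_degree=adm_deg,
        admissible_smallworld=adm_sw,
        edge_counts=ecount,
        lp_excluded_pairs=excl,
    )
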