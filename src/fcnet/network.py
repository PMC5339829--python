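"""Binary network construction by sparsity thresholding.

A connectivity matrix is binarized by keeping the K strongest positive
edges, where K is set by a *sparsity* value s: K = round-half-up of
s * N(N-1)/2. The analysis sweeps a grid of sparsities (default 0.10 to
0.34 in steps of 0.01, 25 points) rather than committing to one threshold.

Two admissibility criteria are evaluated per thresholded network: the mean
degree should exceed 2*log(N) (log base configurable; the convention in the
literature is ambiguous) and the small-worldness sigma should exceed 1.1.
Failures are recorded, not fatal — the full grid is always analysed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix


def round_half_up(x: float) -> int:
    """Deterministic commercial rounding: 0.5 always rounds up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SparsityGrid:
    """Inclusive arithmetic grid of sparsity values."""

    s_min: float = 0.10
    s_max: float = 0.34
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("require 0 < s_min <= s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        grid = self.s_min + self.step * np.arange(n)
        # guard against float drift pushing the last point past s_max
        return np.round(grid[grid <= self.s_max + 1e-12], 12)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class BinaryNetwork:
    """Undirected 0/1 adjacency at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    saturated: bool = False
    admissible_degree: bool | None = None
    admissible_smallworld: bool | None = None
    roi_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be a symmetric 0/1 matrix")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())


def target_edge_count(n_nodes: int, sparsity: float) -> int:
    """K = round_half_up(s * N(N-1)/2); e.g. N=90, s=0.10 -> 401."""
    return round_half_up(sparsity * n_nodes * (n_nodes - 1) / 2.0)


def threshold_by_sparsity(cm: ConnectivityMatrix, sparsity: float) -> BinaryNetwork:
    """Keep the K strongest positive edges of a non-negative connectivity matrix.

    Ties in z are broken by ascending (row, column) index so the edge set is
    deterministic. If the matrix holds fewer than K positive entries, all of
    them are kept and the network is flagged ``saturated`` (with a warning).
    """
    if not (0 < sparsity < 1):
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    z = cm.z_values
    if np.any(z < 0):
        raise ValueError("connectivity must be non-negative; apply positive_part first")
    n = cm.n_rois
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    k_target = target_edge_count(n, sparsity)
    # stable order: z descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -vals))
    positive = vals[order] > 0
    keep = order[positive][:k_target]
    saturated = keep.size < k_target
    if saturated:
        warnings.warn(
            f"only {keep.size} positive edges available for target {k_target} "
            f"at sparsity {sparsity:g}; network saturated",
            stacklevel=2,
        )
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, sparsity=sparsity, saturated=saturated, roi_labels=cm.roi_labels
    )


def largest_component_fraction(net: BinaryNetwork) -> float:
    """Size of the largest connected component over the number of nodes."""
    n_comp, labels = connected_components(
        csr_matrix(net.adjacency), directed=False
    )
    if n_comp == 1:
        return 1.0
    sizes = np.bincount(labels)
    return float(sizes.max() / net.n_nodes)


_LOG = {"e": math.log, "10": math.log10, "2": math.log2}


def check_admissibility(
    net: BinaryNetwork, sigma: float, log_base: str = "e"
) -> tuple[bool, bool]:
    """Evaluate (and record on ``net``) the two threshold-selection criteria.

    ``admissible_degree``: mean degree strictly greater than 2*log(N) in the
    configured base. ``admissible_smallworld``: sigma strictly greater than 1.1.
    """
    if log_base not in _LOG:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}, got {log_base!r}")
    deg_ok = net.mean_degree > 2.0 * _LOG[log_base](net.n_nodes)
    sw_ok = bool(sigma > 1.1)
    net.admissible_degree = bool(deg_ok)
    net.admissible_smallworld = sw_ok
    return bool(deg_ok), sw_ok
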