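"""Topological complexity of functional connectivity graphs.

A weighted connectivity matrix is built from pairwise Pearson correlations
of envelope series (self-loops and negative edges removed), binarised at a
sweep of proportional edge-density thresholds, and summarised by two
measures per graph: algebraic connectivity (the Fiedler value, the
second-smallest Laplacian eigenvalue) and the LZ76 phrase count of the
flattened adjacency matrix. Each measure is reported as a nine-point curve
over thresholds 10%..90% together with its trapezoid integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_prep import EnvelopeSeries
from .temporal import lz76_dictionary_size

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "ThresholdCurve",
    "connectivity_matrix",
    "proportional_binarise",
    "algebraic_connectivity",
    "graph_lz",
    "threshold_curve",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (10, 20, 30, 40, 50, 60, 70, 80, 90)
_ZERO_TOL = 1e-9


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative correlation-weight matrix with zero diagonal."""

    weights: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero (no self-loops)")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryGraph:
    """Simple undirected graph as a {0,1} adjacency matrix."""

    adjacency: np.ndarray
    threshold_k: float | None = None
    realised_density: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ThresholdCurve:
    thresholds: list[int]
    values: list[float]
    integral: float
    measure: str
    degenerate: bool = False


def connectivity_matrix(env: EnvelopeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of envelope rows, filtered to a simple graph.

    The diagonal is zeroed and negative correlations are set to zero (the
    common convention in network neuroscience). Zero-variance rows have
    undefined correlations; these are set to 0 with a warning.
    """
    vals = env.values
    x, t = vals.shape
    if x < 3 or t < 8:
        raise ValueError("need at least 3 regions and 8 timepoints")
    zero_var = vals.std(axis=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance row(s): correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 0.0)
    corr[corr < 0] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(weights=corr, region_ids=list(env.region_ids))


def proportional_binarise(matrix: ConnectivityMatrix, k: float) -> BinaryGraph:
    """Keep the strongest k% of possible edges: weight >= the (100-k)th percentile.

    The percentile is taken over the upper-triangular off-diagonal weights;
    ties at the cutoff are all included, so the realised density can slightly
    exceed k%. An all-equal weight matrix is degenerate (all edges retained)
    and is flagged with a warning.
    """
    if not 0 < k < 100:
        raise ValueError("threshold k must be in (0, 100)")
    w = matrix.weights
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = w[iu]
    if np.ptp(upper) == 0:
        warnings.warn("all weights equal: degenerate threshold", RuntimeWarning,
                      stacklevel=2)
    # cutoff = weight of the ceil(k% * E)-th strongest edge, so at least k% of
    # possible edges survive; ties at the cutoff are all included
    n_keep = int(np.ceil(k / 100 * upper.size))
    cutoff = np.sort(upper)[::-1][n_keep - 1]
    adj = ((w >= cutoff) & ~np.eye(n, dtype=bool)).astype(np.uint8)
    density = adj[iu].sum() / upper.size
    return BinaryGraph(adjacency=adj, threshold_k=k, realised_density=float(density))


def algebraic_connectivity(graph: BinaryGraph) -> float:
    """Fiedler value: second-smallest eigenvalue of the graph Laplacian.

    Zero iff the graph is disconnected; for the complete graph K_n it equals
    n. Computed by dense symmetric eigendecomposition; values below 1e-9 are
    reported as exactly 0.
    """
    a = graph.adjacency.astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    eigvals = np.linalg.eigvalsh(lap)
    lam2 = float(eigvals[1])
    return 0.0 if lam2 < _ZERO_TOL else lam2


def graph_lz(graph: BinaryGraph) -> int:
    """LZ76 phrase count of the row-major flattened adjacency matrix."""
    return lz76_dictionary_size(graph.adjacency.reshape(-1))


_MEASURES = {"algebraic_connectivity": algebraic_connectivity, "graph_lz": graph_lz}


def threshold_curve(
    matrix: ConnectivityMatrix,
    measure: str,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> ThresholdCurve:
    """Evaluate a graph measure across the threshold sweep and integrate.

    The integral uses the trapezoid rule over the threshold axis (spacing 10
    in threshold-percent units for the default sweep), so a measure constant
    at c integrates to c * 80.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    fn = _MEASURES[measure]
    degenerate = np.ptp(matrix.weights[np.triu_indices(matrix.n_nodes, k=1)]) == 0
    values = [float(fn(proportional_binarise(matrix, k))) for k in thresholds]
    integral = float(np.trapezoid(values, x=np.asarray(thresholds, dtype=float)))
    return ThresholdCurve(
        thresholds=list(thresholds),
        values=values,
        integral=integral,
        measure=measure,
        degenerate=bool(degenerate),
    )
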