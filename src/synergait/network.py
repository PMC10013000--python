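"""Per-synergy muscle networks: outer-product connectivity, density,
and weighted transitivity.

Each synergy's weighting coefficients — first scaled by the summed integral
of its temporal patterns over the four support levels, to remove overall
amplitude effects — define a muscle-by-muscle connectivity matrix as the
outer product of the scaled weight vector with itself. Edges below an
absolute threshold of 5e-5 are removed, the diagonal (self-connections) is
excluded, and two topology summaries are reported per synergy: density (the
fraction of possible muscle pairs connected) and a weighted transitivity
(geometric-mean triangle weight relative to connected triples), whose scale
is set by the edge weights rather than bounded at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import LEVELS
from .synergy import SynergyModel

DEFAULT_THRESHOLD = 5e-5

#: Cycle fraction of one normalized sample; pattern integrals are sample
#: sums times this, so a constant pattern of 1 integrates to 1 per level.
_CYCLE_DX = 1.0 / 200.0


@dataclass
class SynergyNetwork:
    """One synergy's thresholded muscle network with its summary metrics."""

    synergy: int
    nodes: list[str]
    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if np.any(A < 0):
            raise ValueError("edge weights must be non-negative")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def density(self) -> float:
        return density(self)

    @property
    def transitivity(self) -> float:
        return transitivity(self)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = self.adjacency[i, j]
                if w > 0:
                    out.append((self.nodes[i], self.nodes[j], float(w)))
        return out


def scale_weightings(model: SynergyModel) -> np.ndarray:
    """Weighting coefficients scaled by the summed pattern integrals.

    Column i of W is divided by ``sum over levels of integral(P_level_i)``,
    the integral taken over the normalized cycle (so a constant pattern of 1
    contributes 1 per level). The factorisation's scale gauge (unit-maximum
    weight columns with the compensating rescale in P) is re-imposed first,
    so the result depends only on the product W P' — doubling all patterns
    while halving the weights leaves the scaled weightings, and hence the
    networks, unchanged.
    """
    cmax = model.W.max(axis=0)
    if np.any(cmax <= 0):
        raise ValueError("cannot scale weightings: some weight column is all zero")
    W = model.W / cmax
    integrals = np.zeros(model.n)
    for lv in LEVELS:
        if lv in model.P:
            integrals += cmax * model.P[lv].sum(axis=0) * _CYCLE_DX
    zero = np.flatnonzero(integrals <= 0)
    if zero.size:
        raise ValueError(
            "zero total pattern integral for synergy index "
            + ", ".join(str(i) for i in zero)
        )
    return W / integrals


def build_network(
    scaled_w_col: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    nodes: list[str] | None = None,
    synergy: int = 0,
) -> SynergyNetwork:
    """Outer-product connectivity of one synergy's scaled weight vector.

    ``adjacency[i, j] = w[i] * w[j]`` for i != j, with entries below the
    absolute ``threshold`` set to zero.
    """
    w = np.asarray(scaled_w_col, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("scaled weightings must be non-negative")
    A = np.outer(w, w)
    np.fill_diagonal(A, 0.0)
    A[A < threshold] = 0.0
    if nodes is None:
        nodes = [f"m{i + 1}" for i in range(w.size)]
    return SynergyNetwork(synergy=synergy, nodes=list(nodes), adjacency=A,
                          threshold=threshold)


def density(net: SynergyNetwork) -> float:
    """Fraction of possible undirected muscle pairs with a surviving edge."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(net.adjacency, k=1)))
    return n_edges / (n * (n - 1) / 2)


def transitivity(net: SynergyNetwork) -> float:
    """Weighted transitivity: geometric-mean triangle weight over triples.

    Numerator: sum over all ordered node triples of the geometric mean of
    the three edge weights of closed triangles (equivalently the trace of
    the cubed element-wise cube-root adjacency). Denominator: the number of
    connected triples — paths of length 2 in the thresholded binary
    topology, ``sum_i k_i (k_i - 1)`` with ``k_i`` the binary degree.
    Returns 0 when no connected triples exist. Because the numerator keeps
    the edge-weight scale, values are of the order of the edge weights (the
    study's networks report transitivities around 1e-5).
    """
    if net.n_nodes < 3:
        raise ValueError("transitivity needs at least 3 nodes")
    A = net.adjacency
    W3 = np.cbrt(A)
    numerator = float(np.trace(W3 @ W3 @ W3))
    k = (A > 0).sum(axis=1)
    denominator = float((k * (k - 1)).sum())
    if denominator == 0:
        return 0.0
    return numerator / denominator


def networks_from_model(
    model: SynergyModel, threshold: float = DEFAULT_THRESHOLD
) -> list[SynergyNetwork]:
    """Build the thresholded muscle network of every synergy in a model."""
    scaled = scale_weightings(model)
    nodes = model.channels or None
    return [build_network(scaled[:, i], threshold=threshold, nodes=nodes, synergy=i + 1)
            for i in range(model.n)]
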