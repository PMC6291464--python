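"""Weighted undirected network topology: clustering, path length, small-worldness.

The network is built directly from the PLI matrix with no thresholding or
binarization.  Nodal clustering follows the Onnela geometric-mean-of-weights
form with the k_i(k_i - 1) denominator used by the Brain Connectivity
Toolbox (the strength-based denominator printed in some papers degenerates
for node strengths <= 1 and is available behind ``denominator="strength"``
for comparison only).  Path length uses edge length = 1/weight.  The
small-world coefficient normalizes C and L by their means over an ensemble
of weight-shuffled surrogates:

    SW = (C / C_rand) / (L / L_rand)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import PLIMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "NetworkMetrics",
    "build_network",
    "nodal_clustering",
    "global_clustering",
    "char_path_length",
    "randomize_weights",
    "small_world",
]


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if w.size and w.min() < 0:
            raise ValueError("weights must be nonnegative")
        self.weights = 0.5 * (w + w.T)  # exact symmetry
        np.fill_diagonal(self.weights, 0.0)
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkMetrics:
    """Nodal/global clustering, path length, surrogate means and SW."""

    nodal_C: np.ndarray
    C: float
    L: float
    C_rand: float
    L_rand: float
    SW: float
    n_surrogates: int
    seed: int | None = None
    labels: list[str] = field(default_factory=list)


def build_network(matrix: PLIMatrix | np.ndarray,
                  labels: list[str] | None = None) -> WeightedNetwork:
    """Weights copied verbatim from the PLI matrix — no threshold, no binarization."""
    if isinstance(matrix, PLIMatrix):
        return WeightedNetwork(weights=matrix.values.copy(), labels=list(matrix.labels))
    w = np.asarray(matrix, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("input matrix is asymmetric")
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(w.shape[0])]
    return WeightedNetwork(weights=w.copy(), labels=list(labels))


def nodal_clustering(net: WeightedNetwork, denominator: str = "degree") -> np.ndarray:
    """Onnela weighted clustering per node.

    numerator_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) = diag((W^(1/3))^3)_i.
    ``denominator="degree"``: k_i (k_i - 1) with k_i = nonzero-neighbor count
    (nodes with k_i < 2 get C_i = 0).  ``"strength"``: s_i (s_i - 1) with
    s_i = sum_j w_ij — degenerate for s_i <= 1, kept for comparison.
    """
    if net.n < 3:
        raise ValueError("need at least 3 nodes for clustering")
    w = net.weights
    w13 = np.cbrt(w)
    numer = np.diag(w13 @ w13 @ w13)
    if denominator == "degree":
        k = np.count_nonzero(w, axis=1).astype(float)
        denom = k * (k - 1.0)
    elif denominator == "strength":
        s = w.sum(axis=1)
        denom = s * (s - 1.0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def global_clustering(net: WeightedNetwork, denominator: str = "degree") -> float:
    """Arithmetic mean of the nodal clustering coefficients."""
    return float(nodal_clustering(net, denominator).mean())


def char_path_length(net: WeightedNetwork, on_disconnected: str = "raise") -> float:
    """Mean shortest-path length over ordered node pairs, edge length = 1/weight.

    Zero-weight edges are treated as absent (infinite length).  A network
    with unreachable pairs raises by default; ``on_disconnected="reachable"``
    averages over the reachable pairs instead.
    """
    if net.n < 2:
        raise ValueError("need at least 2 nodes")
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(net.n, dtype=bool)
    d = dist[off]
    if np.isinf(d).any():
        if on_disconnected == "raise":
            raise ValueError("network is disconnected (unreachable node pairs)")
        if on_disconnected != "reachable":
            raise ValueError(f"unknown on_disconnected mode {on_disconnected!r}")
        d = d[np.isfinite(d)]
        if d.size == 0:
            raise ValueError("no reachable node pairs")
    return float(d.mean())


def randomize_weights(net: WeightedNetwork,
                      seed: int | np.random.Generator = 0) -> WeightedNetwork:
    """Surrogate: randomly permute the upper-triangle weights (multiset preserved)."""
    if net.n < 3:
        raise ValueError("need at least 3 nodes to randomize")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(net.n, k=1)
    vals = net.weights[iu]
    shuffled = rng.permutation(vals)
    w = np.zeros_like(net.weights)
    w[iu] = shuffled
    w = w + w.T
    return WeightedNetwork(weights=w, labels=list(net.labels))


def small_world(net: WeightedNetwork, n_surrogates: int = 50,
                seed: int | np.random.Generator = 0,
                denominator: str = "degree",
                max_resample: int = 20) -> NetworkMetrics:
    """C, L and SW = (C/C_rand)/(L/L_rand) against weight-shuffled surrogates.

    A surrogate that comes out disconnected under the 1/weight mapping is
    resampled (logged); fully positive inputs can never trigger this.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    nodal = nodal_clustering(net, denominator)
    c = float(nodal.mean())
    length = char_path_length(net)

    c_rand = np.empty(n_surrogates)
    l_rand = np.empty(n_surrogates)
    for k in range(n_surrogates):
        for attempt in range(max_resample):
            surr = randomize_weights(net, rng)
            try:
                l_rand[k] = char_path_length(surr)
            except ValueError:
                logger.info("surrogate %d disconnected (attempt %d); resampling",
                            k, attempt + 1)
                continue
            c_rand[k] = global_clustering(surr, denominator)
            break
        else:
            raise RuntimeError(f"could not draw a connected surrogate after "
                               f"{max_resample} attempts")

    c_rand_mean = float(c_rand.mean())
    l_rand_mean = float(l_rand.mean())
    sw = (c / c_rand_mean) / (length / l_rand_mean)
    return NetworkMetrics(nodal_C=nodal, C=c, L=length, C_rand=c_rand_mean,
                          L_rand=l_rand_mean, SW=float(sw),
                          n_surrogates=n_surrogates,
                          seed=seed if isinstance(seed, int) else None,
                          labels=list(net.labels))
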