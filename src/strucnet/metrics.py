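"""Topological metrics for binary networks.

Five graph measures: average clustering coefficient C_G, characteristic path
length I_G, small-worldness sigma = gamma / lambda against an analytic
Erdos-Renyi reference with matched size and mean degree (C_R = d/N,
I_R = log N / log d), Newman modularity Q, and global efficiency E_glob.

The reference values are closed-form expectations for a random graph of the
same N and average degree d: no random graph is actually generated.  The
logarithm base cancels in I_R; natural log is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from strucnet.construct import BinaryNetwork
from strucnet.modularity import modularity_newman


@dataclass
class MetricRecord:
    """Per-network metric values, one record per analyzed binary network.

    ``sigma = gamma / lambda_`` exactly as stored; ``frac_disconnected`` is
    the share of ordered node pairs with no connecting path (I_G averages
    only the finite distances).
    """

    N: int
    d: float
    C_G: float
    I_G: float
    C_R: float
    I_R: float
    gamma: float
    lambda_: float
    sigma: float
    Q: float
    E_glob: float
    frac_disconnected: float
    small_world: bool

    def to_dict(self) -> dict:
        return asdict(self)


def degree_sequence(network: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node degree vector and the average nodal degree d."""
    deg = network.degrees()
    return deg, (float(deg.mean()) if deg.size else 0.0)


def clustering_coefficient(network: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their average C_G.

    C_i = 2 * (triangles at i) / (k_i (k_i - 1)); nodes of degree < 2
    contribute 0 and are included in the average over all N nodes.
    """
    a = network.adjacency.astype(np.float64)
    deg = a.sum(axis=1)
    # diagonal of A^3 counts twice the triangles at each node
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c, (float(c.mean()) if c.size else 0.0)


def _distance_matrix(network: BinaryNetwork) -> np.ndarray:
    a = csr_matrix(network.adjacency)
    return shortest_path(a, method="D", unweighted=True, directed=False)


def characteristic_path_length(network: BinaryNetwork) -> tuple[float, float]:
    """Characteristic path length I_G and the disconnected-pair fraction.

    I_G is the mean shortest-path distance over connected ordered pairs
    (i != j); pairs in different components are excluded from the mean and
    reported as ``frac_disconnected``.
    """
    n = network.n_nodes
    if network.n_edges == 0:
        raise ValueError("path length undefined: network has no edges")
    d = _distance_matrix(network)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = n * (n - 1)
    frac_disconnected = 1.0 - finite.sum() / n_pairs
    return float(d[finite].mean()), float(frac_disconnected)


def global_efficiency(network: BinaryNetwork) -> float:
    """E_glob = mean over ordered pairs of 1/d_ij, with 1/inf = 0."""
    n = network.n_nodes
    if n < 2 or network.n_edges == 0:
        return 0.0
    d = _distance_matrix(network)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def random_reference(n_nodes: int, d: float) -> tuple[float, float]:
    """Analytic Erdos-Renyi reference values (C_R, I_R) = (d/N, log N / log d).

    Defined for N >= 2 and average degree d > 1 (log d must be positive).
    """
    if n_nodes < 2:
        raise ValueError(f"need N >= 2, got {n_nodes}")
    if d <= 1:
        raise ValueError(
            f"random reference undefined for average degree d = {d} <= 1"
        )
    return d / n_nodes, math.log(n_nodes) / math.log(d)


def small_worldness(network: BinaryNetwork) -> dict:
    """gamma = C_G/C_R, lambda = I_G/I_R, sigma = gamma/lambda.

    The single small-world test is sigma > 1.  Requires average degree > 1.
    """
    _, d = degree_sequence(network)
    _, c_g = clustering_coefficient(network)
    i_g, frac_disc = characteristic_path_length(network)
    c_r, i_r = random_reference(network.n_nodes, d)
    gamma = c_g / c_r
    lambda_ = i_g / i_r
    sigma = gamma / lambda_
    return {
        "C_G": c_g,
        "I_G": i_g,
        "C_R": c_r,
        "I_R": i_r,
        "gamma": gamma,
        "lambda_": lambda_,
        "sigma": sigma,
        "frac_disconnected": frac_disc,
        "small_world": sigma > 1,
    }


def compute_metrics(network: BinaryNetwork) -> MetricRecord:
    """All five metrics for one binary network, as a MetricRecord."""
    _, d = degree_sequence(network)
    sw = small_worldness(network)
    q, _ = modularity_newman(network)
    e_glob = global_efficiency(network)
    return MetricRecord(
        N=network.n_nodes,
        d=d,
        Q=q,
        E_glob=e_glob,
        **sw,
    )
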