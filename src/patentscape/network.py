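"""Threshold graphs, LCC diagnostics, and degree-distribution fitting.

Two patents are linked when their angular cosine similarity c_ij does not
exceed a threshold H (small H keeps only highly similar pairs; H = 1
joins every pair).  The analysis concentrates on the largest connected
component (LCC).  Degree densities of patent networks are heavy-tailed;
a discrete truncated power law rho(k) ~ k^-gamma is fitted on a degree
window [k_min, k_max] by maximum likelihood, with a log-binned
least-squares slope reported as an independent diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .vectorize import SimilarityMatrix

__all__ = [
    "build_network",
    "largest_connected_component",
    "lcc_sweep",
    "choose_threshold",
    "degree_stats",
    "DegreeStats",
    "PowerLawFit",
    "fit_power_law",
    "sample_power_law",
    "log_binned_density",
    "DEFAULT_H_GRID",
]

logger = logging.getLogger(__name__)

#: default sweep grid H in {0.05, 0.10, ..., 1.00}
DEFAULT_H_GRID = [round(0.05 * i, 2) for i in range(1, 21)]


def build_network(
    matrix: SimilarityMatrix,
    h: float,
    include_zero_similarity: bool = True,
) -> nx.Graph:
    """Binarize the similarity matrix at threshold H.

    Edge (i, j) is present iff i != j and c_ij <= H.  Pairs with c = 0
    (distinct patents whose keyword lists coincide) are maximally similar
    and connected by default; set ``include_zero_similarity=False`` for
    the strict-inequality reading 0 < c_ij <= H.  Self-loops never occur.
    """
    if not (0.0 < h <= 1.0):
        raise ValueError(f"threshold H must be in (0, 1], got {h}")
    g = nx.Graph(threshold=h)
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    vals = matrix.values
    for a in range(n):
        for b in range(a + 1, n):
            c = vals[a, b]
            if c <= h and (include_zero_similarity or c > 0.0):
                g.add_edge(matrix.ids[a], matrix.ids[b], similarity=float(c))
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on a maximum-cardinality component; size ties are
    broken by the smallest lexicographic member id for determinism."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no connected component")
    components = [sorted(c, key=str) for c in nx.connected_components(g)]
    best = sorted(components, key=lambda c: (-len(c), str(c[0])))[0]
    return g.subgraph(best).copy()


def lcc_sweep(
    matrix: SimilarityMatrix,
    h_values: Sequence[float] = DEFAULT_H_GRID,
    include_zero_similarity: bool = True,
) -> pd.DataFrame:
    """LCC size as a function of the threshold H: table (H, lcc_size).

    Sizes are non-decreasing in H because the edge set at a smaller H is
    nested inside the edge set at any larger H.
    """
    if len(h_values) == 0:
        raise ValueError("empty threshold grid")
    rows = []
    for h in h_values:
        g = build_network(matrix, h, include_zero_similarity)
        lcc = largest_connected_component(g)
        rows.append({"H": h, "lcc_size": lcc.number_of_nodes()})
    return pd.DataFrame(rows)


def choose_threshold(sweep: pd.DataFrame) -> float:
    """Pick the knee of the LCC-vs-H curve: the grid value just before
    the largest single jump in LCC size.

    The sweep curve of a corpus with latent groups grows gradually as
    within-group links accumulate, then jumps when weakly related groups
    merge; the knee sits below that merge.  If the curve never jumps
    (already connected), the smallest H attaining the maximum is used.
    """
    sizes = sweep["lcc_size"].to_numpy()
    hs = sweep["H"].to_numpy()
    if len(sizes) < 2:
        return float(hs[0])
    jumps = np.diff(sizes)
    if jumps.max() <= 0:
        return float(hs[int(np.argmax(sizes))])
    return float(hs[int(np.argmax(jumps))])


@dataclass
class PowerLawFit:
    """Discrete truncated power-law fit rho(k) ~ k^-gamma on [k_min, k_max]."""

    gamma: float
    stderr: float
    k_min: int
    k_max: int
    n_obs: int
    loglik: float
    ls_slope: float  # log-binned least-squares slope (diagnostic)
    degenerate: bool = False  # no tail variation; gamma unreliable


@dataclass
class DegreeStats:
    """Degrees of a (sub)network with its fitted degree-density exponent."""

    degrees: dict
    n: int
    bin_edges: np.ndarray
    density: np.ndarray
    fit: PowerLawFit | None


def _logZ_terms(gamma: float, ks: np.ndarray) -> np.ndarray:
    return ks.astype(float) ** (-gamma)


def fit_power_law(
    degrees: Sequence[int] | np.ndarray,
    k_min: int = 1,
    k_max: int = 100,
) -> PowerLawFit:
    """Maximum-likelihood exponent of a discrete truncated power law.

    The model is P(k) = k^-gamma / Z(gamma) with
    Z(gamma) = sum_{k=k_min}^{k_max} k^-gamma.  Observations outside
    [k_min, k_max] are discarded before fitting.  The standard error is
    the inverse square root of the observed Fisher information
    n * Var_gamma(log K).  A log-binned least-squares slope over the same
    window is attached as a diagnostic of fit quality.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_max <= k_min:
        raise ValueError("k_max must exceed k_min")
    data = np.asarray(degrees, dtype=int)
    data = data[(data >= k_min) & (data <= k_max)]
    if data.size < 10:
        raise ValueError(f"need >= 10 in-range degrees, got {data.size}")

    support = np.arange(k_min, k_max + 1)
    log_support = np.log(support.astype(float))
    mean_log = float(np.mean(np.log(data.astype(float))))
    n = data.size

    degenerate = bool(np.all(data == data[0]))

    def negloglik(gamma: float) -> float:
        z = np.sum(support.astype(float) ** (-gamma))
        return gamma * mean_log + np.log(z)

    res = minimize_scalar(negloglik, bounds=(1e-6, 20.0), method="bounded")
    gamma = float(res.x)

    # Fisher information: n * Var(log K) under the fitted model
    w = support.astype(float) ** (-gamma)
    w /= w.sum()
    var_logk = float(np.sum(w * log_support**2) - np.sum(w * log_support) ** 2)
    stderr = float("inf") if var_logk <= 0 else 1.0 / np.sqrt(n * var_logk)

    edges, dens = log_binned_density(data, k_min=k_min, k_max=k_max)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = dens > 0
    if mask.sum() >= 2:
        slope = float(np.polyfit(np.log(centers[mask]), np.log(dens[mask]), 1)[0])
    else:
        slope = float("nan")
        degenerate = True
    if degenerate:
        logger.warning("degree sequence has no tail variation; exponent estimate unreliable")

    return PowerLawFit(
        gamma=gamma,
        stderr=stderr,
        k_min=k_min,
        k_max=k_max,
        n_obs=n,
        loglik=float(-n * negloglik(gamma)),
        ls_slope=-slope,
        degenerate=degenerate,
    )


def sample_power_law(
    gamma: float,
    size: int,
    k_min: int = 1,
    k_max: int = 100,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Exact inverse-CDF draws from the discrete truncated power law
    (the finite support makes the inverse CDF a table lookup)."""
    rng = np.random.default_rng(rng)
    support = np.arange(k_min, k_max + 1)
    p = support.astype(float) ** (-gamma)
    p /= p.sum()
    cdf = np.cumsum(p)
    u = rng.random(size)
    return support[np.searchsorted(cdf, u)]


def log_binned_density(
    degrees: np.ndarray | Sequence[int],
    k_min: int = 1,
    k_max: int | None = None,
    base: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Degree density on logarithmic bins (edges at powers of ``base``),
    normalized by bin width so the histogram integrates to 1."""
    data = np.asarray(degrees, dtype=float)
    data = data[data >= k_min]
    if data.size == 0:
        raise ValueError("no degrees at or above k_min")
    if k_max is None:
        k_max = int(data.max())
    edges = [float(k_min)]
    while edges[-1] < k_max:
        edges.append(edges[-1] * base)
    edges = np.array(edges + [edges[-1] * base])
    counts, edges = np.histogram(data, bins=edges)
    widths = np.diff(edges)
    density = counts / (widths * data.size)
    return edges, density


def degree_stats(
    g: nx.Graph,
    k_min: int = 1,
    k_max: int = 100,
    fit: bool = True,
) -> DegreeStats:
    """Exact degrees k_i with a log-binned density and, when the network
    has enough positive-degree nodes in the window, a power-law fit."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(g.degree())
    ks = np.array([k for k in degrees.values() if k >= 1])
    if ks.size:
        edges, density = log_binned_density(ks, k_min=1)
    else:
        edges, density = np.array([1.0, 1.5]), np.array([0.0])
    pl_fit = None
    if fit:
        in_range = ks[(ks >= k_min) & (ks <= k_max)] if ks.size else np.array([])
        if in_range.size >= 10:
            pl_fit = fit_power_law(ks, k_min=k_min, k_max=k_max)
        else:
            logger.info("too few in-range degrees (%d) for a power-law fit", in_range.size)
    return DegreeStats(
        degrees=degrees,
        n=g.number_of_nodes(),
        bin_edges=edges,
        density=density,
        fit=pl_fit,
    )
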