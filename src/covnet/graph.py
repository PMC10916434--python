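"""Weighted-graph global efficiency for correlation networks.

Edges are correlation weights; a hop's length is the reciprocal of its
weight, so strongly coupled regions are "close".  Negative or missing
correlations carry no connection by default (standard practice for
covariance networks); absolute-value weighting is available for
sensitivity analyses.

Global efficiency here is the Latora–Marchiori form used by the Brain
Connectivity Toolbox: the mean over ordered node pairs of the inverse
shortest-path length, with unreachable pairs contributing 0.  The
literal reciprocal-of-mean-path-length variant ``1 / L̄`` differs
whenever distances are unequal and is exposed via ``form="inverse_mean"``.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path

from covnet.network import GroupNetwork

__all__ = ["weights_to_lengths", "shortest_path_lengths", "global_efficiency"]


def _as_matrix(network) -> np.ndarray:
    if isinstance(network, GroupNetwork):
        return np.asarray(network.matrix, dtype=float)
    m = np.asarray(network, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {m.shape}")
    return m


def weights_to_lengths(matrix, weight: str = "positive") -> np.ndarray:
    """Convert a correlation-weight matrix to a hop-length matrix.

    ``length[i, j] = 1 / w[i, j]`` for positive weights; non-positive or
    NaN (flagged-missing) weights become unreachable (infinite length);
    the diagonal is 0.  With ``weight="absolute"``, ``|w|`` is used
    before the rule.
    """
    w = _as_matrix(matrix).copy()
    if weight == "absolute":
        w = np.abs(w)
    elif weight != "positive":
        raise ValueError(f"weight must be 'positive' or 'absolute', got {weight!r}")
    lengths = np.full_like(w, np.inf)
    pos = np.isfinite(w) & (w > 0)
    lengths[pos] = 1.0 / w[pos]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_lengths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances (Dijkstra per source)."""
    adjacency = lengths.copy()
    np.fill_diagonal(adjacency, 0.0)
    # csgraph treats 0/inf entries of a dense matrix as absent edges
    dist = shortest_path(adjacency, method="D", directed=False)
    np.fill_diagonal(dist, 0.0)
    return dist


def global_efficiency(
    network,
    weight: str = "positive",
    form: str = "mean_inverse",
) -> float:
    """Global efficiency of a weighted network.

    Parameters
    ----------
    network
        :class:`~covnet.network.GroupNetwork` or square weight matrix.
    weight
        ``"positive"`` (default: negative correlations are disconnected)
        or ``"absolute"``.
    form
        ``"mean_inverse"`` (default): ``E = mean over i != j of 1/d_ij``,
        unreachable pairs contributing 0.  ``"inverse_mean"``: the
        reciprocal of the mean shortest-path length, 0 if any pair is
        unreachable.

    Returns
    -------
    float
        In [0, 1] when all weights are <= 1 (every hop length >= 1).
    """
    w = _as_matrix(network)
    k = w.shape[0]
    if k < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = shortest_path_lengths(weights_to_lengths(w, weight=weight))
    off = ~np.eye(k, dtype=bool)
    d = dist[off]
    if form == "mean_inverse":
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        return float(inv.mean())
    if form == "inverse_mean":
        if not np.all(np.isfinite(d)):
            return 0.0
        mean_d = float(d.mean())
        return 1.0 / mean_d if mean_d > 0 else 0.0
    raise ValueError(f"unknown form {form!r}")
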