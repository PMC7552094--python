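"""Sparsity thresholding and weighted graph-theoretical metrics.

Conventions follow the Brain Connectivity Toolbox for weighted undirected
networks: Onnela-form clustering with weights normalized by the subject's
maximum weight, path-based metrics on edge lengths 1/w, unnormalized
betweenness with Brandes-style fractional allocation, and local efficiency
restricted to each node's neighborhood subgraph.  Edge weights are kept (no
binarization) so that strength remains meaningful after thresholding.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome_io import Connectome

logger = logging.getLogger(__name__)

LOCAL_METRICS = ("strength", "betweenness", "clustering", "local_efficiency")
GLOBAL_METRICS = ("global_strength", "global_clustering", "global_efficiency",
                  "transitivity")


@dataclass
class ThresholdedConnectome(Connectome):
    """A connectome after proportional (sparsity) thresholding.

    ``sparsity`` is the requested fraction of possible edges;
    ``retained_edge_count`` the number of upper-triangle edges that survived.
    Surviving weights are the original weights, never rescaled.
    """

    sparsity: float = 1.0
    retained_edge_count: int = 0


def threshold_sparsity(c: Connectome, sparsity: float) -> ThresholdedConnectome:
    """Keep the K = floor(sparsity * N(N-1)/2) strongest edges, zero the rest.

    Ties at the K-th largest weight are broken deterministically by ascending
    (row, col) index.  If the matrix has fewer than K nonzero edges they are
    all kept and a warning is logged.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = c.n_regions
    k_target = int(np.floor(sparsity * n * (n - 1) / 2))
    rows, cols = np.triu_indices(n, k=1)
    w = c.weights[rows, cols]
    nz = np.flatnonzero(w)
    if len(nz) < k_target:
        logger.warning(
            "subject %s: only %d nonzero edges available for K=%d; keeping all",
            c.subject_id, len(nz), k_target)
        keep = nz
    else:
        # primary key: weight descending; ties: ascending (row, col)
        order = np.lexsort((cols[nz], rows[nz], -w[nz]))
        keep = nz[order[:k_target]]
    out = np.zeros_like(c.weights)
    out[rows[keep], cols[keep]] = w[keep]
    out += out.T
    return ThresholdedConnectome(
        c.subject_id, out, list(c.region_labels), list(c.hemisphere),
        sparsity=sparsity, retained_edge_count=len(keep))


def _as_thresholded(c: Connectome) -> ThresholdedConnectome:
    if isinstance(c, ThresholdedConnectome):
        return c
    return threshold_sparsity(c, 1.0)


def _normalized(w: np.ndarray) -> np.ndarray:
    """Scale weights to [0, 1] by the matrix maximum (per-subject)."""
    m = w.max()
    return w / m if m > 0 else w


def nodal_strength(c: Connectome) -> np.ndarray:
    """Weighted degree: strength_i = sum_j w_ij."""
    return _as_thresholded(c).weights.sum(axis=1)


def clustering_coefficient(c: Connectome) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With w-hat = w / max(w), C_i = sum_{j,h} (wh_ij wh_ih wh_jh)^(1/3) /
    (k_i (k_i - 1)) where k_i counts nonzero neighbors; C_i = 0 for k_i < 2.
    """
    w = _as_thresholded(c).weights
    wh = _normalized(w)
    cr = np.cbrt(wh)
    triangles = np.diagonal(cr @ cr @ cr)  # 2 x weighted triangle count per node
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, triangles / denom, 0.0)
    return out


def transitivity(c: Connectome) -> float:
    """Weighted transitivity: total triangle intensity over total open triples."""
    w = _as_thresholded(c).weights
    cr = np.cbrt(_normalized(w))
    triangles = np.diagonal(cr @ cr @ cr).sum()
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = (k * (k - 1)).sum()
    return float(triangles / denom) if denom > 0 else 0.0


def _length_matrix(w: np.ndarray) -> csr_matrix:
    """Sparse edge-length matrix with l_ij = 1 / w_ij for w_ij > 0."""
    lengths = np.zeros_like(w)
    np.divide(1.0, w, out=lengths, where=w > 0)
    return csr_matrix(lengths)


def shortest_path_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on lengths 1/w (inf if disconnected)."""
    return dijkstra(_length_matrix(w), directed=False)


def global_efficiency(c: Connectome) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    w = _as_thresholded(c).weights
    n = w.shape[0]
    d = shortest_path_lengths(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(c: Connectome) -> np.ndarray:
    """Weighted local efficiency per node (neighborhood-restricted paths).

    For node i with neighbors G_i (k_i >= 2), shortest paths are computed on
    lengths 1/w-hat within the subgraph induced by G_i, and
    E_loc,i = sum_{j != h in G_i} (wh_ij wh_ih / d_jh(G_i))^(1/3) / (k_i (k_i-1)).
    Disconnected neighbor pairs contribute nothing; E_loc,i = 0 for k_i < 2.
    """
    w = _as_thresholded(c).weights
    wh = _normalized(w)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(wh[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = wh[np.ix_(nbrs, nbrs)]
        d = dijkstra(_length_matrix(sub), directed=False)
        with np.errstate(divide="ignore"):
            inv_d = 1.0 / d
        np.fill_diagonal(inv_d, 0.0)
        inv_d[~np.isfinite(inv_d)] = 0.0
        wi = np.cbrt(wh[i, nbrs])
        num = (wi[:, None] * wi[None, :] * np.cbrt(inv_d)).sum()
        out[i] = num / (k * (k - 1))
    return out


def betweenness_centrality(c: Connectome) -> np.ndarray:
    """Unnormalized weighted betweenness (Brandes accumulation).

    Shortest paths on lengths 1/w; each unordered source-target pair counts
    once, endpoints excluded, with fractional allocation across equal-length
    shortest paths.
    """
    w = _as_thresholded(c).weights
    n = w.shape[0]
    adj = [np.flatnonzero(w[i]) for i in range(n)]
    lengths = {}
    for i in range(n):
        for j in adj[i]:
            lengths[(i, j)] = 1.0 / w[i, j]
    bc = np.zeros(n)
    for s in range(n):
        # single-source Dijkstra with path counting
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap = [(0.0, s)]
        while heap:
            d_v, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u in adj[v]:
                alt = d_v + lengths[(v, u)]
                if alt < dist[u]:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
                elif alt == dist[u] and not done[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0  # each unordered pair visited from both endpoints


# ---------------------------------------------------------------------------
# cohort-level table


@dataclass
class MetricTable:
    """Nodal and global metric values for a cohort of subjects.

    ``local`` maps metric name -> (subjects x regions) DataFrame;
    ``global_`` maps metric name -> per-subject Series.  By construction
    global_clustering is the mean of nodal clustering and global_strength the
    mean of nodal strengths.
    """

    local: dict[str, pd.DataFrame] = field(default_factory=dict)
    global_: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        first = next(iter(self.local.values()))
        return list(first.index)

    @property
    def regions(self) -> list[str]:
        first = next(iter(self.local.values()))
        return list(first.columns)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (subject_id, region, metric, value) table."""
        frames = []
        for name, df in self.local.items():
            t = df.stack().rename("value").reset_index()
            t.columns = ["subject_id", "region", "value"]
            t.insert(2, "metric", name)
            frames.append(t)
        for name, s in self.global_.items():
            t = s.rename("value").reset_index()
            t.columns = ["subject_id", "value"]
            t.insert(1, "region", "global")
            t.insert(2, "metric", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def compute_subject_metrics(tc: ThresholdedConnectome) -> tuple[dict, dict]:
    """All four local and four global metrics for one thresholded subject."""
    strength = nodal_strength(tc)
    clust = clustering_coefficient(tc)
    local = {
        "strength": strength,
        "betweenness": betweenness_centrality(tc),
        "clustering": clust,
        "local_efficiency": local_efficiency(tc),
    }
    global_ = {
        "global_strength": float(strength.mean()),
        "global_clustering": float(clust.mean()),
        "global_efficiency": global_efficiency(tc),
        "transitivity": transitivity(tc),
    }
    return local, global_


def compute_metric_table(cohort: list[Connectome], sparsity: float = 0.10
                         ) -> MetricTable:
    """Threshold each subject independently and tabulate all metrics."""
    if not cohort:
        raise ValueError("empty cohort")
    labels = cohort[0].region_labels
    for c in cohort[1:]:
        if c.region_labels != labels:
            raise ValueError(
                f"subject {c.subject_id!r} region labels differ from "
                f"{cohort[0].subject_id!r}")
    local_rows: dict[str, list[np.ndarray]] = {m: [] for m in LOCAL_METRICS}
    global_rows: dict[str, list[float]] = {m: [] for m in GLOBAL_METRICS}
    ids = []
    for c in cohort:
        tc = threshold_sparsity(c, sparsity)
        loc, glob = compute_subject_metrics(tc)
        for m in LOCAL_METRICS:
            local_rows[m].append(loc[m])
        for m in GLOBAL_METRICS:
            global_rows[m].append(glob[m])
        ids.append(c.subject_id)
    local = {m: pd.DataFrame(np.vstack(v), index=ids, columns=labels)
             for m, v in local_rows.items()}
    global_ = {m: pd.Series(v, index=ids, name=m)
               for m, v in global_rows.items()}
    return MetricTable(local=local, global_=global_)
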