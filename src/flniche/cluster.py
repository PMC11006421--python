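"""Signature-guided iterative clustering, marker ranking, cluster-graph
connectivity, and SOM / consensus metaclustering.

The single-cell arm mirrors a standard scRNA-seq workflow: library-size
log1p normalisation, PCA projection, a shared-nearest-neighbour style kNN
graph with Jaccard edge weights, and greedy modularity (Louvain-style)
community detection.  Cluster selection between rounds is driven by a
marker-signature score so that three successive rounds progressively
enrich for the populations of interest, as in iterative subsetting of a
sorted myeloid compartment down to its macrophage clusters.

The cytometry arm fits a batch self-organising map and aggregates repeated
subsampled hierarchical cuts of its codebook into consensus metaclusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalisation and signature scoring
# ---------------------------------------------------------------------------

def normalize_log1p(matrix: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalise to ``scale`` counts per cell, then log1p.

    Cells with zero total counts cannot be normalised; they are dropped with
    a logged warning.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    totals = matrix.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping %d cells with zero total counts", int(zero.sum()))
        matrix = matrix.loc[~zero]
        totals = totals.loc[~zero]
    if matrix.shape[0] == 0:
        raise ValueError("all cells had zero total counts")
    vals = np.log1p(matrix.to_numpy(float) / totals.to_numpy(float)[:, None] * scale)
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def score_signature(norm: pd.DataFrame, signature: Sequence[str]) -> pd.Series:
    """Per-cell mean of per-gene z-scores over the signature genes.

    Genes absent from the matrix are skipped with a warning; a gene constant
    across cells contributes zero.
    """
    present = [g for g in signature if g in norm.columns]
    missing = [g for g in signature if g not in norm.columns]
    if missing:
        logger.warning("signature genes missing from matrix: %s", ", ".join(missing))
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = norm[present].to_numpy(float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=1), index=norm.index, name="signature_score")


# ---------------------------------------------------------------------------
# kNN graph and community detection
# ---------------------------------------------------------------------------

def build_knn_graph(features: pd.DataFrame, k: int = 15, metric: str = "euclidean") -> nx.Graph:
    """Build a kNN graph with Jaccard overlap edge weights.

    An edge (u, v) exists iff v is among u's k nearest neighbours or vice
    versa; its weight is the Jaccard overlap of the two k-neighbour sets.
    Zero-weight edges are dropped.  Distance ties are broken by row order
    (ids sorted lexicographically beforehand) so the graph is deterministic.
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError("metric must be 'euclidean' or 'cosine'")
    feats = features.sort_index()
    X = feats.to_numpy(float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")

    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")  # stable => ties by id order
    nbrs = order[:, :k]
    # self-inclusive neighbour sets (SNN convention) for the Jaccard weights
    nbr_sets = [frozenset(row.tolist()) | {i} for i, row in enumerate(nbrs)]

    ids = list(feats.index)
    G = nx.Graph()
    G.add_nodes_from(ids)
    seen: set[tuple[int, int]] = set()
    for u in range(n):
        for v in nbrs[u]:
            a, b = (u, int(v)) if u < v else (int(v), u)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(nbr_sets[a] & nbr_sets[b])
            union = len(nbr_sets[a] | nbr_sets[b])
            w = inter / union if union else 0.0
            if w > 0:
                G.add_edge(ids[a], ids[b], weight=w)
    return G


def community_detect(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Greedy modularity (Louvain-style multi-level) community detection.

    Returns id -> cluster label ("0", "1", ...), communities numbered by
    their lexicographically smallest member for determinism.  A graph with
    no edges yields singleton clusters with a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if graph.number_of_edges() == 0:
        logger.warning("graph has no edges; every node becomes its own cluster")
        comms = [{n} for n in sorted(graph.nodes)]
    else:
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=int(seed)
        )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels: dict = {}
    for i, members in enumerate(comms):
        for m in members:
            labels[m] = str(i)
    return pd.Series(labels, name="cluster").loc[sorted(graph.nodes)]


def cluster_graph_connectivity(graph: nx.Graph, clusters: pd.Series) -> pd.DataFrame:
    """PAGA-style cluster-graph connectivity.

    For clusters c, d the observed inter-cluster edge count e_cd is compared
    with its expectation under degree-preserving randomisation,
    E[e_cd] = D_c * D_d / (2E); connectivity = min(1, e_cd / E[e_cd]).
    Symmetric with zero diagonal; exactly 0 for disconnected cluster pairs.
    """
    if set(graph.nodes) != set(clusters.index):
        raise ValueError("graph nodes and cluster ids do not match")
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    E = graph.number_of_edges()
    deg = dict(graph.degree())
    D = {c: sum(deg[n] for n in clusters.index[clusters == c]) for c in labels}
    e = {(a, b): 0 for a in labels for b in labels}
    for u, v in graph.edges:
        cu, cv = clusters[u], clusters[v]
        if cu != cv:
            a, b = sorted((cu, cv))
            e[(a, b)] += 1
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            expected = D[a] * D[b] / (2 * E) if E else 0.0
            conn = min(1.0, e[(a, b)] / expected) if expected > 0 else 0.0
            out.loc[a, b] = out.loc[b, a] = conn
    return out


# ---------------------------------------------------------------------------
# Marker ranking
# ---------------------------------------------------------------------------

def rank_genes(norm: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """One-vs-rest rank-sum marker test per cluster.

    For each cluster and gene, a two-sided Mann-Whitney U test compares the
    cluster's cells against all other cells (tie-corrected normal
    approximation; exact enumeration when both groups have <= 10 cells and
    the gene has no ties).  Effect is the difference of means on the
    normalised log scale; p-values are BH-adjusted across genes within each
    cluster.
    """
    clusters = clusters.loc[norm.index]
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = clusters.value_counts()
    if (sizes < 2).any():
        raise ValueError("every cluster needs >= 2 cells")

    X = norm.to_numpy(float)
    genes = list(norm.columns)
    frames = []
    for c in labels:
        mask = (clusters == c).to_numpy()
        x, y = X[mask], X[~mask]
        n1, n2 = x.shape[0], y.shape[0]
        const = np.ptp(X, axis=0) == 0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
        U = np.asarray(res.statistic, float)
        p = np.asarray(res.pvalue, float)

        if n1 <= 10 and n2 <= 10:
            for j in range(len(genes)):
                col = np.concatenate([x[:, j], y[:, j]])
                if len(np.unique(col)) == len(col):  # exact method requires no ties
                    r = mannwhitneyu(x[:, j], y[:, j], alternative="two-sided", method="exact")
                    U[j], p[j] = r.statistic, r.pvalue

        U[const] = n1 * n2 / 2.0
        p[const] = 1.0
        p = np.nan_to_num(p, nan=1.0)
        p = np.clip(p, 0.0, 1.0)
        padj = multipletests(p, method="fdr_bh")[1]
        effect = x.mean(axis=0) - y.mean(axis=0)
        effect[const] = 0.0
        frames.append(pd.DataFrame({
            "cluster": c, "gene": genes, "effect": effect,
            "statistic": U, "pval": p, "padj": padj,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cluster selection and iterative refinement
# ---------------------------------------------------------------------------

def select_clusters(
    clusters: pd.Series, scores: pd.Series, margin: float = 0.0
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep clusters whose median signature score exceeds the global median
    by at least ``margin``; returns (member ids, per-cluster report)."""
    if not clusters.index.equals(scores.index):
        scores = scores.loc[clusters.index]
    global_median = float(scores.median())
    med = scores.groupby(clusters).median()
    report = pd.DataFrame({
        "median_score": med,
        "global_median": global_median,
        "kept": med >= global_median + margin,
    })
    kept = report.index[report["kept"]]
    if len(kept) == 0:
        raise ValueError(f"selection kept no clusters; report:\n{report}")
    ids = clusters.index[clusters.isin(kept)]
    return ids, report


@dataclass(frozen=True)
class RefineRound:
    """One round of clustering + signature-guided selection."""

    signature: tuple[str, ...]
    margin: float = 0.0


@dataclass
class RefineParams:
    scale: float = 1e4
    n_pcs: int = 50
    k: int = 15
    metric: str = "cosine"
    resolution: float = 1.0
    seed: int = 0


@dataclass
class RefineResult:
    labels: pd.Series                 # final cluster label per surviving cell
    reports: list[pd.DataFrame]       # per-round selection reports
    markers: pd.DataFrame             # rank_genes table for the final round
    graph: nx.Graph                   # final-round kNN graph
    connectivity: pd.DataFrame | None # final-round cluster-graph connectivity


def _reduce(norm: pd.DataFrame, n_pcs: int, seed: int) -> pd.DataFrame:
    n_comp = min(n_pcs, norm.shape[0] - 1, norm.shape[1])
    if n_comp < 1:
        return norm
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    return pd.DataFrame(pca.fit_transform(norm.to_numpy(float)), index=norm.index)


def iterative_refine(
    matrix: pd.DataFrame,
    rounds: Sequence[RefineRound],
    params: RefineParams | None = None,
) -> RefineResult:
    """Iterative signature-guided clustering (default: three rounds).

    Each round normalises the current subset, projects to principal
    components, builds the kNN graph, detects communities, scores the
    round's signature and keeps the clusters passing the margin rule; the
    final round additionally ranks marker genes and computes cluster-graph
    connectivity.
    """
    if len(rounds) < 1:
        raise ValueError("need at least one round")
    params = params or RefineParams()
    current = matrix
    reports: list[pd.DataFrame] = []
    labels: pd.Series | None = None
    graph: nx.Graph | None = None

    for i, rnd in enumerate(rounds, start=1):
        if current.shape[0] == 0:
            raise ValueError(f"round {i}: no cells left to cluster")
        norm = normalize_log1p(current, scale=params.scale)
        feats = _reduce(norm, params.n_pcs, params.seed)
        k = min(params.k, feats.shape[0] - 1)
        graph = build_knn_graph(feats, k=k, metric=params.metric)
        labels = community_detect(graph, resolution=params.resolution, seed=params.seed + i)
        scores = score_signature(norm, rnd.signature)
        try:
            kept_ids, report = select_clusters(labels, scores, margin=rnd.margin)
        except ValueError as exc:
            raise ValueError(f"round {i} emptied the matrix: {exc}") from exc
        report.insert(0, "round", i)
        reports.append(report)
        current = current.loc[kept_ids]
        logger.info("round %d: %d clusters, kept %d cells", i, labels.nunique(), len(kept_ids))

    assert labels is not None and graph is not None
    final_labels = labels.loc[current.index]
    norm_final = normalize_log1p(current, scale=params.scale)
    sub_graph = graph.subgraph(current.index).copy()
    markers = (
        rank_genes(norm_final, final_labels)
        if final_labels.nunique() >= 2 and final_labels.value_counts().min() >= 2
        else pd.DataFrame(columns=["cluster", "gene", "effect", "statistic", "pval", "padj"])
    )
    conn = None
    if final_labels.nunique() >= 2:
        conn = cluster_graph_connectivity(sub_graph, final_labels)
    return RefineResult(final_labels, reports, markers, sub_graph, conn)


def default_rounds(margin: float = 0.0) -> list[RefineRound]:
    """Three rounds mirroring progenitor/pre-macrophage selection followed by
    two macrophage-signature rounds."""
    pmac = ("Csf1r", "Cx3cr1", "Ccr2", "Clec7a", "Adgre1", "Mrc1")
    mac = ("Adgre1", "Mrc1", "Timd4", "Siglec1", "Vcam1", "Msr1", "Cd63")
    return [RefineRound(pmac, margin), RefineRound(mac, margin), RefineRound(mac, margin)]


# ---------------------------------------------------------------------------
# Self-organising map + consensus metaclustering
# ---------------------------------------------------------------------------

@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray           # nodes x features
    qe_history: list[float]        # mean squared distance to BMU, per epoch
    epochs: int
    seed: int


def som_fit(
    features: pd.DataFrame,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 20,
    seed: int = 0,
) -> tuple[SOMModel, pd.Series]:
    """Fit a batch self-organising map; returns (model, per-row node index).

    The codebook is initialised by seeded sampling of data rows.  Each epoch
    assigns every row to its best-matching node (Euclidean) and replaces the
    codebook with neighbourhood-weighted means, the Gaussian neighbourhood
    radius decaying linearly from max(rows, cols)/2 to 0.5.
    """
    rows, cols = grid
    if rows * cols < 1:
        raise ValueError("grid must have at least one node")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    X = features.to_numpy(float)
    n, d = X.shape
    n_nodes = rows * cols
    if n_nodes > n:
        raise ValueError(f"more grid nodes ({n_nodes}) than data rows ({n})")

    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n, size=n_nodes, replace=False)].astype(float).copy()
    gy, gx = np.divmod(np.arange(n_nodes), cols)
    grid_d2 = (gy[:, None] - gy[None, :]) ** 2 + (gx[:, None] - gx[None, :]) ** 2
    grid_d = np.sqrt(grid_d2)

    r0 = max(rows, cols) / 2.0
    qe_hist: list[float] = []
    bmu = np.argmin(cdist(X, codebook), axis=1)
    for e in range(epochs):
        frac = e / max(epochs - 1, 1)
        sigma = max(r0 + (0.5 - r0) * frac, 0.5)
        # Gaussian kernel truncated at the neighbourhood radius; once the
        # radius has shrunk below the grid spacing this is a k-means update
        H = np.exp(-grid_d2 / (2.0 * sigma**2)) * (grid_d <= sigma)
        W = H[:, bmu]                                # node x n
        den = W.sum(axis=1)
        upd = den > 0
        codebook[upd] = (W @ X)[upd] / den[upd, None]  # empty nodes keep their row
        d2 = cdist(X, codebook, metric="sqeuclidean")
        bmu = np.argmin(d2, axis=1)
        qe_hist.append(float(d2[np.arange(n), bmu].mean()))

    model = SOMModel(grid=grid, codebook=codebook, qe_history=qe_hist, epochs=epochs, seed=seed)
    assign = pd.Series(bmu, index=features.index, name="som_node")
    return model, assign


def consensus_metacluster(
    model: SOMModel | np.ndarray,
    K: int,
    resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Consensus metaclustering of SOM codebook rows into K metaclusters.

    Repeatedly subsamples codebook rows, cuts an average-linkage Euclidean
    dendrogram at K, and accumulates co-assignment frequencies among
    co-sampled pairs; the final labels cut an average-linkage dendrogram of
    (1 - consensus) at K.  Labels are renumbered 0..K-1 by first occurrence.
    """
    codebook = model.codebook if isinstance(model, SOMModel) else np.asarray(model, float)
    n = codebook.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= number of nodes ({n})")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    if K == 1:
        return np.zeros(n, dtype=int)

    rng = np.random.default_rng(seed)
    m = max(K, int(round(subsample_frac * n)))
    m = min(m, n)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = codebook[idx]
        lab = fcluster(linkage(sub, method="average", metric="euclidean"), K, criterion="maxclust")
        co = (lab[:, None] == lab[None, :]).astype(float)
        together[np.ix_(idx, idx)] += co
        sampled[np.ix_(idx, idx)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.where(sampled > 0, sampled, 1.0), 0.0)
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    lab = fcluster(linkage(squareform(dist, checks=False), method="average"), K, criterion="maxclust")

    # renumber deterministically by first occurrence
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, l in enumerate(lab):
        if l not in remap:
            remap[l] = len(remap)
        out[i] = remap[l]
    return out


def metacluster_events(
    assignments: pd.Series, node_labels: np.ndarray
) -> pd.Series:
    """Propagate node metacluster labels to the underlying events."""
    return pd.Series(
        [str(node_labels[i]) for i in assignments.to_numpy()],
        index=assignments.index,
        name="metacluster",
    )


def asinh_transform(table: pd.DataFrame, cofactor: float = 150.0) -> pd.DataFrame:
    """Standard cytometry variance-stabilising transform asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return pd.DataFrame(
        np.arcsinh(table.to_numpy(float) / cofactor), index=table.index, columns=table.columns
    )
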