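"""Cross-modality cluster correlation.

Transcriptomic clusters (log-normalised gene expression) and cytometry
clusters (asinh marker intensities) are matched through the markers the two
panels share: per-cluster centroids are computed in each modality, each
feature is z-scored across that modality's clusters, and every pair of
centroids is compared by Spearman rank correlation.  Cytometry protein
names are translated to gene symbols through a small alias table shipped
with the package (e.g. CD206 -> Mrc1, F4/80 -> Adgre1).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def load_marker_aliases() -> pd.Series:
    """Return the shipped protein-name -> gene-symbol alias table."""
    with resources.files("flniche.data").joinpath("marker_aliases.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return pd.Series(table["gene"].to_numpy(), index=table["marker"], name="gene")


def map_markers_to_genes(table: pd.DataFrame, aliases: pd.Series | None = None) -> pd.DataFrame:
    """Rename cytometry marker columns to gene symbols; unmapped markers are
    dropped with a warning."""
    aliases = load_marker_aliases() if aliases is None else aliases
    mapped = {m: aliases[m] for m in table.columns if m in aliases.index}
    unmapped = [m for m in table.columns if m not in aliases.index]
    if unmapped:
        logger.warning("dropping unmapped markers: %s", ", ".join(unmapped))
    return table[list(mapped)].rename(columns=mapped)


def cluster_centroids(
    values: pd.DataFrame,
    clusters: pd.Series,
    features: list[str] | None = None,
    method: str = "mean",
) -> pd.DataFrame:
    """Per-cluster centroid (mean or median) of the requested features."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    features = list(values.columns) if features is None else features
    missing = [f for f in features if f not in values.columns]
    if missing:
        raise ValueError(f"unknown features: {', '.join(missing)}")
    clusters = clusters.loc[clusters.index.intersection(values.index)]
    if clusters.empty:
        raise ValueError("no overlapping ids between values and clusters")
    sub = values.loc[clusters.index, features]
    grouped = sub.groupby(clusters)
    out = grouped.mean() if method == "mean" else grouped.median()
    if (grouped.size() == 0).any():
        raise ValueError("empty cluster after id filtering")
    out.attrs["method"] = method
    return out


def modality_correlation(
    A: pd.DataFrame, B: pd.DataFrame, scale: str = "feature"
) -> pd.DataFrame:
    """Spearman correlation between every cluster centroid of A and of B.

    Features are intersected ("mutual markers"; >= 3 required) and, by
    default, z-scored across each modality's own clusters before comparing
    (``scale='feature'``; ``scale='none'`` skips it).  Rows with constant
    values yield NaN entries, reported via a warning rather than silently
    coerced to 0.
    """
    common = [f for f in A.columns if f in B.columns]
    if len(common) < 3:
        raise ValueError(f"need >= 3 mutual features, got {len(common)}")
    if scale not in ("feature", "none"):
        raise ValueError("scale must be 'feature' or 'none'")

    def _prep(M: pd.DataFrame) -> np.ndarray:
        X = M[common].to_numpy(float)
        if scale == "feature":
            mu, sd = X.mean(axis=0), X.std(axis=0)
            X = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return X

    Xa, Xb = _prep(A), _prep(B)
    Ra = np.apply_along_axis(rankdata, 1, Xa)  # average ranks for ties
    Rb = np.apply_along_axis(rankdata, 1, Xb)

    out = np.full((Xa.shape[0], Xb.shape[0]), np.nan)
    const_a = np.ptp(Ra, axis=1) == 0
    const_b = np.ptp(Rb, axis=1) == 0
    if const_a.any() or const_b.any():
        logger.warning(
            "constant centroid rows produce undefined correlations: A=%s B=%s",
            list(A.index[const_a]), list(B.index[const_b]),
        )
    za = (Ra - Ra.mean(axis=1, keepdims=True))
    zb = (Rb - Rb.mean(axis=1, keepdims=True))
    na = np.sqrt((za**2).sum(axis=1))
    nb = np.sqrt((zb**2).sum(axis=1))
    for i in range(Xa.shape[0]):
        if const_a[i]:
            continue
        denom = na[i] * nb
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (za[i] @ zb.T) / denom
        r[const_b] = np.nan
        out[i] = r
    return pd.DataFrame(out, index=A.index, columns=B.index)


def correspondence(rho: pd.DataFrame) -> pd.Series:
    """Row-wise argmax of the correlation matrix: each cluster of A mapped to
    its best-matching cluster of B."""
    return rho.idxmax(axis=1)
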