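"""Threshold-chained ligand-receptor inference and bulk pre-processing.

The chain links macrophage-cluster expression to receptor expression on
long-term HSCs through a ligand-receptor pair database:

1. ligands expressed in the kept macrophage clusters (nonzero in at least
   ``min_cells`` cells);
2. over-representation (hypergeometric) of those ligands in gene-set terms,
   keeping significant terms whose name matches hematopoiesis-related
   keywords, and restricting ligands to members of the selected terms;
3. a summed-count filter (>= 5 counts across the kept clusters' cells);
4. a receptor filter on bulk counts (group mean strictly > 40).

Edges are database pairs whose ligand and receptor both survive.  Each
filter returns a subset of its input, so relaxing any threshold can only
grow the final edge table.

Bulk helpers: low-count gene removal (a gene is kept if any sample reaches
``min_count`` = 11) and up/down classification of an externally produced
differential-expression table (|log2FC| > 0.5, BH-adjusted p < 0.1).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_TERM_KEYWORDS = ("hemato", "stem cell", "chemotaxis", "vascul")


# ---------------------------------------------------------------------------
# Bulk pre-processing
# ---------------------------------------------------------------------------

def filter_low_counts(bulk: pd.DataFrame, min_count: int = 11) -> pd.DataFrame:
    """Remove genes that never reach ``min_count`` in any sample."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = (bulk >= min_count).any(axis=1)
    if not keep.any():
        raise ValueError("filter removed every gene")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_counts removed %d of %d genes", dropped, len(bulk))
    return bulk.loc[keep]


def classify_degs(
    table: pd.DataFrame, lfc_cut: float = 0.5, alpha: float = 0.1
) -> tuple[set[str], set[str]]:
    """Split a DE table (columns gene, log2fc, padj) into up/down gene sets."""
    for col in ("gene", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    sig = table["padj"] < alpha
    up = set(table.loc[sig & (table["log2fc"] > lfc_cut), "gene"])
    down = set(table.loc[sig & (table["log2fc"] < -lfc_cut), "gene"])
    return up, down


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_test(
    query: Iterable[str], term: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (overlap k, P(X >= k)) with X ~ Hypergeom(N=|universe|,
    K=|term|, n=|query|).
    """
    universe = set(universe)
    query = set(query)
    term = set(term) & universe
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query genes outside the universe")
    k = len(query & term)
    p = float(hypergeom.sf(k - 1, len(universe), len(term), len(query)))
    return k, min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The ligand chain
# ---------------------------------------------------------------------------

def _check_db(db: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand", "receptor"):
        if col not in db.columns:
            raise ValueError(f"LR database missing column {col!r}")
    if len(db) == 0:
        raise ValueError("empty LR database")
    db = db.drop_duplicates(subset=["ligand", "receptor"])
    if (db["ligand"].astype(str).str.len() == 0).any() or (db["receptor"].astype(str).str.len() == 0).any():
        raise ValueError("empty gene symbols in LR database")
    return db


def _kept_cells(clusters: pd.Series, keep_clusters: Sequence[str]) -> pd.Index:
    if len(keep_clusters) == 0:
        raise ValueError("keep_clusters must be non-empty")
    return clusters.index[clusters.isin(set(keep_clusters))]


def expressed_ligands(
    expr: pd.DataFrame,
    clusters: pd.Series,
    keep_clusters: Sequence[str],
    db: pd.DataFrame,
    min_cells: int = 3,
) -> set[str]:
    """Database ligands expressed (nonzero in >= min_cells cells) in the kept
    clusters."""
    db = _check_db(db)
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    cells = _kept_cells(clusters, keep_clusters)
    sub = expr.loc[expr.index.intersection(cells)]
    out = set()
    for lig in sorted(set(db["ligand"])):
        if lig in sub.columns and int((sub[lig] > 0).sum()) >= min_cells:
            out.add(lig)
    return out


def filter_ligands_by_terms(
    ligands: set[str],
    collection: pd.DataFrame,
    universe: Iterable[str],
    keywords: Sequence[str] = DEFAULT_TERM_KEYWORDS,
    alpha: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Restrict ligands to members of significant, keyword-matching terms.

    ORA is run for the ligand set against every term in the collection
    (BH-adjusted over terms); a term is selected if its adjusted p < alpha
    AND its name contains any keyword (case-insensitive substring).  Returns
    (ligands in the union of selected terms, per-term report).
    """
    if len(keywords) == 0:
        raise ValueError("keywords must be non-empty")
    for col in ("term_id", "term_name", "gene"):
        if col not in collection.columns:
            raise ValueError(f"gene-set collection missing column {col!r}")
    universe = set(universe)
    terms = collection.groupby("term_id").agg(
        term_name=("term_name", "first"), genes=("gene", lambda g: set(g))
    )
    matches = terms["term_name"].str.lower().apply(lambda n: any(k.lower() in n for k in keywords))
    if not matches.any():
        raise ValueError(
            "no term name matches the keywords; term names: "
            + ", ".join(terms["term_name"])
        )
    ks, ps = [], []
    for _, row in terms.iterrows():
        k, p = ora_test(ligands, row["genes"], universe)
        ks.append(k)
        ps.append(p)
    report = pd.DataFrame({
        "term_name": terms["term_name"],
        "overlap": ks,
        "pval": ps,
        "padj": bh_adjust(ps),
        "keyword_match": matches,
    }, index=terms.index)
    report["selected"] = (report["padj"] < alpha) & report["keyword_match"]
    member_union: set[str] = set()
    for tid in report.index[report["selected"]]:
        member_union |= terms.loc[tid, "genes"]
    return ligands & member_union, report


def count_filter(
    expr: pd.DataFrame,
    genes: set[str],
    clusters: pd.Series,
    keep_clusters: Sequence[str],
    min_total: int = 5,
) -> set[str]:
    """Genes with summed counts >= min_total across the kept clusters' cells."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    cells = _kept_cells(clusters, keep_clusters)
    sub = expr.loc[expr.index.intersection(cells)]
    out = set()
    for g in genes:
        if g in sub.columns and float(sub[g].sum()) >= min_total:
            out.add(g)
    return out


def receptor_filter(
    bulk: pd.DataFrame,
    receptors: set[str],
    groups: pd.Series,
    group: str = "control",
    min_mean: float = 40.0,
) -> set[str]:
    """Receptors whose mean raw count over the named group's samples is
    strictly greater than ``min_mean``; receptors absent from the bulk table
    are dropped with a warning."""
    if group not in set(groups):
        raise ValueError(f"group {group!r} not present")
    samples = groups.index[groups == group]
    missing = sorted(r for r in receptors if r not in bulk.index)
    if missing:
        logger.warning("receptors absent from bulk counts, dropped: %s", ", ".join(missing))
    out = set()
    for r in receptors - set(missing):
        if float(bulk.loc[r, samples].mean()) > min_mean:
            out.add(r)
    return out


def lr_edges(
    ligands: set[str],
    receptors: set[str],
    db: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Database pairs whose ligand and receptor both survived their filters.

    If expression and cluster labels are supplied, each edge is annotated
    with the per-cluster mean ligand expression (chord-plot-ready long
    table).  An empty result is allowed and logged.
    """
    db = _check_db(db)
    edges = db[db["ligand"].isin(ligands) & db["receptor"].isin(receptors)].copy()
    edges = edges.sort_values(["ligand", "receptor"]).reset_index(drop=True)
    if edges.empty:
        logger.info("no ligand-receptor edges survived the chain")
    if expr is not None and clusters is not None and not edges.empty:
        clusters = clusters.loc[clusters.index.intersection(expr.index)]
        means = expr.loc[clusters.index].groupby(clusters).mean()
        for c in means.index:
            edges[f"mean_expr_{c}"] = [
                float(means.loc[c, l]) if l in means.columns else np.nan
                for l in edges["ligand"]
            ]
    return edges


def run_lr_chain(
    expr: pd.DataFrame,
    clusters: pd.Series,
    keep_clusters: Sequence[str],
    db: pd.DataFrame,
    gene_sets: pd.DataFrame,
    bulk: pd.DataFrame,
    bulk_groups: pd.Series,
    min_cells: int = 3,
    keywords: Sequence[str] = DEFAULT_TERM_KEYWORDS,
    term_alpha: float = 0.05,
    min_total: int = 5,
    receptor_group: str = "control",
    receptor_min_mean: float = 40.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full inference chain; returns (edge table, stage report)."""
    lig0 = expressed_ligands(expr, clusters, keep_clusters, db, min_cells=min_cells)
    universe = set(expr.columns)
    lig1, term_report = filter_ligands_by_terms(
        lig0, gene_sets, universe, keywords=keywords, alpha=term_alpha
    )
    lig2 = count_filter(expr, lig1, clusters, keep_clusters, min_total=min_total)
    db_checked = _check_db(db)
    candidate_receptors = set(db_checked.loc[db_checked["ligand"].isin(lig2), "receptor"])
    rec = receptor_filter(
        bulk, candidate_receptors, bulk_groups, group=receptor_group, min_mean=receptor_min_mean
    )
    edges = lr_edges(lig2, rec, db, expr=expr, clusters=clusters)
    report = {
        "n_ligands_expressed": len(lig0),
        "n_ligands_in_terms": len(lig1),
        "n_ligands_count_filtered": len(lig2),
        "n_receptors_retained": len(rec),
        "n_edges": len(edges),
        "term_report": term_report,
    }
    return edges, report
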