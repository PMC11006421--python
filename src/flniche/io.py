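"""Table I/O, configuration, seeding and the end-to-end pipeline driver.

All inputs and outputs are plain text: TSV tables with validated headers
and MatrixMarket triplets with sidecar gene/cell name files for sparse
count matrices.  The pipeline (`run_pipeline`) chains simulation ->
iterative clustering -> SOM/consensus flow clustering -> cross-modality
correlation -> the spatial suite -> the ligand-receptor chain, writing
every intermediate table plus a run log; identical configurations produce
byte-identical artifacts.

Randomness discipline: every stage draws from a substream derived from the
global seed and the stage name, so adding or reordering stages never
perturbs another stage's random numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from . import cluster as _cluster
from . import lrnet as _lrnet
from . import spatial as _spatial
from . import syndata as _syndata
from . import xmod as _xmod

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Seed substreams
# ---------------------------------------------------------------------------

def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed
    and the stage name."""
    digest = hashlib.sha256(f"{int(global_seed)}::{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


# ---------------------------------------------------------------------------
# Typed table I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    table = pd.read_csv(path, sep=sep)
    for col in required:
        if col not in table.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    for col in numeric:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        elif table[col].isna().any():
            row = int(np.flatnonzero(table[col].isna().to_numpy())[0]) + 2
        else:
            table[col] = coerced
            continue
        raise ValueError(f"{path.name}: non-numeric value in column {col!r} at line {row}")
    return table


def read_cell_map(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, _spatial.CELL_MAP_COLUMNS, ["x_um", "y_um"])


def write_cell_map(cell_map: pd.DataFrame, path: str | Path) -> None:
    cell_map[_spatial.CELL_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Dense id x feature matrix with the id in the first column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    vals = table.apply(pd.to_numeric, errors="coerce")
    if vals.isna().to_numpy().any() and not table.isna().to_numpy().any():
        bad = np.argwhere(vals.isna().to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric value at line {bad[0] + 2}, column {table.columns[bad[1]]!r}"
        )
    return vals


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def write_expression_mtx(matrix: pd.DataFrame, directory: str | Path) -> None:
    """Write a cells x genes matrix as MatrixMarket triplet + name sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(matrix.to_numpy())
    scipy.io.mmwrite(directory / "matrix.mtx", sparse)
    (directory / "cells.txt").write_text("\n".join(map(str, matrix.index)) + "\n")
    (directory / "genes.txt").write_text("\n".join(map(str, matrix.columns)) + "\n")


def read_expression_mtx(directory: str | Path) -> pd.DataFrame:
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx").toarray()
    cells = (directory / "cells.txt").read_text().splitlines()
    genes = (directory / "genes.txt").read_text().splitlines()
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"MTX dimensions {mat.shape} do not match sidecars ({len(cells)} cells, {len(genes)} genes)"
        )
    return pd.DataFrame(mat, index=cells, columns=genes)


def read_lr_db(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["ligand", "receptor"], [])


def read_gene_sets(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["term_id", "term_name", "gene"], [])


def read_deg_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["gene", "log2fc", "padj"], ["log2fc", "padj"])


def read_assignment(path: str | Path) -> pd.Series:
    table = _read_tsv(path, ["id", "cluster"], [])
    return pd.Series(table["cluster"].astype(str).to_numpy(), index=table["id"], name="cluster")


def write_assignment(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"id": labels.index, "cluster": labels.to_numpy()}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """End-to-end run configuration; unknown keys in the file are rejected."""

    seed: int = 0
    outdir: str = "flniche_run"
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    spatial: dict = field(default_factory=dict)   # SpatialConfig overrides
    clustering: dict = field(default_factory=dict)  # RefineParams overrides + margin
    flow: dict = field(default_factory=dict)      # grid/epochs/K/resamples
    lr: dict = field(default_factory=dict)        # chain thresholds

    def sim_config(self) -> _syndata.SimConfig:
        known = {f.name for f in dataclasses.fields(_syndata.SimConfig)}
        _reject_unknown(self.sim, known, "sim")
        sim = dict(self.sim)
        # allow rules as plain mappings/sequences in YAML configs
        if "attraction_rules" in sim:
            sim["attraction_rules"] = [
                r if isinstance(r, _syndata.AttractionRule)
                else _syndata.AttractionRule(**r) if isinstance(r, dict)
                else _syndata.AttractionRule(*r)
                for r in sim["attraction_rules"]
            ]
        if "rosette_rules" in sim:
            sim["rosette_rules"] = [
                r if isinstance(r, _syndata.RosetteRule)
                else _syndata.RosetteRule(**r) if isinstance(r, dict)
                else _syndata.RosetteRule(*r)
                for r in sim["rosette_rules"]
            ]
        if "field_size" in sim:
            sim["field_size"] = tuple(sim["field_size"])
        cfg = _syndata.SimConfig(seed=stage_seed(self.seed, "simulate"), **sim)
        cfg.validate()
        return cfg

    def spatial_config(self) -> _spatial.SpatialConfig:
        known = {f.name for f in dataclasses.fields(_spatial.SpatialConfig)}
        _reject_unknown(self.spatial, known, "spatial")
        cfg = _spatial.SpatialConfig(**{"seed": stage_seed(self.seed, "spatial"), **self.spatial})
        cfg.validate()
        return cfg


def _reject_unknown(block: dict, known: set[str], name: str) -> None:
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    _reject_unknown(raw, known, "root")
    cfg = AnalysisConfig(**raw)
    if cfg.seed < 0:
        raise ValueError("seed must be >= 0")
    # validate nested blocks eagerly so misconfiguration fails before compute
    cfg.sim_config()
    cfg.spatial_config()
    for blk, keys in (
        ("clustering", {"scale", "n_pcs", "k", "metric", "resolution", "margin", "rounds"}),
        ("flow", {"grid", "epochs", "K", "resamples", "subsample_frac"}),
        ("lr", {"min_cells", "keywords", "term_alpha", "min_total", "receptor_group",
                "receptor_min_mean"}),
    ):
        _reject_unknown(getattr(cfg, blk), keys, blk)
    return cfg


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig, outdir: str | Path | None = None) -> dict:
    """Run simulate -> cluster -> flow -> xmod -> spatial -> LR end to end.

    Writes every intermediate table under ``outdir`` and returns a summary
    dictionary (also written as ``run_log.json``).  Identical configs yield
    byte-identical artifacts.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        sim_cfg = config.sim_config()
        cell_map, map_truth = _syndata.gen_cell_map(sim_cfg)
        expr, expr_truth = _syndata.gen_expression(sim_cfg)
        flow, flow_truth = _syndata.gen_flow(sim_cfg)
        bulk, bulk_groups, bulk_truth = _syndata.gen_bulk(sim_cfg)
        lr_fix = _syndata.gen_lr_fixtures(sim_cfg)

        write_cell_map(cell_map, out / "cell_map.tsv")
        write_expression_mtx(expr, out / "expression")
        write_matrix_tsv(flow, out / "flow_intensities.tsv", "event_id")
        write_matrix_tsv(bulk, out / "bulk_counts.tsv", "gene")
        bulk_groups.rename_axis("sample").to_frame().to_csv(out / "bulk_groups.tsv", sep="\t")
        lr_fix.db.to_csv(out / "lr_database.tsv", sep="\t", index=False)
        lr_fix.gene_sets.to_csv(out / "gene_sets.tsv", sep="\t", index=False)
        write_assignment(expr_truth.true_labels, out / "truth_expression_labels.tsv")
        write_assignment(flow_truth.true_labels, out / "truth_flow_labels.tsv")
        summary["stages"][stage] = {
            "n_cells_map": len(cell_map), "n_cells_expr": expr.shape[0],
            "n_genes": expr.shape[1], "n_events": flow.shape[0],
            "n_bulk_genes": bulk.shape[0],
        }

        stage = "cluster"
        cl = dict(config.clustering)
        margin = float(cl.pop("margin", 0.0))
        rounds_cfg = cl.pop("rounds", None)
        params = _cluster.RefineParams(seed=stage_seed(config.seed, stage), **cl)
        if rounds_cfg is None:
            rounds = _cluster.default_rounds(margin=margin)
        else:
            rounds = [_cluster.RefineRound(tuple(r["signature"]), float(r.get("margin", margin)))
                      for r in rounds_cfg]
        refined = _cluster.iterative_refine(expr, rounds, params)
        write_assignment(refined.labels, out / "scrna_clusters.tsv")
        refined.markers.to_csv(out / "scrna_markers.tsv", sep="\t", index=False)
        if refined.connectivity is not None:
            write_matrix_tsv(refined.connectivity, out / "scrna_connectivity.tsv", "cluster")
        pd.concat(refined.reports).to_csv(out / "scrna_selection_report.tsv", sep="\t")
        summary["stages"][stage] = {
            "n_cells_final": int(len(refined.labels)),
            "n_clusters_final": int(refined.labels.nunique()),
            "rounds": len(rounds),
        }

        stage = "flow"
        fl = dict(config.flow)
        grid = tuple(fl.get("grid", (10, 10)))
        epochs = int(fl.get("epochs", 20))
        K = int(fl.get("K", max(2, len(sim_cfg.flow_populations))))
        resamples = int(fl.get("resamples", 100))
        frac = float(fl.get("subsample_frac", 0.8))
        asinh = _cluster.asinh_transform(flow, cofactor=sim_cfg.asinh_cofactor)
        som, assign = _cluster.som_fit(asinh, grid=grid, epochs=epochs,
                                       seed=stage_seed(config.seed, stage))
        node_labels = _cluster.consensus_metacluster(
            som, K=K, resamples=resamples, subsample_frac=frac,
            seed=stage_seed(config.seed, "flow-consensus"),
        )
        flow_labels = _cluster.metacluster_events(assign, node_labels)
        write_assignment(flow_labels, out / "flow_metaclusters.tsv")
        summary["stages"][stage] = {"grid": list(grid), "K": K,
                                    "qe_final": som.qe_history[-1] if som.qe_history else None}

        stage = "xmod"
        norm = _cluster.normalize_log1p(expr.loc[refined.labels.index])
        flow_genes = _xmod.map_markers_to_genes(asinh)
        shared = [g for g in flow_genes.columns if g in norm.columns]
        if len(shared) >= 3:
            cent_rna = _xmod.cluster_centroids(norm, refined.labels, shared, method="mean")
            cent_flow = _xmod.cluster_centroids(flow_genes, flow_labels, shared, method="median")
            rho = _xmod.modality_correlation(cent_rna, cent_flow)
            write_matrix_tsv(rho, out / "xmod_spearman.tsv", "scrna_cluster")
            long = rho.stack().rename("rho").rename_axis(["scrna_cluster", "flow_cluster"]).reset_index()
            long.to_csv(out / "xmod_spearman_long.tsv", sep="\t", index=False)
            summary["stages"][stage] = {"n_mutual_markers": len(shared)}
        else:
            summary["stages"][stage] = {"n_mutual_markers": len(shared), "skipped": True}

        stage = "spatial"
        sp_cfg = config.spatial_config()
        itypes = sorted(t for t in cell_map["type"].unique() if t != "erythroblast")
        lor, pmat = _spatial.interaction_matrix(cell_map, itypes, sp_cfg)
        write_matrix_tsv(lor, out / "spatial_log_odds.tsv", "type")
        write_matrix_tsv(pmat, out / "spatial_log_odds_p.tsv", "type")
        mac_types = [t for t in cell_map["type"].unique() if t.startswith("mac_")]
        contact = {}
        for t in sorted(mac_types):
            try:
                res = _spatial.contact_fraction(cell_map, t, "erythroblast", sp_cfg)
                contact[t] = res.fraction
            except ValueError:
                continue
        pd.Series(contact, name="contact_fraction").rename_axis("type").to_frame().to_csv(
            out / "spatial_contact_fractions.tsv", sep="\t"
        )
        census_center = "hsc" if "hsc" in set(cell_map["type"]) else itypes[0]
        try:
            census = _spatial.radius_census(cell_map, census_center, sorted(mac_types), sp_cfg)
            census.counts.rename_axis("center").to_csv(out / "spatial_census.tsv", sep="\t")
            census_stats = {"anova_f": census.anova_f, "anova_p": census.anova_p}
        except ValueError as exc:
            census_stats = {"skipped": str(exc)}
        raster = _spatial.raster_neighborhoods(cell_map, sp_cfg, types_subset=sorted(mac_types))
        n_labels, n_comp = _spatial.neighborhood_cluster(
            raster, K=min(4, len(raster.composition)), seed=stage_seed(config.seed, stage)
        )
        raster.composition.join(n_labels).rename_axis("window").to_csv(
            out / "spatial_neighborhoods.tsv", sep="\t"
        )
        n_comp.rename_axis("neighborhood").to_csv(out / "spatial_neighborhood_composition.tsv", sep="\t")
        summary["stages"][stage] = {"n_in_band_types": len(itypes), **census_stats,
                                    "n_windows": int(len(raster.composition))}

        stage = "lr"
        lr_kwargs = dict(config.lr)
        if "keywords" in lr_kwargs:
            lr_kwargs["keywords"] = tuple(lr_kwargs["keywords"])
        edges, lr_report = _lrnet.run_lr_chain(
            lr_fix.expression, lr_fix.clusters, lr_fix.keep_clusters,
            lr_fix.db, lr_fix.gene_sets, lr_fix.bulk, lr_fix.bulk_groups, **lr_kwargs,
        )
        edges.to_csv(out / "lr_edges.tsv", sep="\t", index=False)
        lr_report["term_report"].rename_axis("term_id").to_csv(out / "lr_term_report.tsv", sep="\t")
        summary["stages"][stage] = {k: v for k, v in lr_report.items() if k != "term_report"}
        summary["stages"][stage]["truth_edges"] = sorted(map(list, lr_fix.truth.true_lr_edges))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["config"] = {
        "seed": config.seed, "sim": config.sim, "spatial": config.spatial,
        "clustering": config.clustering, "flow": config.flow, "lr": config.lr,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
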