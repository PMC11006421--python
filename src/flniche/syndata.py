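"""Synthetic inputs with known ground truth for the fetal-liver niche pipeline.

Every downstream stage of the pipeline (clustering, cross-modality
correlation, spatial statistics, ligand-receptor inference) consumes
tabular inputs that, in a real study, come from single-cell RNA-seq,
high-dimensional cytometry, multiplexed-imaging segmentation, and bulk
RNA-seq.  This module generates all of them from a single :class:`SimConfig`
with planted structure, so recovery can be checked against an explicit
:class:`GroundTruth`:

* typed 2D cell-centroid maps with homogeneous-Poisson background,
  Thomas-process style pairwise attraction (offspring scattered
  isotropically around parents), and "rosette" motifs emulating
  erythroblastic islands (a core macrophage ringed by erythroblasts);
* negative-binomial cell-by-gene count matrices with planted
  marker-signature populations and an optional progenitor population whose
  mean profile bridges two mature populations;
* cytometry event-by-marker intensities drawn as Gaussians in asinh space
  and back-transformed;
* two-group bulk counts with planted log2 fold-changes;
* a small ligand-receptor database plus gene-set collection fixture in
  which the pairs surviving the full inference chain are known by
  construction.

All generators are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Per-generator substream keys: adding a generator never perturbs the
# randomness of existing ones for the same config seed.
_STREAM = {"cell_map": 0, "expression": 1, "flow": 2, "bulk": 3, "lr": 4, "matched": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM[stream],)))


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttractionRule:
    """Thomas-process style attraction: `offspring_per_parent` offspring of
    `offspring_type` are scattered N(0, dispersion_sd^2 I) around each parent."""

    parent_type: str
    offspring_type: str
    dispersion_sd: float = 20.0
    offspring_per_parent: int = 5


@dataclass(frozen=True)
class RosetteRule:
    """Erythroblastic-island motif: each core is ringed by `n_satellites`
    satellite cells placed at radius <= contact_radius."""

    core_type: str
    satellite_type: str
    n_satellites: int = 8
    contact_radius: float = 6.0


# Population marker signatures used by the default expression simulation.
# Gene symbols follow the field's mouse nomenclature: pan-macrophage
# (Adgre1/F4-80, Mrc1/CD206, Siglec1/CD169, Timd4/Tim4, Vcam1/CD106),
# precursor (Csf1r, Cx3cr1, Ccr2, Clec7a) and decoy monocyte/granulocyte
# programs (Ly6c2, Ly6g, Mpo, Elane, Ctsg).
DEFAULT_POPULATIONS: dict[str, int] = {
    "progenitor": 80,
    "mac_inflam": 100,
    "mac_timd4": 100,
    "mac_marco": 100,
    "monocyte": 110,
    "granulocyte": 110,
}

DEFAULT_SIGNATURES: dict[str, list[str]] = {
    "progenitor": ["Csf1r", "Cx3cr1", "Ccr2", "Clec7a", "Kit"],
    "mac_inflam": ["Adgre1", "Msr1", "Cd63", "Il1b", "S100a6", "Clec4a3"],
    "mac_timd4": ["Adgre1", "Mrc1", "Timd4", "Siglec1", "Vcam1", "Lyve1"],
    "mac_marco": ["Adgre1", "Mrc1", "Siglec1", "Msr1", "Marco", "Clec4f"],
    "monocyte": ["Ly6c2", "Ccr2", "Cd33", "Itgam"],
    "granulocyte": ["Ly6g", "Cxcr2", "Mpo", "Elane", "Ctsg"],
}

# asinh means per cytometry population per marker (separation added on top
# of a common baseline); markers are panel protein names.
DEFAULT_FLOW_MARKERS: list[str] = [
    "F4/80", "Tim4", "CD206", "CD169", "CD106", "CD115", "Cx3cr1", "Ly6C",
]
DEFAULT_FLOW_POPULATIONS: dict[str, int] = {"mac_A": 300, "mac_B": 300, "mac_C": 400}
DEFAULT_FLOW_HIGH: dict[str, list[str]] = {
    "mac_A": ["F4/80", "Tim4", "CD106"],
    "mac_B": ["F4/80", "Tim4", "CD206", "Cx3cr1"],
    "mac_C": ["F4/80", "Tim4", "CD169", "CD206"],
}

DEFAULT_CELL_COUNTS: dict[str, int] = {
    "mac_A": 250,
    "mac_B": 250,
    "mac_C": 300,
    "mac_EI": 400,
    "erythroblast": 1200,
    "vessel": 150,
}


@dataclass
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults emulate a desk-scale version of an E14.5 fetal-liver dataset:
    a 2x2 mm imaging field with a few thousand typed centroids, a sorted
    myeloid scRNA-seq matrix with macrophage and decoy populations, a
    downsampled macrophage cytometry panel, and a 4-control / 6-knockout
    bulk design.
    """

    seed: int = 0

    # --- cell map ---
    n_cells_per_type: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    field_size: tuple[float, float] = (2000.0, 2000.0)
    attraction_rules: Sequence[AttractionRule] = field(
        default_factory=lambda: [AttractionRule("mac_C", "hsc", 20.0, 1)]
    )
    rosette_rules: Sequence[RosetteRule] = field(
        default_factory=lambda: [RosetteRule("mac_EI", "erythroblast", 6, 6.0)]
    )

    # --- expression ---
    populations: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    population_signatures: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()}
    )
    progenitor_bridge: tuple[str, str, str] | None = ("progenitor", "mac_inflam", "mac_timd4")
    n_genes: int = 600
    nb_mean: float = 1.0          # median of the lognormal per-gene baseline mean
    nb_dispersion: float = 0.5    # NB dispersion alpha (var = m + alpha m^2)
    signature_effect: float = 8.0  # multiplicative mean shift of signature genes

    # --- flow ---
    flow_populations: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_FLOW_POPULATIONS))
    flow_markers: Sequence[str] = field(default_factory=lambda: list(DEFAULT_FLOW_MARKERS))
    flow_high_markers: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FLOW_HIGH.items()}
    )
    flow_baseline: float = 0.5     # asinh units
    flow_separation: float = 3.0   # added to high markers, asinh units
    flow_sd: float = 0.35          # isotropic s.d. in asinh space
    flow_cov: np.ndarray | None = None  # optional full covariance (asinh space)
    asinh_cofactor: float = 150.0

    # --- bulk ---
    n_bulk_genes: int = 400
    bulk_group_sizes: Mapping[str, int] = field(default_factory=lambda: {"control": 4, "knockout": 6})
    planted_lfc: float = 2.0
    n_planted_up: int = 20
    n_planted_down: int = 20
    bulk_base_mean: float = 100.0

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field dimensions must be positive")
        for t, n in self.n_cells_per_type.items():
            if n < 0:
                raise ValueError(f"negative cell count for type {t!r}")
        for r in self.attraction_rules:
            if r.dispersion_sd <= 0:
                raise ValueError("dispersion_sd must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not np.isfinite(self.signature_effect) or not np.isfinite(self.planted_lfc):
            raise ValueError("planted effects must be finite")


@dataclass
class GroundTruth:
    """Planted truth accompanying each generated object."""

    true_labels: pd.Series | None = None
    true_interacting_pairs: set[tuple[str, str]] = field(default_factory=set)
    true_lr_edges: set[tuple[str, str]] = field(default_factory=set)
    true_deg_up: set[str] = field(default_factory=set)
    true_deg_down: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Cell map
# ---------------------------------------------------------------------------

def gen_cell_map(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a typed 2D centroid table (`cell_id, x_um, y_um, type`).

    Background types are scattered uniformly (homogeneous Poisson conditioned
    on the requested counts); attraction rules add offspring around parents
    (isotropic Gaussian, rejection-resampled inside the field); rosette rules
    ring each core with satellites within the contact radius.  Rosette cores are
    inset from the field boundary by the contact radius so the ring always
    fits.
    """
    config.validate()
    rng = _rng(config.seed, "cell_map")
    w, h = config.field_size

    placed_types = set(config.n_cells_per_type)
    for r in config.attraction_rules:
        if r.parent_type not in placed_types:
            raise ValueError(f"attraction rule references unknown parent type {r.parent_type!r}")
    core_types = {r.core_type for r in config.rosette_rules}
    for r in config.rosette_rules:
        if r.core_type not in placed_types:
            raise ValueError(f"rosette rule references unknown core type {r.core_type!r}")

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    types: list[str] = []
    parents: dict[str, np.ndarray] = {}

    for t in config.n_cells_per_type:
        n = config.n_cells_per_type[t]
        if n == 0:
            continue
        if t in core_types:
            # inset so every satellite ring fits inside the field
            inset = max(r.contact_radius for r in config.rosette_rules if r.core_type == t)
            x = rng.uniform(inset, w - inset, n)
            y = rng.uniform(inset, h - inset, n)
        else:
            x = rng.uniform(0.0, w, n)
            y = rng.uniform(0.0, h, n)
        xs.append(x)
        ys.append(y)
        types.extend([t] * n)
        parents[t] = np.column_stack([x, y])

    for rule in config.attraction_rules:
        pxy = parents[rule.parent_type]
        n_off = rule.offspring_per_parent * len(pxy)
        centers = np.repeat(pxy, rule.offspring_per_parent, axis=0)
        pts = centers + rng.normal(0.0, rule.dispersion_sd, size=(n_off, 2))
        outside = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        while outside.any():
            k = int(outside.sum())
            pts[outside] = centers[outside] + rng.normal(0.0, rule.dispersion_sd, size=(k, 2))
            outside = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        types.extend([rule.offspring_type] * n_off)

    for rule in config.rosette_rules:
        cxy = parents[rule.core_type]
        n_sat = rule.n_satellites * len(cxy)
        centers = np.repeat(cxy, rule.n_satellites, axis=0)
        radius = rule.contact_radius * rng.uniform(0.5, 1.0, n_sat)
        theta = rng.uniform(0.0, 2 * np.pi, n_sat)
        pts = centers + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        np.clip(pts[:, 0], 0.0, w, out=pts[:, 0])
        np.clip(pts[:, 1], 0.0, h, out=pts[:, 1])
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        types.extend([rule.satellite_type] * n_sat)

    if not types:
        raise ValueError("configuration produced zero cells")

    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    ids = [f"c{i:06d}" for i in range(len(types))]
    cell_map = pd.DataFrame({"cell_id": ids, "x_um": x_all, "y_um": y_all, "type": types})

    truth = GroundTruth(
        true_labels=pd.Series(types, index=ids, name="type"),
        true_interacting_pairs=(
            {(r.parent_type, r.offspring_type) for r in config.attraction_rules}
            | {(r.core_type, r.satellite_type) for r in config.rosette_rules}
        ),
    )
    return cell_map, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with var = m + alpha m^2."""
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def gen_expression(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cells x genes count matrix with planted signature populations.

    Each population multiplies its signature genes' baseline means by
    ``signature_effect``.  If ``progenitor_bridge=(prog, a, b)`` is set, the
    progenitor population's mean profile is the geometric mean of the two
    bridged populations' profiles (before overlaying its own signature),
    yielding the intermediate transcriptome that links the mature
    populations in a cluster graph.
    """
    config.validate()
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    pops = dict(config.populations)
    if len(pops) < 2:
        raise ValueError("need at least 2 planted populations")

    sig_genes: list[str] = []
    for p, genes in config.population_signatures.items():
        for g in genes:
            if g not in sig_genes:
                sig_genes.append(g)
    if config.n_genes < len(sig_genes):
        raise ValueError("n_genes smaller than the number of distinct signature genes")
    fillers = [f"Gene{i:04d}" for i in range(config.n_genes - len(sig_genes))]
    gene_ids = sig_genes + fillers
    gidx = {g: i for i, g in enumerate(gene_ids)}

    rng = _rng(config.seed, "expression")
    base = config.nb_mean * rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    # marker genes are, by definition, detectably expressed: pin their
    # baseline at nb_mean so the planted effect is exactly signature_effect
    # on a unit-baseline gene rather than scaled by a random draw
    base[: len(sig_genes)] = config.nb_mean

    # per-population multiplicative profile
    mult = {p: np.ones(config.n_genes) for p in pops}
    for p in pops:
        for g in config.population_signatures.get(p, []):
            mult[p][gidx[g]] = config.signature_effect
    if config.progenitor_bridge is not None:
        prog, a, b = config.progenitor_bridge
        if prog in mult and a in mult and b in mult:
            bridged = np.sqrt(mult[a] * mult[b])
            own = np.ones(config.n_genes)
            for g in config.population_signatures.get(prog, []):
                own[gidx[g]] = config.signature_effect
            mult[prog] = np.maximum(bridged, own)

    blocks = []
    labels: list[str] = []
    for p, n in pops.items():
        if n <= 0:
            continue
        mean = base * mult[p]
        blocks.append(_nb_counts(rng, np.broadcast_to(mean, (n, config.n_genes)), config.nb_dispersion))
        labels.extend([p] * n)
    counts = np.vstack(blocks)
    cell_ids = [f"cell{i:05d}" for i in range(len(labels))]
    matrix = pd.DataFrame(counts, index=cell_ids, columns=gene_ids)
    truth = GroundTruth(true_labels=pd.Series(labels, index=cell_ids, name="population"))
    return matrix, truth


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

def gen_flow(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an events x markers intensity table.

    Events are drawn per population from a multivariate Gaussian in
    asinh(x / cofactor) space and back-transformed with
    ``x = cofactor * sinh(z)`` clipped at zero, emulating compensated
    cytometry intensities.
    """
    config.validate()
    pops = {p: n for p, n in config.flow_populations.items()}
    markers = list(config.flow_markers)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    if not pops or sum(pops.values()) == 0:
        raise ValueError("zero events requested")

    d = len(markers)
    if config.flow_cov is not None:
        cov = np.asarray(config.flow_cov, float)
        if cov.shape != (d, d):
            raise ValueError("flow_cov shape mismatch")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("flow_cov is singular or not positive definite") from exc
    else:
        cov = np.eye(d) * config.flow_sd**2

    rng = _rng(config.seed, "flow")
    rows = []
    labels: list[str] = []
    for p, n in pops.items():
        if n <= 0:
            continue
        mu = np.full(d, config.flow_baseline)
        for m in config.flow_high_markers.get(p, []):
            if m in markers:
                mu[markers.index(m)] += config.flow_separation
        z = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        rows.append(np.maximum(config.asinh_cofactor * np.sinh(z), 0.0))
        labels.extend([p] * n)
    if not rows:
        raise ValueError("zero events requested")
    intens = np.vstack(rows)
    event_ids = [f"ev{i:05d}" for i in range(len(labels))]
    table = pd.DataFrame(intens, index=event_ids, columns=markers)
    truth = GroundTruth(true_labels=pd.Series(labels, index=event_ids, name="population"))
    return table, truth


# ---------------------------------------------------------------------------
# Bulk counts
# ---------------------------------------------------------------------------

def gen_bulk(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate genes x samples NB counts for a two-group design.

    Returns (counts, sample_groups, truth); planted up/down genes are shifted
    by ``planted_lfc`` log2 units in the second group.
    """
    config.validate()
    groups = dict(config.bulk_group_sizes)
    if len(groups) != 2 or any(n < 2 for n in groups.values()):
        raise ValueError("need two groups with >= 2 samples each")
    (g1, n1), (g2, n2) = groups.items()

    n_up, n_dn = config.n_planted_up, config.n_planted_down
    up = [f"UpGene{i:03d}" for i in range(n_up)]
    dn = [f"DnGene{i:03d}" for i in range(n_dn)]
    fill = [f"BulkGene{i:04d}" for i in range(config.n_bulk_genes - n_up - n_dn)]
    genes = up + dn + fill

    rng = _rng(config.seed, "bulk")
    base = config.bulk_base_mean * rng.lognormal(0.0, 1.0, size=len(genes))
    fc = np.ones(len(genes))
    fc[:n_up] = 2.0**config.planted_lfc
    fc[n_up:n_up + n_dn] = 2.0**-config.planted_lfc

    m1 = np.broadcast_to(base[:, None], (len(genes), n1))
    m2 = np.broadcast_to((base * fc)[:, None], (len(genes), n2))
    c1 = _nb_counts(rng, m1, config.nb_dispersion)
    c2 = _nb_counts(rng, m2, config.nb_dispersion)
    samples = [f"{g1}_{i+1}" for i in range(n1)] + [f"{g2}_{i+1}" for i in range(n2)]
    counts = pd.DataFrame(np.hstack([c1, c2]), index=genes, columns=samples)
    sample_groups = pd.Series([g1] * n1 + [g2] * n2, index=samples, name="group")
    truth = GroundTruth(true_deg_up=set(up), true_deg_down=set(dn))
    return counts, sample_groups, truth


# ---------------------------------------------------------------------------
# Ligand-receptor fixture
# ---------------------------------------------------------------------------

@dataclass
class LRFixture:
    """A fully wired ligand-receptor inference test case.

    The expression matrix, cluster labels, bulk counts and database are
    constructed so that the set of pairs surviving the full threshold chain
    (expressed in >= min_cells kept cells -> member of a significant
    keyword-matching term -> summed counts >= 5 -> receptor control mean
    > 40) is known exactly and recorded in ``truth.true_lr_edges``.
    """

    db: pd.DataFrame                 # columns ligand, receptor
    gene_sets: pd.DataFrame          # columns term_id, term_name, gene
    expression: pd.DataFrame         # cells x genes counts
    clusters: pd.Series              # cell -> cluster label
    keep_clusters: tuple[str, ...]
    bulk: pd.DataFrame               # genes x samples
    bulk_groups: pd.Series
    truth: GroundTruth


def gen_lr_fixtures(config: SimConfig) -> LRFixture:
    """Build the ligand-receptor fixture bundle (see :class:`LRFixture`).

    Twelve ligand-receptor pairs cover every way a pair can fail the chain:
    ligand not expressed, ligand outside the selected terms, ligand below
    the 5-count filter (including the 4-vs-5 boundary), and receptor at or
    below the 40-count mean (including the 40.0-vs-40.1 boundary).
    """
    config.validate()
    rng = _rng(config.seed, "lr")

    # flags per ligand: (expressed, in_hemato_term, passes_count_filter)
    lig_flags = {
        "Lig01": (True, True, True),
        "Lig02": (True, True, True),
        "Lig03": (True, True, True),
        "Lig04": (True, True, False),   # total counts 4 (boundary fail)
        "Lig05": (True, False, True),   # not in any selected term
        "Lig06": (False, True, True),   # nonzero in too few cells
        "Lig07": (True, True, True),
        "Lig08": (False, False, False),
        "Lig09": (True, True, True),
        "Lig10": (True, False, False),
    }
    # receptor control means; strict > 40 retains
    rec_means = {
        "Rec01": 100.0, "Rec02": 80.0, "Rec03": 41.0, "Rec04": 40.0,
        "Rec05": 10.0, "Rec06": 120.0, "Rec07": 40.1, "Rec08": 0.0,
    }
    pairs = [
        ("Lig01", "Rec01"), ("Lig01", "Rec02"), ("Lig02", "Rec03"),
        ("Lig03", "Rec04"), ("Lig04", "Rec01"), ("Lig05", "Rec02"),
        ("Lig06", "Rec06"), ("Lig07", "Rec05"), ("Lig08", "Rec08"),
        ("Lig09", "Rec07"), ("Lig10", "Rec06"), ("Lig02", "Rec06"),
    ]
    db = pd.DataFrame(pairs, columns=["ligand", "receptor"])

    # --- expression: 3 kept macrophage clusters + 1 decoy cluster ---
    keep = ("mac_1", "mac_2", "mac_3")
    cells_per = 12
    clusters = []
    for name in keep + ("decoy",):
        clusters += [(f"{name}_cell{i:02d}", name) for i in range(cells_per)]
    cell_ids = [c for c, _ in clusters]
    labels = pd.Series([l for _, l in clusters], index=cell_ids, name="cluster")

    fill_genes = [f"Bg{i:03d}" for i in range(40)]
    genes = list(lig_flags) + fill_genes
    expr = pd.DataFrame(0, index=cell_ids, columns=genes, dtype=int)
    kept_cells = [c for c in cell_ids if labels[c] != "decoy"]
    min_cells = 3
    for lig, (expressed, _term, count_ok) in lig_flags.items():
        if expressed and count_ok:
            chosen = rng.choice(kept_cells, size=min_cells + 1, replace=False)
            expr.loc[chosen, lig] = [3, 2, 1, 1]  # total 7 >= 5
        elif expressed and not count_ok:
            chosen = rng.choice(kept_cells, size=min_cells, replace=False)
            expr.loc[chosen, lig] = [2, 1, 1]     # total 4 < 5 (boundary)
        else:
            chosen = rng.choice(kept_cells, size=min_cells - 1, replace=False)
            expr.loc[chosen, lig] = [5, 3]        # high counts but too few cells
    for g in fill_genes:
        chosen = rng.choice(cell_ids, size=6, replace=False)
        expr.loc[chosen, g] = rng.integers(1, 5, size=6)

    # --- gene sets: one hemato term capturing the planted ligands, one
    # significant decoy without a matching name, one keyword term with no
    # enrichment ---
    hemato_members = [l for l, f in lig_flags.items() if f[1]] + fill_genes[:2]
    decoy_members = fill_genes[2:10]
    vascular_members = fill_genes[10:30]
    rows = (
        [("T001", "regulation of hematopoiesis (synthetic)", g) for g in hemato_members]
        + [("T002", "ribosome biogenesis (synthetic)", g) for g in decoy_members]
        + [("T003", "vasculature development (synthetic)", g) for g in vascular_members]
    )
    gene_sets = pd.DataFrame(rows, columns=["term_id", "term_name", "gene"])

    # --- bulk: receptors with pinned control means ---
    ctrl_n, ko_n = 4, 6
    bulk_genes = list(rec_means) + [f"BulkBg{i:03d}" for i in range(30)]
    samples = [f"control_{i+1}" for i in range(ctrl_n)] + [f"knockout_{i+1}" for i in range(ko_n)]
    bulk = pd.DataFrame(0.0, index=bulk_genes, columns=samples)
    for rec, mean in rec_means.items():
        # exact control mean by construction; knockout values free
        ctrl = np.full(ctrl_n, mean)
        ctrl[0] = mean + 0.2 if mean > 0 else 0.0
        ctrl[1] = max(mean - 0.2, 0.0) if mean > 0 else 0.0
        if abs(ctrl.mean() - mean) > 1e-9:  # keep the mean pinned exactly
            ctrl = np.full(ctrl_n, mean)
        bulk.loc[rec, samples[:ctrl_n]] = ctrl
        bulk.loc[rec, samples[ctrl_n:]] = rng.integers(0, 200, size=ko_n).astype(float)
    for g in bulk_genes[len(rec_means):]:
        bulk.loc[g] = rng.integers(0, 150, size=ctrl_n + ko_n).astype(float)
    bulk = bulk.round(1)
    bulk_groups = pd.Series(["control"] * ctrl_n + ["knockout"] * ko_n, index=samples, name="group")

    # --- truth, by construction (independent of the inference code) ---
    true_edges = set()
    for lig, rec in pairs:
        expressed, in_term, count_ok = lig_flags[lig]
        if expressed and in_term and count_ok and rec_means[rec] > 40.0:
            true_edges.add((lig, rec))
    truth = GroundTruth(true_lr_edges=true_edges)

    return LRFixture(
        db=db, gene_sets=gene_sets, expression=expr, clusters=labels,
        keep_clusters=keep, bulk=bulk, bulk_groups=bulk_groups, truth=truth,
    )


# ---------------------------------------------------------------------------
# Matched modalities (for cross-modality correspondence experiments)
# ---------------------------------------------------------------------------

def gen_matched_modalities(
    seed: int,
    n_pops: int = 4,
    markers: Sequence[str] | None = None,
    cells_per_pop: int = 40,
    events_per_pop: int = 80,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Generate paired scRNA counts and flow intensities from shared profiles.

    A latent per-population, per-marker level v is drawn once; scRNA counts
    are Poisson with mean exp(v) for the marker gene and flow events are
    Gaussian around v in asinh space.  Because both modalities are monotone
    transforms of the same v, the true cluster correspondence is the
    identity, which rank correlation should recover.
    """
    if markers is None:
        markers = ["Adgre1", "Timd4", "Mrc1", "Siglec1", "Vcam1", "Csf1r", "Cx3cr1", "Ly6c2"]
    markers = list(markers)
    rng = _rng(seed, "matched")
    v = rng.uniform(0.0, 3.0, size=(n_pops, len(markers)))

    pop_names = [f"pop{i}" for i in range(n_pops)]
    expr_rows, expr_labels = [], []
    flow_rows, flow_labels = [], []
    for i, p in enumerate(pop_names):
        lam = np.exp(v[i])
        expr_rows.append(rng.poisson(np.broadcast_to(lam, (cells_per_pop, len(markers)))))
        expr_labels += [p] * cells_per_pop
        z = v[i] + rng.normal(0.0, 0.15, size=(events_per_pop, len(markers)))
        flow_rows.append(np.maximum(150.0 * np.sinh(z), 0.0))
        flow_labels += [p] * events_per_pop

    expr = pd.DataFrame(
        np.vstack(expr_rows),
        index=[f"cell{i:05d}" for i in range(n_pops * cells_per_pop)],
        columns=markers,
    )
    flow = pd.DataFrame(
        np.vstack(flow_rows),
        index=[f"ev{i:05d}" for i in range(n_pops * events_per_pop)],
        columns=markers,
    )
    expr_lab = pd.Series(expr_labels, index=expr.index, name="population")
    flow_lab = pd.Series(flow_labels, index=flow.index, name="population")
    return expr, expr_lab, flow, flow_lab
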