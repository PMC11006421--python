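"""Point-pattern statistics on typed cell-centroid maps.

Implements the spatial readouts used to relate macrophage subsets, HSCs and
erythroblasts on 2D segmented-tissue centroid tables:

* in-band pair enumeration (default 5-50 um interaction band);
* type-pair interaction log-odds with a label-permutation null;
* nearest-neighbour distances between typed cells and group comparison;
* density enrichment of one type near another (3 um default);
* radius census around sampled centre cells (50 um, 20 centres) + ANOVA;
* contact fractions of sampled cells against a partner type (6 um);
* raster-scan neighbourhood composition windows and SOM/consensus
  neighbourhood clustering;
* pixel-level Pearson colocalization and two-step marker gating.

The interaction log-odds statistic is built over ordered in-band pairs
(u, v): the 2x2 table cross-tabulates [u is A] x [v is B], the odds ratio
gets a Haldane-Anscombe +0.5 correction when any cell is empty, and the
p-value shuffles type labels over cells with positions fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import f_oneway, mannwhitneyu, ttest_ind

logger = logging.getLogger(__name__)

CELL_MAP_COLUMNS = ["cell_id", "x_um", "y_um", "type"]


@dataclass
class SpatialConfig:
    """Radii, sample sizes and permutation settings (distances in um)."""

    band_min: float = 5.0
    band_max: float = 50.0
    census_radius: float = 50.0
    contact_radius: float = 6.0
    density_radius: float = 3.0
    n_census_centers: int = 20
    n_contact_sample: int = 50
    n_permutations: int = 1000
    raster_step: float = 50.0
    min_window_cells: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.band_min < self.band_max:
            raise ValueError("need 0 <= band_min < band_max")
        for r in (self.census_radius, self.contact_radius, self.density_radius, self.raster_step):
            if r <= 0:
                raise ValueError("radii and raster_step must be > 0")
        for c in (self.n_census_centers, self.n_contact_sample, self.n_permutations):
            if c < 1:
                raise ValueError("counts must be >= 1")


def _check_map(cell_map: pd.DataFrame) -> None:
    missing = [c for c in CELL_MAP_COLUMNS if c not in cell_map.columns]
    if missing:
        raise ValueError(f"cell map missing columns: {', '.join(missing)}")
    if len(cell_map) == 0:
        raise ValueError("empty cell map")


def _xy(cell_map: pd.DataFrame) -> np.ndarray:
    return cell_map[["x_um", "y_um"]].to_numpy(float)


# ---------------------------------------------------------------------------
# Pairs and interaction log-odds
# ---------------------------------------------------------------------------

def pairs_within_band(
    cell_map: pd.DataFrame, band_min: float = 5.0, band_max: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered distinct-cell pairs with band_min <= distance <= band_max.

    Returns (pairs, distances) where pairs is an (m, 2) array of row indices
    into ``cell_map`` with pairs[:, 0] < pairs[:, 1].
    """
    _check_map(cell_map)
    if not 0 <= band_min < band_max:
        raise ValueError("need 0 <= band_min < band_max")
    xy = _xy(cell_map)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(band_max, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
    keep = d >= band_min
    pairs, d = pairs[keep], d[keep]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order], d[order]


@dataclass
class InteractionResult:
    type_pair: tuple[str, str]
    table: np.ndarray            # 2x2 ordered-pair counts [[n11, n10], [n01, n00]]
    log_odds: float
    p_value: float | None
    n_permutations: int
    undefined: bool = False


def _lor_from_counts(n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray) -> np.ndarray:
    n11, n10, n01, n00 = (np.asarray(a, float) for a in (n11, n10, n01, n00))
    zero = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    h = np.where(zero, 0.5, 0.0)
    return np.log((n11 + h) * (n00 + h) / ((n10 + h) * (n01 + h)))


def interaction_log_odds_from_pairs(
    pairs: np.ndarray,
    is_a: np.ndarray,
    is_b: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    type_pair: tuple[str, str] = ("A", "B"),
) -> InteractionResult:
    """Interaction log-odds from precomputed unordered in-band pairs.

    ``is_a`` / ``is_b`` are boolean membership masks over cells.  Ordered
    pairs are both orientations of each unordered pair.  The permutation
    null shuffles cell labels jointly (positions fixed); the p-value is
    (1 + #{|LOR*| >= |LOR|}) / (n_permutations + 1).
    """
    if pairs.shape[0] == 0:
        return InteractionResult(type_pair, np.zeros((2, 2)), np.nan, None, 0, undefined=True)
    rng = np.random.default_rng(0) if rng is None else rng
    iu = np.concatenate([pairs[:, 0], pairs[:, 1]])
    iv = np.concatenate([pairs[:, 1], pairs[:, 0]])
    m = iu.size
    n = is_a.size

    def counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
        au, bv = a[iu], b[iv]
        n11 = int(np.count_nonzero(au & bv))
        na = int(np.count_nonzero(au))
        nb = int(np.count_nonzero(bv))
        return n11, na - n11, nb - n11, m - na - nb + n11

    n11, n10, n01, n00 = counts(is_a, is_b)
    lor = float(_lor_from_counts(n11, n10, n01, n00))
    table = np.array([[n11, n10], [n01, n00]])

    # vectorised label permutations, chunked to bound memory
    abs_lor = abs(lor)
    exceed = 0
    chunk = max(1, int(2_000_000 // max(m, 1)))
    done = 0
    while done < n_permutations:
        b_sz = min(chunk, n_permutations - done)
        perms = np.empty((b_sz, n), dtype=np.int64)
        for r in range(b_sz):
            perms[r] = rng.permutation(n)
        au = is_a[perms][:, iu]
        bv = is_b[perms][:, iv]
        c11 = np.count_nonzero(au & bv, axis=1)
        ca = np.count_nonzero(au, axis=1)
        cb = np.count_nonzero(bv, axis=1)
        lors = _lor_from_counts(c11, ca - c11, cb - c11, m - ca - cb + c11)
        exceed += int(np.count_nonzero(np.abs(lors) >= abs_lor - 1e-12))
        done += b_sz
    p = (1 + exceed) / (n_permutations + 1)
    return InteractionResult(type_pair, table, lor, p, n_permutations)


def interaction_log_odds(
    cell_map: pd.DataFrame,
    type_a: str,
    type_b: str,
    config: SpatialConfig | None = None,
    rng: np.random.Generator | None = None,
) -> InteractionResult:
    """Spatial interaction log-odds of two cell types within the distance band."""
    config = config or SpatialConfig()
    config.validate()
    _check_map(cell_map)
    types = cell_map["type"].to_numpy()
    for t in (type_a, type_b):
        if t not in types:
            raise ValueError(f"type {t!r} absent from the map")
    pairs, _ = pairs_within_band(cell_map, config.band_min, config.band_max)
    if pairs.shape[0] == 0:
        logger.warning("no in-band pairs; interaction undefined")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return interaction_log_odds_from_pairs(
        pairs, types == type_a, types == type_b,
        n_permutations=config.n_permutations, rng=rng, type_pair=(type_a, type_b),
    )


def interaction_matrix(
    cell_map: pd.DataFrame, types: Sequence[str], config: SpatialConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-odds and p-value matrices over all ordered pairs of the given types.

    The in-band pair set is computed once and shared across type pairs.
    """
    config = config or SpatialConfig()
    config.validate()
    _check_map(cell_map)
    pairs, _ = pairs_within_band(cell_map, config.band_min, config.band_max)
    labels = cell_map["type"].to_numpy()
    rng = np.random.default_rng(config.seed)
    lor = pd.DataFrame(np.nan, index=list(types), columns=list(types))
    pval = pd.DataFrame(np.nan, index=list(types), columns=list(types))
    for ta in types:
        for tb in types:
            res = interaction_log_odds_from_pairs(
                pairs, labels == ta, labels == tb,
                n_permutations=config.n_permutations, rng=rng, type_pair=(ta, tb),
            )
            lor.loc[ta, tb] = res.log_odds
            pval.loc[ta, tb] = res.p_value if res.p_value is not None else np.nan
    return lor, pval


# ---------------------------------------------------------------------------
# Distances, density, census, contact
# ---------------------------------------------------------------------------

def nn_distances(cell_map: pd.DataFrame, query_type: str, ref_type: str) -> pd.Series:
    """Distance from each query-type cell to its nearest ref-type cell.

    When query and reference types coincide, each cell is excluded from its
    own reference set.
    """
    _check_map(cell_map)
    refs = cell_map[cell_map["type"] == ref_type]
    if len(refs) == 0:
        raise ValueError(f"reference type {ref_type!r} absent")
    queries = cell_map[cell_map["type"] == query_type]
    if len(queries) == 0:
        return pd.Series(dtype=float, name="nn_distance")
    tree = cKDTree(_xy(refs))
    if query_type == ref_type:
        if len(refs) < 2:
            raise ValueError("need >= 2 cells for within-type distances")
        d, _ = tree.query(_xy(queries), k=2)
        dist = d[:, 1]
    else:
        dist, _ = tree.query(_xy(queries), k=1)
    return pd.Series(dist, index=queries["cell_id"].to_numpy(), name="nn_distance")


def compare_nn_distances(
    cell_map: pd.DataFrame,
    query_a: str,
    query_b: str,
    ref_type: str,
    test: str = "welch",
) -> tuple[float, float]:
    """Two-sided location test of nearest-ref distances between two query types
    (Welch's t by default; 'ranksum' for Mann-Whitney)."""
    da = nn_distances(cell_map, query_a, ref_type).to_numpy()
    db = nn_distances(cell_map, query_b, ref_type).to_numpy()
    if test == "welch":
        stat, p = ttest_ind(da, db, equal_var=False)
    elif test == "ranksum":
        stat, p = mannwhitneyu(da, db, alternative="two-sided")
    else:
        raise ValueError("test must be 'welch' or 'ranksum'")
    return float(stat), float(p)


@dataclass
class DensityResult:
    ratio: float
    near_density: float       # query cells per um^2 within radius of refs
    global_density: float
    union_area: float         # Monte-Carlo estimate of the disc-union area
    annuli: pd.DataFrame      # per 1-um annulus: count, area, density


def density_enrichment(
    cell_map: pd.DataFrame,
    ref_type: str,
    query_type: str,
    radius: float = 3.0,
    field_size: tuple[float, float] | None = None,
    seed: int = 0,
    n_mc: int = 200_000,
    max_annulus: int = 10,
) -> DensityResult:
    """Density of query cells within ``radius`` of any ref cell, relative to
    their global density.

    The area of the union of discs around reference cells (and of each 1-um
    annulus) is estimated by seeded Monte-Carlo over the field.
    """
    _check_map(cell_map)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    refs = cell_map[cell_map["type"] == ref_type]
    queries = cell_map[cell_map["type"] == query_type]
    if len(refs) == 0:
        raise ValueError(f"reference type {ref_type!r} absent")
    if len(queries) == 0:
        raise ValueError("zero query cells")

    if field_size is None:
        x0, y0 = cell_map["x_um"].min(), cell_map["y_um"].min()
        x1, y1 = cell_map["x_um"].max(), cell_map["y_um"].max()
    else:
        x0 = y0 = 0.0
        x1, y1 = field_size
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        raise ValueError("degenerate field")

    tree = cKDTree(_xy(refs))
    dq, _ = tree.query(_xy(queries), k=1)

    rng = np.random.default_rng(seed)
    mc = np.column_stack([rng.uniform(x0, x1, n_mc), rng.uniform(y0, y1, n_mc)])
    dmc, _ = tree.query(mc, k=1)

    union_area = area * float(np.mean(dmc <= radius))
    n_in = int(np.count_nonzero(dq <= radius))
    global_density = len(queries) / area
    near_density = n_in / union_area if union_area > 0 else np.nan
    ratio = near_density / global_density if union_area > 0 else np.nan

    rows = []
    for r in range(1, max_annulus + 1):
        cnt = int(np.count_nonzero((dq > r - 1) & (dq <= r)))
        a = area * float(np.mean((dmc > r - 1) & (dmc <= r)))
        rows.append({"annulus_um": r, "count": cnt, "area_um2": a,
                     "density": cnt / a if a > 0 else np.nan})
    return DensityResult(ratio, near_density, global_density, union_area, pd.DataFrame(rows))


@dataclass
class CensusResult:
    counts: pd.DataFrame      # centers x counted types
    anova_f: float
    anova_p: float
    undefined: bool = False


def radius_census(
    cell_map: pd.DataFrame,
    center_type: str,
    counted_types: Sequence[str],
    config: SpatialConfig | None = None,
) -> CensusResult:
    """Counts of each counted type strictly within ``census_radius`` of sampled
    centre cells, with a one-way ANOVA across counted types."""
    config = config or SpatialConfig()
    config.validate()
    _check_map(cell_map)
    centers = cell_map[cell_map["type"] == center_type]
    if len(centers) == 0:
        raise ValueError(f"center type {center_type!r} absent")
    if len(centers) < config.n_census_centers:
        raise ValueError(
            f"only {len(centers)} centers available, {config.n_census_centers} requested"
        )
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(centers), size=config.n_census_centers, replace=False)
    centers = centers.iloc[np.sort(pick)]

    xy_all = _xy(cell_map)
    types = cell_map["type"].to_numpy()
    pos_of = {idx: i for i, idx in enumerate(cell_map.index)}
    tree = cKDTree(xy_all)
    rows = []
    for ridx, c in centers.iterrows():
        cxy = np.array([c["x_um"], c["y_um"]])
        hits = np.array(tree.query_ball_point(cxy, config.census_radius), dtype=int)
        self_i = pos_of[ridx]
        if hits.size:
            d = np.linalg.norm(xy_all[hits] - cxy, axis=1)
            hits = hits[(d < config.census_radius) & (hits != self_i)]  # strictly within
        rows.append({t: int(np.count_nonzero(types[hits] == t)) for t in counted_types})
    counts_df = pd.DataFrame(rows, index=centers["cell_id"].to_numpy())

    cols = [counts_df[t].to_numpy(float) for t in counted_types]
    if all(np.ptp(col) == 0 for col in cols) and len({col[0] for col in cols}) <= 1:
        return CensusResult(counts_df, np.nan, np.nan, undefined=True)
    f, p = f_oneway(*cols)
    if not np.isfinite(f):
        return CensusResult(counts_df, np.nan, np.nan, undefined=True)
    return CensusResult(counts_df, float(f), float(p))


@dataclass
class ContactResult:
    fraction: float
    n_sampled: int
    distances: pd.Series      # sampled cell -> nearest-partner distance


def contact_fraction(
    cell_map: pd.DataFrame,
    cell_type: str,
    partner_type: str,
    config: SpatialConfig | None = None,
) -> ContactResult:
    """Fraction of sampled cells of ``cell_type`` whose nearest partner cell
    lies within ``contact_radius`` (centroid-distance contact criterion)."""
    config = config or SpatialConfig()
    config.validate()
    _check_map(cell_map)
    cells = cell_map[cell_map["type"] == cell_type]
    partners = cell_map[cell_map["type"] == partner_type]
    if len(cells) == 0:
        raise ValueError(f"type {cell_type!r} absent")
    if len(partners) == 0:
        raise ValueError(f"partner type {partner_type!r} absent")
    rng = np.random.default_rng(config.seed)
    n = min(config.n_contact_sample, len(cells))
    pick = rng.choice(len(cells), size=n, replace=False)
    sampled = cells.iloc[np.sort(pick)]
    tree = cKDTree(_xy(partners))
    d, _ = tree.query(_xy(sampled), k=1)
    dist = pd.Series(d, index=sampled["cell_id"].to_numpy(), name="nearest_partner_um")
    return ContactResult(float(np.mean(d <= config.contact_radius)), n, dist)


# ---------------------------------------------------------------------------
# Raster neighbourhoods
# ---------------------------------------------------------------------------

@dataclass
class RasterResult:
    centers: pd.DataFrame       # window_id, x_um, y_um, total
    counts: pd.DataFrame        # windows x types (restricted subset if given)
    composition: pd.DataFrame   # counts row-normalised to sum 1


def raster_neighborhoods(
    cell_map: pd.DataFrame,
    config: SpatialConfig | None = None,
    types_subset: Sequence[str] | None = None,
) -> RasterResult:
    """Raster-scan circular windows over the map and profile their composition.

    Windows are centred on a square grid with spacing ``raster_step``
    covering the bounding box; each window counts cells within
    ``census_radius``.  Windows with fewer than ``min_window_cells`` counted
    cells are dropped.  If ``types_subset`` is given, counts and composition
    are restricted to those types (e.g. only the macrophage populations).
    """
    config = config or SpatialConfig()
    config.validate()
    _check_map(cell_map)
    types = sorted(types_subset) if types_subset else sorted(cell_map["type"].unique())
    sub = cell_map[cell_map["type"].isin(types)]
    if len(sub) == 0:
        raise ValueError("no cells of the requested types")

    x0, x1 = cell_map["x_um"].min(), cell_map["x_um"].max()
    y0, y1 = cell_map["y_um"].min(), cell_map["y_um"].max()
    gx = np.arange(x0, x1 + config.raster_step, config.raster_step)
    gy = np.arange(y0, y1 + config.raster_step, config.raster_step)
    centers = np.array([(x, y) for y in gy for x in gx])

    tree = cKDTree(_xy(sub))
    tcodes = pd.Categorical(sub["type"], categories=types).codes
    rows, keep_centers = [], []
    for cx, cy in centers:
        hits = tree.query_ball_point([cx, cy], config.census_radius)
        if len(hits) < config.min_window_cells:
            continue
        cnt = np.bincount(tcodes[hits], minlength=len(types))
        rows.append(cnt)
        keep_centers.append((cx, cy))
    if not rows:
        raise ValueError("no window reached min_window_cells; decrease the threshold or step")

    counts = pd.DataFrame(rows, columns=types)
    counts.index = [f"w{i:04d}" for i in range(len(counts))]
    centers_df = pd.DataFrame(keep_centers, columns=["x_um", "y_um"], index=counts.index)
    centers_df["total"] = counts.sum(axis=1)
    comp = counts.div(counts.sum(axis=1), axis=0)
    return RasterResult(centers_df, counts, comp)


def neighborhood_cluster(
    raster: RasterResult,
    K: int,
    grid: tuple[int, int] = (4, 4),
    epochs: int = 20,
    resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster window composition vectors into K neighbourhoods via
    SOM + consensus metaclustering; returns (window labels, mean composition
    per neighbourhood)."""
    from .cluster import consensus_metacluster, som_fit

    comp = raster.composition
    if len(comp) < K:
        raise ValueError("fewer windows than requested neighbourhoods")
    n_nodes = grid[0] * grid[1]
    if n_nodes > len(comp):
        side = max(1, int(np.sqrt(len(comp))))
        grid = (side, side)
    model, assign = som_fit(comp, grid=grid, epochs=epochs, seed=seed)
    node_labels = consensus_metacluster(
        model, K=min(K, model.codebook.shape[0]),
        resamples=resamples, subsample_frac=subsample_frac, seed=seed,
    )
    win_labels = pd.Series(
        [str(node_labels[i]) for i in assign.to_numpy()], index=comp.index, name="neighborhood"
    )
    mean_comp = comp.groupby(win_labels).mean()
    return win_labels, mean_comp


# ---------------------------------------------------------------------------
# Colocalization and gating
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    pearson: float
    defined: bool
    n_pixels: int


def coloc_pearson(
    img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray | None = None
) -> ColocResult:
    """Pearson correlation of two intensity images over (masked) pixels."""
    a = np.asarray(img_a, float)
    b = np.asarray(img_b, float)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs")
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant channel: colocalization undefined")
        return ColocResult(np.nan, False, a.size)
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocResult(r, True, a.size)


@dataclass
class GateResult:
    fraction: float
    n_gated: int
    n_positive: int


def gate_fraction(
    table: pd.DataFrame,
    first_gate: tuple[str, float, str],
    second_gate: tuple[str, float, str],
) -> GateResult:
    """Two-step gating: fraction of cells passing the second gate among those
    passing the first.  Each gate is (marker, threshold, '>' or '<')."""

    def _pass(gate: tuple[str, float, str]) -> pd.Series:
        marker, thr, sign = gate
        if marker not in table.columns:
            raise ValueError(f"marker {marker!r} absent")
        if sign == ">":
            return table[marker] > thr
        if sign == "<":
            return table[marker] < thr
        raise ValueError("gate sign must be '>' or '<'")

    gated = table[_pass(first_gate)]
    if len(gated) == 0:
        raise ValueError("first gate selected no cells")
    pos = int(_pass(second_gate).loc[gated.index].sum())
    return GateResult(pos / len(gated), len(gated), pos)
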