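"""Spatial standardisation of occurrence data.

Occurrences are binned on a geodesic hexagonal grid (the Voronoi cells of a
subdivided icosahedron, so cell areas are free of latitudinal distortion), the
spatial extent of a stage/region sample is measured as the summed great-circle
length of the minimum spanning tree (MST) over occupied cell centres, and
samples are standardised by pruning MST tips until the extent best matches a
target.  Coverage-based (shareholder quorum) richness and extent-diversity
correlations check that residual spatial extent no longer drives diversity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.special import gammaln
from scipy import stats

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


def _unit_vectors(lon_deg, lat_deg):
    lon = np.radians(np.asarray(lon_deg, float))
    lat = np.radians(np.asarray(lat_deg, float))
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def great_circle_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between points given in degrees."""
    v1 = _unit_vectors(lon1, lat1)
    v2 = _unit_vectors(lon2, lat2)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    return radius_km * np.arctan2(cross, dot)


# ---------------------------------------------------------------------------
# geodesic grid
# ---------------------------------------------------------------------------

@dataclass
class GeodesicGrid:
    """Voronoi tessellation of the sphere around the 10f^2 + 2 vertices of an
    icosahedron subdivided at frequency ``f`` (12 pentagonal + hexagonal cells)."""

    subdivision_frequency: int
    centroids: pd.DataFrame  # cell_id, lon, lat
    _vectors: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


def build_grid(subdivision_frequency: int) -> GeodesicGrid:
    """Build the geodesic grid at a given icosahedral subdivision frequency."""
    f = int(subdivision_frequency)
    if f < 1:
        raise ValueError("subdivision_frequency must be >= 1")
    phi = (1 + math.sqrt(5)) / 2
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    points = {}
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * va + j * vb + k * vc) / f
                p /= np.linalg.norm(p)
                points[tuple(np.round(p, 9))] = p
    vecs = np.array(list(points.values()))
    expected = 10 * f * f + 2
    if len(vecs) != expected:  # pragma: no cover - construction sanity
        raise RuntimeError(f"grid construction produced {len(vecs)} != {expected} cells")
    lon = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0]))
    lat = np.degrees(np.arcsin(np.clip(vecs[:, 2], -1, 1)))
    order = np.lexsort((lon, lat))
    vecs = vecs[order]
    centroids = pd.DataFrame(
        {"cell_id": np.arange(len(vecs)), "lon": lon[order], "lat": lat[order]}
    )
    return GeodesicGrid(f, centroids, vecs)


@dataclass
class CellOccupancy:
    """Occurrence counts per occupied grid cell (optionally labelled)."""

    counts: pd.Series  # index cell_id, values > 0
    stage: str = ""
    region: str = ""

    @property
    def cell_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()


def assign_cells(lon, lat, grid: GeodesicGrid, stage: str = "", region: str = "") -> CellOccupancy:
    """Assign points to their nearest grid-cell centroid (great-circle metric).

    Ties are broken deterministically toward the smallest cell id.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if lon.size == 0:
        return CellOccupancy(pd.Series(dtype=int), stage, region)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinates out of range")
    v = _unit_vectors(lon, lat)
    # nearest centroid maximises the dot product; argmax returns first (lowest id) on ties
    nearest = np.argmax(v @ grid._vectors.T, axis=1)
    counts = pd.Series(nearest).value_counts().sort_index()
    counts.index.name = "cell_id"
    return CellOccupancy(counts, stage, region)


# ---------------------------------------------------------------------------
# minimum spanning tree extent
# ---------------------------------------------------------------------------

@dataclass
class SpanningTree:
    """MST over occupied cell centroids with great-circle edge lengths (km)."""

    edges: list  # (cell_id_a, cell_id_b, length_km)
    total_length_km: float


def _pairwise_km(vectors: np.ndarray, radius_km: float) -> np.ndarray:
    dot = np.clip(vectors @ vectors.T, -1.0, 1.0)
    cross = np.linalg.norm(
        np.cross(vectors[:, None, :], vectors[None, :, :]), axis=-1
    )
    return radius_km * np.arctan2(cross, dot)


def mst_length(
    occupancy: CellOccupancy, grid: GeodesicGrid, earth_radius_km: float = EARTH_RADIUS_KM
) -> SpanningTree:
    """Minimum spanning tree over occupied cell centres; a single cell has length 0."""
    ids = occupancy.cell_ids
    if len(ids) == 0:
        raise ValueError("empty occupancy")
    if len(ids) == 1:
        return SpanningTree([], 0.0)
    vecs = grid._vectors[ids]
    dist = _pairwise_km(vecs, earth_radius_km)
    tree = minimum_spanning_tree(dist).tocoo()
    edges = [
        (int(ids[i]), int(ids[j]), float(w))
        for i, j, w in zip(tree.row, tree.col, tree.data)
    ]
    return SpanningTree(edges, float(tree.data.sum()))


def prune_to_target(
    occupancy: CellOccupancy,
    grid: GeodesicGrid,
    target_km: float,
    earth_radius_km: float = EARTH_RADIUS_KM,
):
    """Prune MST tip cells until the extent best matches ``target_km``.

    At each step the degree-1 (tip) cell with the fewest occurrences is removed
    (ties broken toward the smallest cell id) and the MST recomputed.  Because
    the MST length is non-increasing along the removal path, the absolute gap
    ``|length - target|`` falls and then rises; the returned state is the first
    along the path at the minimal gap (so pruning stops before any removal
    that would widen the gap).

    Returns ``(pruned CellOccupancy, SpanningTree)``.
    """
    if target_km < 0:
        raise ValueError("target_km must be >= 0")
    counts = occupancy.counts.copy()
    if len(counts) == 0:
        raise ValueError("empty occupancy")
    best_counts, best_tree, best_gap = None, None, np.inf
    while True:
        occ = CellOccupancy(counts, occupancy.stage, occupancy.region)
        tree = mst_length(occ, grid, earth_radius_km)
        gap = abs(tree.total_length_km - target_km)
        if gap < best_gap - 1e-12:
            best_counts, best_tree, best_gap = counts.copy(), tree, gap
        if len(counts) == 1:
            break
        if tree.total_length_km < target_km and gap > best_gap:
            break  # below target: further removals only widen the gap
        degree = pd.Series(0, index=counts.index)
        for a, b, _ in tree.edges:
            degree[a] += 1
            degree[b] += 1
        tips = degree.index[degree <= 1]
        tip_order = sorted(tips, key=lambda c: (counts[c], c))
        counts = counts.drop(tip_order[0])
    return CellOccupancy(best_counts, occupancy.stage, occupancy.region), best_tree


# ---------------------------------------------------------------------------
# sliding spatial windows
# ---------------------------------------------------------------------------

@dataclass
class WindowTrack:
    """A fixed-size lon/lat window drifting at a constant bearing between stages."""

    window: tuple  # (dlon, dlat) degrees
    anchor: tuple  # first-stage window centre (lon, lat)
    bearing_deg: float
    step_deg: float
    retained: dict  # stage -> retained occurrence count
    total_retained: int


def _wrap_lon(d):
    return (np.asarray(d) + 180.0) % 360.0 - 180.0


def slide_windows(
    table: pd.DataFrame,
    window: tuple,
    bearing_candidates=tuple(range(0, 360, 15)),
    step_candidates=tuple(np.arange(0.0, 4.01, 0.5)),
    anchor_offsets=(-0.5, -0.25, 0.0, 0.25, 0.5),
):
    """Choose the drifting window track retaining the most occurrences.

    Stages are ordered oldest to youngest; the first-stage window is anchored
    at the occurrence centroid of the oldest stage (plus a small offset grid,
    as fractions of the window size), and subsequent stages drift ``step_deg``
    degrees per stage along a constant bearing (degrees clockwise from north).
    The track maximising total retained occurrences wins; ties go to the
    smallest total displacement.  Returns ``(WindowTrack, stage -> row mask)``.
    """
    dlon, dlat = window
    if dlon <= 0 or dlat <= 0:
        raise ValueError("window dimensions must be positive")
    mid = 0.5 * (table["max_ma"] + table["min_ma"])
    stage_age = mid.groupby(table["stage"]).mean().sort_values(ascending=False)
    stages = list(stage_age.index)
    if not stages:
        raise ValueError("no stages with occurrences")
    first = table.loc[table["stage"] == stages[0]]
    lon0, lat0 = float(first["plon"].mean()), float(first["plat"].mean())

    lons = {s: table.loc[table["stage"] == s, "plon"].to_numpy() for s in stages}
    lats = {s: table.loc[table["stage"] == s, "plat"].to_numpy() for s in stages}

    best = None
    for off_lon in anchor_offsets:
        for off_lat in anchor_offsets:
            a_lon = lon0 + off_lon * dlon
            a_lat = lat0 + off_lat * dlat
            for step in step_candidates:
                bearings = bearing_candidates if step > 0 else (0.0,)
                for bearing in bearings:
                    blon = step * math.sin(math.radians(bearing))
                    blat = step * math.cos(math.radians(bearing))
                    total = 0
                    per_stage = []
                    for i, s in enumerate(stages):
                        clon, clat = a_lon + i * blon, a_lat + i * blat
                        ok = (np.abs(_wrap_lon(lons[s] - clon)) <= dlon / 2) & (
                            np.abs(lats[s] - clat) <= dlat / 2
                        )
                        per_stage.append(int(ok.sum()))
                        total += int(ok.sum())
                    displacement = step * (len(stages) - 1)
                    key = (-total, displacement, bearing, abs(off_lon), abs(off_lat))
                    if best is None or key < best[0]:
                        best = (key, a_lon, a_lat, bearing, step, per_stage)
    _, a_lon, a_lat, bearing, step, per_stage = best
    masks = {}
    for i, s in enumerate(stages):
        clon = a_lon + i * step * math.sin(math.radians(bearing))
        clat = a_lat + i * step * math.cos(math.radians(bearing))
        in_win = (
            (np.abs(_wrap_lon(table["plon"].to_numpy() - clon)) <= dlon / 2)
            & (np.abs(table["plat"].to_numpy() - clat) <= dlat / 2)
            & (table["stage"] == s).to_numpy()
        )
        masks[s] = in_win
    track = WindowTrack(
        window=(dlon, dlat),
        anchor=(a_lon, a_lat),
        bearing_deg=float(bearing),
        step_deg=float(step),
        retained=dict(zip(stages, per_stage)),
        total_retained=sum(per_stage),
    )
    if track.total_retained == 0:
        logger.warning("no occurrences retained by any window placement")
    return track, masks


# ---------------------------------------------------------------------------
# coverage-based (shareholder quorum) diversity
# ---------------------------------------------------------------------------

@dataclass
class SQSResult:
    richness: float
    quorum: float
    extrapolated: bool
    coverage_full: float  # estimated coverage of the full sample (Chao-Jost)


def _log_ratio(n: int, x: np.ndarray, m: float) -> np.ndarray:
    """log of C(n - x, m) / C(n, m) for integer m (0 where n - x < m)."""
    out = np.full(len(x), -np.inf)
    ok = (n - x) >= m
    nx = n - x[ok]
    out[ok] = (
        gammaln(nx + 1) - gammaln(nx - m + 1) - (gammaln(n + 1) - gammaln(n - m + 1))
    )
    return out


def _rarefaction_point(n: int, x: np.ndarray, m: int):
    """Expected richness and within-sample coverage of a size-m subsample.

    Expectations are over all C(n, m) equally likely subsamples drawn without
    replacement from the observed sample; coverage of a subsample is the share
    of the full sample's individuals whose taxa it contains.
    """
    ratio = np.exp(_log_ratio(n, x, m))
    richness = float(np.sum(1.0 - ratio))
    coverage = float(np.sum((x / n) * (1.0 - ratio)))
    return richness, coverage


def sqs_diversity(abundances, quorum: float = 0.5) -> SQSResult:
    """Coverage-standardised richness at a sampling quorum.

    The full sample's coverage is estimated with the Chao-Jost singleton/
    doubleton correction; the within-sample rarefaction coverage curve is
    rescaled to end at that estimate.  When the quorum lies below the full
    coverage, richness is linearly interpolated on the coverage curve between
    adjacent subsample sizes (never below one individual); when it lies above,
    Chao-style extrapolation is used and the result flagged.
    """
    x = np.asarray([a for a in abundances if a > 0], dtype=float)
    if x.size == 0:
        raise ValueError("empty abundance vector")
    if not (0 < quorum <= 1):
        raise ValueError("quorum must be in (0, 1]")
    if np.any(x != np.round(x)):
        raise ValueError("abundances must be positive integers")
    n = int(x.sum())
    s_obs = len(x)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0 or n <= 1:
        c_full = 1.0
    else:
        if f2 > 0:
            a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
        else:
            a = (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2)
        c_full = 1.0 - (f1 / n) * a

    if quorum > c_full:
        # Chao1-style extrapolation beyond the observed sample
        f0 = f1 * f1 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2.0
        if f0 <= 0 or f1 == 0:
            return SQSResult(float(s_obs), quorum, True, c_full)
        b = 1.0 - f1 / (n * f0 + f1)
        m_star = math.log(n * (1.0 - quorum) / f1) / math.log(b) - 1.0
        m_star = max(m_star, 0.0)
        richness = s_obs + f0 * (1.0 - b**m_star)
        return SQSResult(float(richness), quorum, True, c_full)

    # interpolation: within-sample coverage rescaled so coverage(n) = c_full
    s1, c1 = _rarefaction_point(n, x, 1)
    if quorum <= c_full * c1:
        return SQSResult(s1, quorum, False, c_full)
    lo, hi = 1, n
    s_lo, c_lo = s1, c_full * c1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        s_mid, c_mid = _rarefaction_point(n, x, mid)
        if c_full * c_mid < quorum:
            lo, s_lo, c_lo = mid, s_mid, c_full * c_mid
        else:
            hi = mid
    s_hi, c_hi = _rarefaction_point(n, x, hi)
    c_hi *= c_full
    if c_hi <= c_lo:
        return SQSResult(s_hi, quorum, False, c_full)
    w = (quorum - c_lo) / (c_hi - c_lo)
    return SQSResult(s_lo + w * (s_hi - s_lo), quorum, False, c_full)


# ---------------------------------------------------------------------------
# extent-diversity correlations
# ---------------------------------------------------------------------------

def extent_correlations(diversity, extents: dict, exact_max_n: int = 8) -> pd.DataFrame:
    """One-tailed extent-diversity correlations per extent metric.

    Tests H1: larger spatial extent -> larger diversity (positive direction).
    Pearson p-values use the t approximation; Spearman p-values are exact
    permutation fractions for n <= ``exact_max_n`` and asymptotic otherwise.
    """
    y = np.asarray(diversity, float)
    if len(y) < 3:
        raise ValueError("need at least 3 paired stages")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance diversity: correlation undefined")
    rows = []
    for name, vals in extents.items():
        xv = np.asarray(vals, float)
        if len(xv) != len(y):
            raise ValueError(f"extent metric {name!r} length mismatch")
        if np.ptp(xv) == 0:
            raise ValueError(f"zero-variance extent metric {name!r}")
        r, p_r = stats.pearsonr(xv, y, alternative="greater")
        rho = stats.spearmanr(xv, y).statistic
        n = len(y)
        if n <= exact_max_n:
            ranks_y = stats.rankdata(y)
            ranks_x = stats.rankdata(xv)
            count = total = 0
            for perm in itertools.permutations(ranks_y):
                rp = np.corrcoef(ranks_x, perm)[0, 1]
                count += rp >= rho - 1e-12
                total += 1
            p_rho = count / total
        else:
            p_rho = stats.spearmanr(xv, y, alternative="greater").pvalue
        rows.append((name, float(r), float(p_r), float(rho), float(p_rho)))
    return pd.DataFrame(
        rows, columns=["metric", "pearson_r", "pearson_p", "spearman_rho", "spearman_p"]
    )
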