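"""Seasonal utilization distributions, Bhattacharyya overlap, and
longline-effort aggregation.

Per colony x season, bycatch locations become a utilization distribution
(UD): a Gaussian kernel density evaluated on a shared lat/lon grid with a
cos(latitude) equal-area weight, normalized to unit mass.  Core-use areas
are the 50% highest-density isopleths; similarity between two colonies is
Bhattacharyya's Affinity BA = sum sqrt(f1 f2) over cells with each UD
truncated (not renormalized) outside its own 50% isopleth, so BA runs from
0 (disjoint cores) to 0.5 (identical UDs).  Longline effort is summed onto
a 0.5-degree grid per season; the per-month effort ratio compares seasons
of unequal length.

Longitudes are handled on an unwrapped axis so grids spanning the
antimeridian (the Bering Sea case) stay contiguous.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import EffortRecord, ObserverRecord, PipelineConfig

logger = logging.getLogger("fulmargsi")


def unwrap_longitudes(lons: np.ndarray) -> np.ndarray:
    """Map longitudes onto a contiguous axis across the antimeridian.

    If the point set straddles +/-180 (gap through 180 smaller than through
    0), western negatives are shifted by +360 so 179.9 and -179.9 become
    neighbours at 179.9 and 180.1.
    """
    lons = np.asarray(lons, dtype=float)
    if lons.size == 0:
        return lons
    span_plain = lons.max() - lons.min()
    shifted = np.where(lons < 0, lons + 360.0, lons)
    if shifted.size and shifted.max() - shifted.min() < span_plain:
        return shifted
    return lons


# ---------------------------------------------------------------------------
# utilization distributions
# ---------------------------------------------------------------------------

@dataclass
class UDGrid:
    """Gridded probability mass for one colony x season stratum."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray          # on the unwrapped axis
    density: np.ndarray            # (n_lat, n_lon), sums to 1
    colony: str = ""
    season: str = ""

    def isopleth(self, q: float) -> np.ndarray:
        return isopleth(self, q)


def _href_bandwidth(x: np.ndarray, y: np.ndarray) -> tuple:
    """Ad-hoc normal reference bandwidth per marginal: sigma * n^(-1/6)."""
    n = len(x)
    return (np.std(x, ddof=1) * n ** (-1 / 6),
            np.std(y, ddof=1) * n ** (-1 / 6))


def make_grid(lats: np.ndarray, lons_unwrapped: np.ndarray,
              cell_size: float, pad: float = 2.0) -> tuple:
    """Common cell edges covering the data, aligned to the cell lattice."""
    lat0 = np.floor((lats.min() - pad) / cell_size) * cell_size
    lat1 = np.ceil((lats.max() + pad) / cell_size) * cell_size
    lon0 = np.floor((lons_unwrapped.min() - pad) / cell_size) * cell_size
    lon1 = np.ceil((lons_unwrapped.max() + pad) / cell_size) * cell_size
    return (np.arange(lat0, lat1 + cell_size / 2, cell_size),
            np.arange(lon0, lon1 + cell_size / 2, cell_size))


def estimate_ud(points: Sequence[ObserverRecord], lat_edges: np.ndarray,
                lon_edges: np.ndarray, bandwidth_method: str = "href",
                colony: str = "", season: str = "",
                delta_fallback: bool = False) -> UDGrid:
    """Gaussian-kernel UD on a fixed grid.

    Needs >= 5 points.  Degenerate variance (all points coincident) is an
    error unless ``delta_fallback`` puts all mass in the containing cell.
    Cell mass is the kernel density at the cell centre weighted by
    cos(latitude) (local equal-area correction), renormalized to sum 1.
    """
    if len(points) < 5:
        raise ValueError(
            f"stratum {colony}/{season}: need >= 5 points, got {len(points)}")
    lats = np.array([p.latitude for p in points])
    lons = np.array([p.longitude for p in points])
    # place points on the grid's (possibly unwrapped) longitude axis
    grid_center = (lon_edges[0] + lon_edges[-1]) / 2
    lons = lons + 360.0 * np.round((grid_center - lons) / 360.0)
    lat_c = (lat_edges[:-1] + lat_edges[1:]) / 2
    lon_c = (lon_edges[:-1] + lon_edges[1:]) / 2

    if np.std(lats) == 0 and np.std(lons) == 0:
        if not delta_fallback:
            raise ValueError(f"stratum {colony}/{season}: degenerate variance")
        density = np.zeros((len(lat_c), len(lon_c)))
        i = np.clip(np.searchsorted(lat_edges, lats[0], side="right") - 1,
                    0, len(lat_c) - 1)
        j = np.clip(np.searchsorted(lon_edges, lons[0], side="right") - 1,
                    0, len(lon_c) - 1)
        density[i, j] = 1.0
        return UDGrid(lat_edges, lon_edges, density, colony, season)

    if bandwidth_method == "href":
        h_lat, h_lon = _href_bandwidth(lats, lons)
    elif bandwidth_method == "scott":
        n = len(lats)
        h_lat = np.std(lats, ddof=1) * n ** (-1 / 6)
        h_lon = np.std(lons, ddof=1) * n ** (-1 / 6)
    else:
        raise ValueError(f"unknown bandwidth method {bandwidth_method!r}")
    h_lat = max(h_lat, 1e-6)
    h_lon = max(h_lon, 1e-6)

    dlat = (lat_c[:, None] - lats[None, :]) / h_lat     # (n_lat, n_pts)
    dlon = (lon_c[:, None] - lons[None, :]) / h_lon     # (n_lon, n_pts)
    k_lat = np.exp(-0.5 * dlat ** 2)
    k_lon = np.exp(-0.5 * dlon ** 2)
    density = k_lat @ k_lon.T                           # (n_lat, n_lon)
    density *= np.cos(np.radians(lat_c))[:, None]       # equal-area weight
    total = density.sum()
    if total <= 0:
        raise ValueError(f"stratum {colony}/{season}: zero density on grid")
    return UDGrid(lat_edges, lon_edges, density / total, colony, season)


def _isopleth_order(ud: UDGrid, q: float) -> tuple:
    """Flat cell order (density descending, ties by cell index) and the
    index of the cell whose inclusion first reaches cumulative mass q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")  # deterministic tie-break
    csum = np.cumsum(flat[order])
    cut = int(np.searchsorted(csum, q - 1e-12))
    cut = min(cut, len(flat) - 1)
    return order, csum, cut


def isopleth(ud: UDGrid, q: float) -> np.ndarray:
    """Greedy highest-density region: the smallest cell set (by the greedy
    construction, ties broken by cell index) whose mass reaches q."""
    order, _, cut = _isopleth_order(ud, q)
    mask = np.zeros(ud.density.size, dtype=bool)
    mask[order[:cut + 1]] = True
    return mask.reshape(ud.density.shape)


def truncated_density(ud: UDGrid, q: float) -> np.ndarray:
    """Density truncated outside the q-isopleth, NOT renormalized.

    The crossing cell is included fractionally so the retained mass is
    exactly q; this realizes the continuous-isopleth limit on a finite grid
    and keeps the Bhattacharyya affinity of identical UDs at exactly q.
    """
    order, csum, cut = _isopleth_order(ud, q)
    flat = ud.density.ravel().copy()
    keep = np.zeros_like(flat)
    keep[order[:cut]] = flat[order[:cut]]
    before = csum[cut - 1] if cut > 0 else 0.0
    cross = flat[order[cut]]
    if cross > 0:
        keep[order[cut]] = min(q - before, cross)
    return keep.reshape(ud.density.shape)


def bhattacharyya_affinity(ud1: UDGrid, ud2: UDGrid, q: float = 0.5) -> float:
    """BA between two UDs, each truncated outside its own q-isopleth.

    BA = sum_cells sqrt(f1 f2) with each f truncated (not renormalized) to
    mass q; by Cauchy-Schwarz BA <= q, so the 50% UDs range from 0 (no
    overlap) to 0.5 (identical distributions).
    """
    if (ud1.density.shape != ud2.density.shape
            or not np.array_equal(ud1.lat_edges, ud2.lat_edges)
            or not np.array_equal(ud1.lon_edges, ud2.lon_edges)):
        raise ValueError("UD grids do not match")
    f1 = truncated_density(ud1, q)
    f2 = truncated_density(ud2, q)
    return float(np.sqrt(f1 * f2).sum())


def rank_overlaps(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Ascending by BA (least to most similar); ties by pair then season."""
    out = overlaps.sort_values(["BA", "colony_a", "colony_b", "season"],
                               kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# effort
# ---------------------------------------------------------------------------

def aggregate_effort(records: Sequence[EffortRecord], cell_size: float = 0.5,
                     breeding_months: frozenset | None = None) -> pd.DataFrame:
    """Sum hooks per (season, lat cell, lon cell).

    Cell index is floor(coordinate / cell_size) on the unwrapped longitude
    axis, so effort on either side of the antimeridian lands in adjacent
    cells.  Returns columns season, lat_cell, lon_cell, hooks (cell indices,
    multiply by cell_size for the cell's south-west corner).
    """
    from .io_formats import BREEDING_MONTHS, season_of_month
    breeding = BREEDING_MONTHS if breeding_months is None else breeding_months
    if not records:
        return pd.DataFrame(columns=["season", "lat_cell", "lon_cell", "hooks"])
    lats = np.array([r.latitude for r in records])
    lons = unwrap_longitudes(np.array([r.longitude for r in records]))
    seasons = [season_of_month(r.date.month if r.date else None, breeding)
               for r in records]
    df = pd.DataFrame({
        "season": seasons,
        "lat_cell": np.floor(lats / cell_size).astype(int),
        "lon_cell": np.floor(lons / cell_size).astype(int),
        "hooks": [r.hooks for r in records],
    })
    return (df.groupby(["season", "lat_cell", "lon_cell"], sort=True)["hooks"]
            .sum().reset_index())


def effort_ratio(hooks_a: float, months_a: int, hooks_b: float,
                 months_b: int) -> float:
    """Per-month effort ratio (hooks_a/months_a) / (hooks_b/months_b)."""
    if months_a <= 0 or months_b <= 0:
        raise ValueError("months must be positive")
    if hooks_b <= 0:
        raise ValueError("denominator season has zero hooks")
    return (hooks_a / months_a) / (hooks_b / months_b)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    overlaps: pd.DataFrame
    uds: dict
    effort_grid: pd.DataFrame
    effort_ratio_summary: dict


def overlap_report(assignments: pd.DataFrame,
                   observers: Sequence[ObserverRecord],
                   effort: Sequence[EffortRecord],
                   config: PipelineConfig | None = None,
                   min_points: int = 5) -> OverlapReport:
    """UDs, pairwise BA table and effort summary for assigned bycatch.

    Only threshold-passing birds with known season contribute to UDs;
    strata with fewer than ``min_points`` birds are skipped with a log line.
    """
    config = config or PipelineConfig()
    ok = assignments[assignments["assigned"].astype(bool)]
    by_sample = {r.sample_id: r for r in observers}
    rows = []
    for row in ok.itertuples():
        rec = by_sample.get(row.sample_id)
        if rec is None or rec.season == "unknown":
            continue
        rows.append((row.map_colony, rec))
    if not rows:
        raise ValueError("no assigned birds with usable season/location data")

    lats = np.array([r.latitude for _, r in rows])
    lons = unwrap_longitudes(np.array([r.longitude for _, r in rows]))
    lat_edges, lon_edges = make_grid(lats, lons, config.cell_size_deg)

    strata: dict = {}
    for (colony, season), recs in itertools.groupby(
            sorted(rows, key=lambda t: (t[0], t[1].season)),
            key=lambda t: (t[0], t[1].season)):
        pts = [r for _, r in recs]
        if len(pts) < min_points:
            logger.warning("overlap: stratum %s/%s has %d point(s), skipped",
                           colony, season, len(pts))
            continue
        strata[(colony, season)] = estimate_ud(
            pts, lat_edges, lon_edges,
            bandwidth_method=config.kde_bandwidth_method,
            colony=colony, season=season)

    colonies = sorted({c for c, _ in strata})
    out = []
    for season in ("breeding", "nonbreeding"):
        for ca, cb in itertools.combinations(colonies, 2):
            if (ca, season) in strata and (cb, season) in strata:
                ba = bhattacharyya_affinity(strata[(ca, season)],
                                            strata[(cb, season)],
                                            q=config.isopleth_level)
                out.append({"colony_a": ca, "colony_b": cb,
                            "season": season, "BA": ba})
    overlaps = rank_overlaps(pd.DataFrame(out))

    grid = aggregate_effort(effort, cell_size=config.effort_cell_size_deg,
                            breeding_months=config.breeding_months)
    totals = grid.groupby("season")["hooks"].sum()
    n_breeding = len(config.breeding_months)
    n_nonbreeding = len(config.nonbreeding_months)
    summary = {"hooks_breeding": float(totals.get("breeding", 0.0)),
               "hooks_nonbreeding": float(totals.get("nonbreeding", 0.0)),
               "months_breeding": n_breeding,
               "months_nonbreeding": n_nonbreeding}
    if totals.get("breeding", 0) > 0:
        summary["nonbreeding_to_breeding_per_month_ratio"] = effort_ratio(
            summary["hooks_nonbreeding"], n_nonbreeding,
            summary["hooks_breeding"], n_breeding)
    return OverlapReport(overlaps=overlaps, uds=strata, effort_grid=grid,
                         effort_ratio_summary=summary)
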