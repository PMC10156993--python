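"""Geometry and spatial point-pattern statistics.

Great-circle distances use the haversine formula with the IUGG mean Earth
radius 6371.0088 km. Point-pattern analyses work on an equirectangular
projection of lon/lat (x scaled by cos of the mean latitude), which preserves
local distances at study-area scale. Ripley's K is the plain (uncorrected)
estimator; complete-spatial-randomness verdicts come from simulation
envelopes, so no analytic edge correction is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import chi2
from shapely.geometry import Point
from shapely.strtree import STRtree

from .core import PointPattern, Site, UnitPartition

__all__ = [
    "EARTH_RADIUS_KM",
    "geodesic_distance",
    "geodesic_matrix",
    "assign_units",
    "nearest_site_classify",
    "project_sites",
    "sites_to_pattern",
    "ripley_k",
    "csr_envelope",
    "CSREnvelope",
    "quadrat_chisq",
    "QuadratResult",
    "default_quadrat_grid",
]

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

Metric = Literal["planar", "geodesic"]


def _check_latlon(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"coordinate ({lat}, {lon}) outside valid lat/lon ranges")


def geodesic_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in km between (lat, lon) pairs."""
    _check_latlon(*a)
    _check_latlon(*b)
    lat1, lon1, lat2, lon2 = np.radians([a[0], a[1], b[0], b[1]])
    s = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def geodesic_matrix(lats: Sequence[float], lons: Sequence[float]) -> np.ndarray:
    """All-pairs haversine distance matrix (km), vectorised."""
    lat = np.radians(np.asarray(lats, dtype=float))[:, None]
    lon = np.radians(np.asarray(lons, dtype=float))[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    s = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    np.fill_diagonal(out, 0.0)
    return out


def assign_units(sites: Sequence[Site], partition: UnitPartition,
                 ) -> tuple[dict[str, str], list[str]]:
    """Map each site to the unit polygon containing it.

    Returns ``(assignments, unassigned)`` where ``assignments`` maps site_id
    to unit_id and ``unassigned`` lists site_ids outside every polygon
    (logged as a warning; excluded from the mapping). A site on a shared
    boundary goes to the lexicographically smallest touching unit_id.
    """
    ids = sorted(partition.units)
    geoms = [partition.units[u] for u in ids]
    tree = STRtree(geoms)
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for site in sites:
        pt = Point(site.lon, site.lat)
        hits = sorted(ids[i] for i in tree.query(pt, predicate="intersects"))
        if hits:
            assignments[site.site_id] = hits[0]
        else:
            unassigned.append(site.site_id)
    if unassigned:
        logger.warning("%d site(s) outside all unit polygons, excluded: %s",
                       len(unassigned), ", ".join(unassigned[:10]))
    return assignments, unassigned


def _coords(sites: Sequence[Site]) -> np.ndarray:
    return np.array([[s.lon, s.lat] for s in sites], dtype=float)


def nearest_site_classify(train: Sequence[Site], query: Site,
                          metric: Metric = "planar") -> str:
    """Clade of the training site nearest to ``query``.

    Equivalent to membership in the Voronoi tessellation seeded by the
    training sites. Ties go to the lexicographically smallest site_id.
    ``metric="planar"`` is Euclidean on raw (lon, lat), matching a Voronoi
    layer tessellated in geographic coordinates; ``"geodesic"`` uses
    great-circle distance.
    """
    return nearest_site_classify_many(train, [query], metric=metric)[0]


def nearest_site_classify_many(train: Sequence[Site], queries: Sequence[Site],
                               metric: Metric = "planar") -> list[str]:
    """Vectorised :func:`nearest_site_classify` over many query sites."""
    if not train:
        raise ValueError("training set must be non-empty")
    for s in train:
        if not s.clade:
            raise ValueError(f"training site {s.site_id!r} has no clade label")
    order = np.argsort([s.site_id for s in train], kind="stable")
    train = [train[i] for i in order]  # lowest site_id wins argmin ties
    if metric == "planar":
        d = cdist(_coords(queries), _coords(train))
    elif metric == "geodesic":
        qlat = np.radians([s.lat for s in queries])[:, None]
        qlon = np.radians([s.lon for s in queries])[:, None]
        tlat = np.radians([s.lat for s in train])[None, :]
        tlon = np.radians([s.lon for s in train])[None, :]
        h = (np.sin((tlat - qlat) / 2.0) ** 2
             + np.cos(qlat) * np.cos(tlat) * np.sin((tlon - qlon) / 2.0) ** 2)
        d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    nearest = np.argmin(d, axis=1)  # first (lowest site_id) minimum
    return [train[j].clade for j in nearest]


def project_sites(sites: Sequence[Site]) -> np.ndarray:
    """Equirectangular km projection: x = R·cos(lat̄)·lon, y = R·lat (radians)."""
    lats = np.array([s.lat for s in sites], dtype=float)
    lons = np.array([s.lon for s in sites], dtype=float)
    mean_lat = np.radians(lats.mean()) if len(lats) else 0.0
    x = EARTH_RADIUS_KM * np.cos(mean_lat) * np.radians(lons)
    y = EARTH_RADIUS_KM * np.radians(lats)
    return np.column_stack([x, y])


def sites_to_pattern(sites: Sequence[Site],
                     bbox: tuple[float, float, float, float] | None = None,
                     ) -> PointPattern:
    """Project sites to a planar point pattern.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max); when omitted, the
    window is the bounding rectangle of the projected points.
    """
    pts = project_sites(sites)
    if bbox is not None:
        lats = np.array([s.lat for s in sites], dtype=float)
        mean_lat = np.radians(lats.mean()) if len(lats) else 0.0
        kx = EARTH_RADIUS_KM * np.cos(mean_lat)
        ky = EARTH_RADIUS_KM
        window = (kx * np.radians(bbox[0]), ky * np.radians(bbox[1]),
                  kx * np.radians(bbox[2]), ky * np.radians(bbox[3]))
    else:
        window = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    return PointPattern(points=pts, window=window)


def ripley_k(pattern: PointPattern, radii: Sequence[float]) -> np.ndarray:
    """Ripley's K estimates K̂(r) = A/(n(n−1)) · #{ordered pairs with d ≤ r}.

    No edge correction is applied; under CSR, E[K̂(r)] ≈ πr² for r small
    relative to the window.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    n = pattern.n
    if n < 2:
        raise ValueError("Ripley's K requires at least two points")
    d = pdist(pattern.points)
    counts = np.searchsorted(np.sort(d), radii, side="right")  # unordered pairs
    return pattern.area / (n * (n - 1)) * 2.0 * counts


@dataclass
class CSREnvelope:
    """Simulation envelope of K̂ under complete spatial randomness."""

    radii: np.ndarray
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    inside: bool
    n_sim: int

    def theoretical(self) -> np.ndarray:
        """πr², the CSR expectation of Ripley's K."""
        return np.pi * self.radii ** 2


def csr_envelope(pattern: PointPattern, radii: Sequence[float], n_sim: int = 99,
                 seed: int | None = None) -> CSREnvelope:
    """Monte-Carlo min/max envelope of K̂ under CSR with matching n and window.

    ``inside`` is True when the observed K̂ stays within the envelope at
    every radius — the point pattern is then consistent with complete
    spatial randomness at the envelope's level (2/(n_sim+1) pointwise).
    """
    if n_sim < 19:
        raise ValueError("n_sim must be at least 19 for a meaningful envelope")
    radii = np.asarray(radii, dtype=float)
    observed = ripley_k(pattern, radii)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = pattern.window
    sims = np.empty((n_sim, len(radii)))
    for i in range(n_sim):
        pts = np.column_stack([rng.uniform(xmin, xmax, pattern.n),
                               rng.uniform(ymin, ymax, pattern.n)])
        sims[i] = ripley_k(PointPattern(pts, pattern.window), radii)
    lo, hi = sims.min(axis=0), sims.max(axis=0)
    inside = bool(np.all((observed >= lo) & (observed <= hi)))
    return CSREnvelope(radii=radii, observed=observed, lo=lo, hi=hi,
                       inside=inside, n_sim=n_sim)


@dataclass
class QuadratResult:
    """Chi-square quadrat test of spatial homogeneity."""

    statistic: float
    df: int
    p_value: float
    counts: np.ndarray
    expected: float


def default_quadrat_grid(n: int) -> tuple[int, int]:
    """Largest square grid keeping the expected count per cell at least 5."""
    g = max(2, int(np.floor(np.sqrt(n / 5.0))))
    return g, g


def quadrat_chisq(pattern: PointPattern, grid_rows: int | None = None,
                  grid_cols: int | None = None) -> QuadratResult:
    """Quadrat-count chi-square test against spatial homogeneity.

    The window is divided into ``grid_rows × grid_cols`` equal cells;
    X² = Σ (O − E)²/E with E = n/cells and df = cells − 1. Defaults to the
    largest square grid with E ≥ 5.
    """
    if pattern.n < 1:
        raise ValueError("quadrat test requires at least one point")
    if grid_rows is None or grid_cols is None:
        grid_rows, grid_cols = default_quadrat_grid(pattern.n)
    if grid_rows * grid_cols < 2:
        raise ValueError("quadrat grid must have at least two cells")
    xmin, ymin, xmax, ymax = pattern.window
    counts, _, _ = np.histogram2d(
        pattern.points[:, 0], pattern.points[:, 1],
        bins=[grid_cols, grid_rows], range=[[xmin, xmax], [ymin, ymax]])
    cells = grid_rows * grid_cols
    expected = pattern.n / cells
    if expected < 1:
        logger.warning("expected count per quadrat cell is %.2f < 1; "
                       "chi-square approximation is poor", expected)
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = cells - 1
    p = float(chi2.sf(stat, df))
    return QuadratResult(statistic=stat, df=df, p_value=p,
                         counts=counts.T[::-1], expected=expected)
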