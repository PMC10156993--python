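"""Core containers shared across the package.

Coordinates are decimal degrees (WGS84 assumed, no reprojection); elevations
are meters; phylogenetic distances are in the tree's branch-length units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Site",
    "UnitPartition",
    "DistanceMatrix",
    "PointPattern",
    "sites_to_frame",
    "frame_to_sites",
]

SITE_COLUMNS = ("site_id", "lat", "lon", "elevation", "watershed_id", "clade", "strain_id")


@dataclass(frozen=True)
class Site:
    """One georeferenced strain record.

    ``watershed_id``, ``clade`` and ``strain_id`` may be empty strings when
    unknown; ``elevation`` defaults to 0 m.
    """

    site_id: str
    lat: float
    lon: float
    elevation: float = 0.0
    watershed_id: str = ""
    clade: str = ""
    strain_id: str = ""

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"site {self.site_id!r}: latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"site {self.site_id!r}: longitude {self.lon} outside [-180, 180]")

    def with_unit(self, unit_id: str) -> "Site":
        return replace(self, watershed_id=unit_id)


def sites_to_frame(sites: Sequence[Site]) -> pd.DataFrame:
    """Tabulate sites as a DataFrame with the canonical column order."""
    return pd.DataFrame([{c: getattr(s, c) for c in SITE_COLUMNS} for s in sites],
                        columns=list(SITE_COLUMNS))


def frame_to_sites(frame: pd.DataFrame) -> list[Site]:
    """Inverse of :func:`sites_to_frame`; optional columns may be absent."""
    required = {"site_id", "lat", "lon"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"site table missing required columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(Site(
            site_id=str(row["site_id"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            elevation=float(row.get("elevation", 0.0) or 0.0),
            watershed_id=str(row.get("watershed_id", "") or ""),
            clade=str(row.get("clade", "") or ""),
            strain_id=str(row.get("strain_id", "") or ""),
        ))
    return out


@dataclass
class UnitPartition:
    """A named set of non-overlapping polygons defining spatial study units.

    ``kind`` records how the partition was built: ``"watershed"``, ``"grid"``
    or ``"voronoi"``. Unit geometries are shapely polygons in lon/lat degrees.
    """

    units: dict[str, BaseGeometry]
    kind: str = "watershed"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("partition must contain at least one unit")

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.units)

    def validate(self, tol: float = 1e-9) -> None:
        """Check pairwise interior-disjointness of the unit polygons."""
        ids = self.unit_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                inter = self.units[a].intersection(self.units[b])
                if inter.area > tol:
                    raise ValueError(f"units {a!r} and {b!r} overlap (area {inter.area:g})")

    def total_area(self) -> float:
        return float(sum(g.area for g in self.units.values()))

    def to_geojson(self) -> dict:
        feats = [{
            "type": "Feature",
            "properties": {"unit_id": uid, "kind": self.kind},
            "geometry": geom_mapping(self.units[uid]),
        } for uid in self.unit_ids]
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_geojson(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_geojson(cls, source, kind: str | None = None) -> "UnitPartition":
        """Read a FeatureCollection of (Multi)Polygons carrying ``unit_id``."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        elif isinstance(source, Mapping):
            obj = source
        else:
            with open(source, encoding="utf-8") as fh:
                obj = json.load(fh)
        units: dict[str, BaseGeometry] = {}
        inferred = kind
        for feat in obj["features"]:
            props = feat.get("properties") or {}
            uid = str(props.get("unit_id", f"U{len(units) + 1}"))
            if uid in units:
                raise ValueError(f"duplicate unit_id {uid!r} in GeoJSON")
            geom = geom_shape(feat["geometry"])
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise ValueError(f"unit {uid!r}: unsupported geometry {geom.geom_type}")
            units[uid] = geom
            inferred = inferred or props.get("kind")
        return cls(units=units, kind=inferred or "watershed")


class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns.

    Invariants enforced at construction: unique labels, symmetry within
    1e-12 (relative to scale), exactly-zero diagonal, non-negative entries.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = [str(x) for x in labels]
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} labels")
        scale = max(1.0, float(np.abs(values).max(initial=0.0)))
        if not np.allclose(values, values.T, rtol=0.0, atol=1e-12 * scale):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(values) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(values < 0.0):
            raise ValueError("distances must be non-negative")
        self.labels = list(labels)
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index.astype(str)) != [str(c) for c in frame.columns]:
            raise ValueError("distance matrix CSV must have identical row and column labels")
        return cls([str(c) for c in frame.columns], frame.to_numpy(dtype=float))


@dataclass
class PointPattern:
    """Planar point pattern observed in a rectangular window.

    ``window`` is (xmin, ymin, xmax, ymax) in the same (arbitrary planar)
    units as the points.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        xmin, ymin, xmax, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive width and height")
        x, y = self.points[:, 0], self.points[:, 1]
        if self.n and not ((x >= xmin).all() and (x <= xmax).all()
                           and (y >= ymin).all() and (y <= ymax).all()):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)
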