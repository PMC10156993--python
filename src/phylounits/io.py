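"""CSV/GeoJSON/Newick readers and writers with row-level validation.

CSV dialect: comma-separated, UTF-8, "." decimal, mandatory header.
Coordinates are decimal degrees (WGS84 assumed).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import Site, UnitPartition, sites_to_frame

__all__ = ["read_sites", "write_sites", "read_partition", "read_covariates"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site_id", "lat", "lon")
OPTIONAL_COLUMNS = ("elevation", "watershed_id", "clade", "strain_id")


def read_sites(path) -> list[Site]:
    """Read a site table CSV into validated :class:`Site` records.

    Errors name the offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    seen: dict[str, int] = {}
    sites: list[Site] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        sid = row["site_id"].strip()
        if not sid:
            raise ValueError(f"{path}: row {pos}: empty site_id")
        if sid in seen:
            raise ValueError(f"{path}: duplicate site_id {sid!r} in rows "
                             f"{seen[sid]} and {pos}")
        seen[sid] = pos
        try:
            lat, lon = float(row["lat"]), float(row["lon"])
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: unparsable coordinate "
                             f"(lat={row['lat']!r}, lon={row['lon']!r})") from exc
        elev_raw = row.get("elevation", "")
        try:
            elevation = float(elev_raw) if str(elev_raw).strip() else 0.0
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: unparsable elevation "
                             f"{elev_raw!r}") from exc
        try:
            sites.append(Site(
                site_id=sid, lat=lat, lon=lon, elevation=elevation,
                watershed_id=str(row.get("watershed_id", "")).strip(),
                clade=str(row.get("clade", "")).strip(),
                strain_id=str(row.get("strain_id", "")).strip(),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: {exc}") from exc
    logger.info("read %d sites from %s", len(sites), path)
    return sites


def write_sites(sites: Sequence[Site], path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)


def read_partition(path, kind: str | None = None) -> UnitPartition:
    """Read a GeoJSON FeatureCollection of unit polygons."""
    return UnitPartition.from_geojson(Path(path), kind=kind)


def read_covariates(path) -> pd.DataFrame:
    """Read a per-site covariate CSV indexed by site_id."""
    frame = pd.read_csv(path)
    if "site_id" not in frame.columns:
        raise ValueError(f"{path}: covariate table needs a site_id column")
    frame = frame.set_index("site_id")
    if frame.index.duplicated().any():
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate site_id(s) {dupes}")
    return frame
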