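"""Georeferenced sampling/release locations.

A :class:`SiteTable` holds the study's sampling sites: a short unique label,
a display name, WGS1984 decimal-degree coordinates, and optional depth and
distance-to-shore columns.  Outgroup sites (reference populations outside
the study region) are retained but excluded by default from pairwise
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: km per degree of latitude/longitude in the equirectangular working plane.
KM_PER_DEGREE = 111.19

_REQUIRED = ("site_id", "lat", "lon")


@dataclass(frozen=True)
class SiteTable:
    """Table of sampling/release sites.

    Parameters
    ----------
    frame
        DataFrame with at least ``site_id``, ``lat``, ``lon`` columns and
        optionally ``full_name``, ``depth_m``, ``dist_shore_km``,
        ``is_outgroup``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValueError(f"site table is missing required column {col!r}")
        if len(df) == 0:
            raise ValueError("no sites: site table is empty")
        dup = df["site_id"][df["site_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate site_id: {sorted(set(dup))}")
        lat, lon = df["lat"].to_numpy(float), df["lon"].to_numpy(float)
        bad_lat = df["site_id"][(lat < -90) | (lat > 90) | ~np.isfinite(lat)]
        bad_lon = df["site_id"][(lon < -180) | (lon > 180) | ~np.isfinite(lon)]
        if len(bad_lat) or len(bad_lon):
            raise ValueError(
                "coordinate out of range for site(s): "
                f"{sorted(set(bad_lat) | set(bad_lon))}"
            )
        if "is_outgroup" not in df.columns:
            object.__setattr__(
                self, "frame", df.assign(is_outgroup=False).reset_index(drop=True)
            )
        else:
            object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- basic accessors -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.frame["site_id"])

    @property
    def n_sites(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def ingroup(self) -> "SiteTable":
        """Sites not flagged as outgroups (the pairwise-analysis set)."""
        sub = self.frame[~self.frame["is_outgroup"].astype(bool)]
        if len(sub) < 2:
            raise ValueError("fewer than 2 non-outgroup sites")
        return SiteTable(sub.reset_index(drop=True))

    def subset(self, site_ids: Iterable[str]) -> "SiteTable":
        wanted = list(site_ids)
        missing = set(wanted) - set(self.site_ids)
        if missing:
            raise KeyError(f"unknown site_id(s): {sorted(missing)}")
        sub = self.frame.set_index("site_id").loc[wanted].reset_index()
        return SiteTable(sub)

    def coordinates(self) -> pd.DataFrame:
        return self.frame.set_index("site_id")[["lat", "lon"]]

    def positions_km(
        self, origin: tuple[float, float] | None = None
    ) -> pd.DataFrame:
        """Project lat/lon to the equirectangular km plane.

        ``x = KM_PER_DEGREE * (lon - lon0)``, ``y = KM_PER_DEGREE * (lat - lat0)``;
        the origin defaults to the south-west corner of the site cloud.
        """
        lat = self.frame["lat"].to_numpy(float)
        lon = self.frame["lon"].to_numpy(float)
        lat0, lon0 = origin if origin is not None else (lat.min(), lon.min())
        return pd.DataFrame(
            {
                "x_km": KM_PER_DEGREE * (lon - lon0),
                "y_km": KM_PER_DEGREE * (lat - lat0),
            },
            index=pd.Index(self.site_ids, name="site_id"),
        )


def read_site_table(path: str | Path) -> SiteTable:
    """Read a site table from CSV (columns: site_id, lat, lon, ...).

    Rows flagged ``is_outgroup`` are retained; callers exclude them from
    pairwise geometry via :meth:`SiteTable.ingroup`.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"no sites: {path} is empty") from exc
    if len(df) == 0:
        raise ValueError(f"no sites in {path}")
    for col in ("lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"site table {path} is missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"unparseable {col} in {path} at data row(s) {[int(i) + 2 for i in bad]}"
            )
        df[col] = coerced
    if "is_outgroup" in df.columns:
        df["is_outgroup"] = (
            df["is_outgroup"].astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
        )
    return SiteTable(df)


def north_sea_sites() -> SiteTable:
    """The 27 North Sea study sites (25 ingroup + 2 outgroup references).

    Coordinates are WGS1984 decimal degrees; the Limfjorden (LIMF,
    *M. edulis*) and Lisbon (LISB, *M. galloprovincialis*) reference
    populations are flagged as outgroups.
    """
    with resources.as_file(
        resources.files("stepstone.data").joinpath("north_sea_sites.csv")
    ) as p:
        return read_site_table(p)
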