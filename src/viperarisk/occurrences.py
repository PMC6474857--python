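"""Occurrence records: spatial thinning and pooling into clades.

Presence points carry a label (a species or sub-clade name) and lon/lat in
degrees.  Field records are spatially autocorrelated by survey design, so
before modelling they are thinned to at most one point per distance buffer;
sparse per-species samples are then pooled into phylogeographic clades, with
optional polygon-based exclusions (e.g. removing a sub-clade's outlying
mountain population from an otherwise lowland clade).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import ConfigurationError

EARTH_RADIUS_KM = 6371.0

_COLUMNS = ["id", "clade", "lon", "lat"]


@dataclass
class OccurrenceSet:
    """Labelled presence points.

    ``data`` is a DataFrame with columns id, clade, lon, lat; ids are unique
    and coordinates are valid degrees.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"occurrence table missing columns {missing}")
        self.data = self.data[_COLUMNS].reset_index(drop=True)
        if self.data["id"].duplicated().any():
            raise ConfigurationError("occurrence ids must be unique")
        lon, lat = self.data["lon"], self.data["lat"]
        if len(self.data) and not (
            lon.between(-180, 180).all() and lat.between(-90, 90).all()
        ):
            raise ConfigurationError("coordinates outside valid degree ranges")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float, float]],
                     provenance: str = "") -> "OccurrenceSet":
        return cls(pd.DataFrame(list(records), columns=_COLUMNS), provenance)

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path), provenance=str(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lonlat(self) -> np.ndarray:
        return self.data[["lon", "lat"]].to_numpy(dtype=float)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (vectorised)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def thin_occurrences(occs: OccurrenceSet, radius_km: float = 10.0,
                     seed: int = 0) -> OccurrenceSet:
    """Randomly sub-select points so no two are within ``radius_km``.

    Greedy first-come acceptance over a seeded random permutation: a point is
    retained iff it lies at least ``radius_km`` (great-circle) from every
    already-retained point.  The retained set is a subset of the input and is
    idempotent under re-thinning; no attempt is made to maximise its size.
    """
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be positive")
    n = len(occs)
    if n == 0:
        return OccurrenceSet(occs.data.copy(), occs.provenance)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pts = occs.lonlat
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        kept_pts = pts[kept]
        d = haversine_km(pts[i, 0], pts[i, 1], kept_pts[:, 0], kept_pts[:, 1])
        if np.all(d >= radius_km):
            kept.append(i)
    kept_sorted = sorted(kept)
    return OccurrenceSet(
        occs.data.iloc[kept_sorted].reset_index(drop=True),
        provenance=f"{occs.provenance} | thinned {radius_km} km",
    )


def pool_by_clade(
    occs: OccurrenceSet,
    clade_map: Mapping[str, str],
    exclusions: Sequence[tuple[str, Polygon]] = (),
) -> dict[str, OccurrenceSet]:
    """Pool labelled points into clades, minus per-clade exclusion polygons.

    ``clade_map`` sends each input label (the ``clade`` column, typically a
    species or sub-clade name) to a pooled clade label; every label must be
    mapped.  An exclusion ``(clade, polygon)`` removes from that clade any
    point on or inside the polygon (boundary counts as inside).
    """
    labels = occs.data["clade"].unique()
    unmapped = [l for l in labels if l not in clade_map]
    if unmapped:
        raise ConfigurationError(f"labels without a clade mapping: {sorted(unmapped)}")
    excl: dict[str, list] = {}
    for clade, poly in exclusions:
        excl.setdefault(clade, []).append(prep(poly))
    out: dict[str, OccurrenceSet] = {}
    pooled = occs.data.assign(_pool=occs.data["clade"].map(clade_map))
    for clade, group in pooled.groupby("_pool", sort=True):
        rows = group.drop(columns="_pool")
        if clade in excl:
            keep = [
                not any(p.intersects(Point(lon, lat)) for p in excl[clade])
                for lon, lat in rows[["lon", "lat"]].to_numpy()
            ]
            rows = rows.loc[keep]
        rows = rows.assign(clade=clade)
        out[str(clade)] = OccurrenceSet(
            rows.reset_index(drop=True),
            provenance=f"{occs.provenance} | pooled {clade}",
        )
    return out
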