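"""Occurrence cleaning, thinning, splitting, and the accessible area M.

Presence records are georeferenced museum-style observations with a
reported positional uncertainty. Before calibration they are filtered on
that uncertainty, optionally restricted to a known-range polygon, rarefied
to a minimum inter-record great-circle separation, and split 50/50 into
calibration and evaluation halves. The accessible area **M** — the region
assumed reachable by the species, and the source of background cells — is
the union of discs of a fixed angular radius (default 7 degrees of arc)
around the occurrences, intersected with the non-missing cells of the
environmental stack.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .rasters import GridSpec, RasterStack, arc_degrees, haversine_km

log = logging.getLogger(__name__)

OCC_COLUMNS = ["id", "longitude", "latitude", "uncertainty_m", "source"]


class OccurrenceSet:
    """Ordered set of georeferenced presence records (WGS84).

    Backed by a DataFrame with columns
    ``id, longitude, latitude, uncertainty_m, source``; ids are unique and
    coordinates are validated on construction.
    """

    crs = "EPSG:4326"

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in OCC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        df = df[OCC_COLUMNS].reset_index(drop=True).copy()
        if df["id"].duplicated().any():
            raise ValueError("occurrence ids must be unique")
        lon = df["longitude"].to_numpy(dtype=float)
        lat = df["latitude"].to_numpy(dtype=float)
        if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside WGS84 bounds")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lon(self) -> np.ndarray:
        return self.df["longitude"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["latitude"].to_numpy(dtype=float)

    def take(self, index) -> "OccurrenceSet":
        return OccurrenceSet(self.df.iloc[np.asarray(index, dtype=int)])

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def drop_duplicate_coordinates(self) -> "OccurrenceSet":
        """Remove records sharing exact (longitude, latitude); keeps the first."""
        keep = ~self.df.duplicated(subset=["longitude", "latitude"])
        removed = int((~keep).sum())
        if removed:
            log.info("removed %d exact coordinate duplicates", removed)
        return OccurrenceSet(self.df[keep])


@dataclass
class CalibrationArea:
    """Accessible-area mask M aligned to an environmental stack."""

    mask: np.ndarray  # boolean, (nrows, ncols)
    buffer_degrees: float
    grid: GridSpec
    clamp_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def filter_by_uncertainty(occ: OccurrenceSet, max_uncertainty_m: float = 10_000) -> OccurrenceSet:
    """Drop records whose reported uncertainty exceeds the cutoff (strict >)
    and records with no usable uncertainty at all."""
    unc = occ.df["uncertainty_m"]
    missing = unc.isna()
    over = unc > max_uncertainty_m
    keep = ~(missing | over)
    log.info(
        "uncertainty filter: %d retained, %d over %.0f m, %d missing uncertainty",
        int(keep.sum()), int(over.sum()), max_uncertainty_m, int(missing.sum()),
    )
    return OccurrenceSet(occ.df[keep])


def filter_by_range(occ: OccurrenceSet, range_polygon: BaseGeometry) -> OccurrenceSet:
    """Retain records inside or on the boundary of the known-range polygon."""
    if range_polygon is None or not range_polygon.is_valid:
        raise ValueError("range polygon is invalid")
    if range_polygon.is_empty or len(occ) == 0:
        return OccurrenceSet(occ.df.iloc[:0])
    inside = np.array(
        [range_polygon.covers(Point(x, y)) for x, y in zip(occ.lon, occ.lat)],
        dtype=bool,
    )
    dropped = occ.df.loc[~inside, "id"].tolist()
    if dropped:
        log.info("range filter removed %d records: %s", len(dropped), dropped)
    return OccurrenceSet(occ.df[inside])


def spatial_thin(
    occ: OccurrenceSet, min_distance_km: float = 50.0, seed: int = 0
) -> OccurrenceSet:
    """Rarefy records so every retained pair is > ``min_distance_km`` apart.

    Seeded random-order greedy retention: records are visited in a shuffled
    order and kept iff farther than the cutoff from everything already
    kept. The result is maximal — no removed record could be re-added.
    Exact coordinate duplicates are removed first.
    """
    occ = occ.drop_duplicate_coordinates()
    n = len(occ)
    if n <= 1:
        return occ
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    lon, lat = occ.lon, occ.lat
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if np.all(d > min_distance_km):
            kept.append(i)
    kept_sorted = sorted(kept)
    log.info("thinning kept %d of %d records (> %.0f km)", len(kept), n, min_distance_km)
    return occ.take(kept_sorted)


def split_calibration_evaluation(
    occ: OccurrenceSet, fraction: float = 0.5, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded disjoint split into calibration and evaluation subsets."""
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_cal = int(math.ceil(n * fraction))
    cal_idx = sorted(order[:n_cal])
    eval_idx = sorted(order[n_cal:])
    return occ.take(cal_idx), occ.take(eval_idx)


def build_M(
    occ: OccurrenceSet, stack: RasterStack, buffer_degrees: float = 7.0
) -> CalibrationArea:
    """Accessible area: cells within ``buffer_degrees`` of arc of any record.

    The mask is true exactly for valid stack cells whose centre lies within
    the angular radius (great-circle measure) of at least one occurrence.
    Also records the per-variable min/max over the masked cells, which
    become the clamping bounds for model transfer.
    """
    if len(occ) == 0:
        raise ValueError("no occurrences to buffer")
    lon_g, lat_g = stack.grid.cell_centers()
    valid = stack.valid_mask()
    flat_lon = lon_g.ravel()
    flat_lat = lat_g.ravel()
    within = np.zeros(flat_lon.size, dtype=bool)
    # accumulate the union of discs one occurrence at a time; cheap pruning
    # by bounding box in degrees before the exact arc computation
    for x, y in zip(occ.lon, occ.lat):
        box = (np.abs(flat_lat - y) <= buffer_degrees) & ~within
        if not box.any():
            continue
        d = arc_degrees(flat_lon[box], flat_lat[box], x, y)
        sel = np.flatnonzero(box)
        within[sel[d <= buffer_degrees]] = True
    mask = within.reshape(valid.shape) & valid
    if not mask.any():
        raise ValueError("calibration area does not intersect the stack")
    bounds = {}
    for name in stack.layer_names:
        vals = stack[name][mask]
        bounds[name] = (float(np.nanmin(vals)), float(np.nanmax(vals)))
    return CalibrationArea(mask=mask, buffer_degrees=buffer_degrees, grid=stack.grid, clamp_bounds=bounds)
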