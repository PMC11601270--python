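"""Geography containers and scan-input preparation.

Turns raw event records plus per-level boundary data into the inputs the
scan engine consumes: validity filtering, spatial join of residential
coordinates to areas at each level, population-weighted and geometric
centroids, and area x month case-count matrices per age stratum.

Two coordinate modes are supported.  ``planar`` treats coordinates as
kilometres on a flat grid (the synthetic mode; Euclidean distances);
``lonlat`` treats them as degrees (real boundary data; great-circle
distances).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

LEVELS = ("MB", "SA1", "SA2")
AGE_GROUPS = ("all", "under25")

#: strict cut: the under-25 stratum keeps ages 0..24 only
UNDER25_MAX_AGE = 25


class GeometryError(ValueError):
    """Raised for degenerate or unusable geometric input."""


class StructuralError(ValueError):
    """Raised when a hierarchy constraint is violated (e.g. no children)."""


@dataclass
class AreaUnit:
    """One geographic unit at one level of the nested hierarchy."""

    area_id: str
    level: str
    parent_id: str | None
    centroid: tuple[float, float]
    pop_all: int
    pop_u25: int
    geometry: object | None = None

    def __post_init__(self) -> None:
        if self.pop_u25 > self.pop_all:
            raise ValueError(
                f"{self.area_id}: under-25 population exceeds total population"
            )
        if not np.all(np.isfinite(self.centroid)):
            raise GeometryError(f"{self.area_id}: non-finite centroid")


@dataclass
class GridInfo:
    """Index arithmetic for the synthetic rectangular mesh-block grid.

    Mesh blocks tile ``[0, nx*cell_km) x [0, ny*cell_km)``; cell ``(ix, iy)``
    owns the half-open rectangle so each point belongs to exactly one cell.
    """

    nx: int
    ny: int
    cell_km: float

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor(np.asarray(x, dtype=float) / self.cell_km).astype(int)
        iy = np.floor(np.asarray(y, dtype=float) / self.cell_km).astype(int)
        return ix, iy

    def inside(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)


class Geography:
    """Three nested area levels with stratified populations and centroids.

    ``levels`` maps level name to a DataFrame with columns
    ``area_id, level, parent_id, pop_all, pop_u25, cx_all, cy_all,
    cx_u25, cy_u25, geometry`` (shapely objects; optional).  Stratum-specific
    centroids exist because the under-25 population is distributed
    differently from the all-ages population.
    """

    def __init__(
        self,
        levels: Mapping[str, pd.DataFrame],
        mode: str = "planar",
        grid: GridInfo | None = None,
        meta: dict | None = None,
    ) -> None:
        if mode not in ("planar", "lonlat"):
            raise ValueError(f"unknown coordinate mode {mode!r}")
        self.levels = {k: v.reset_index(drop=True) for k, v in levels.items()}
        self.mode = mode
        self.grid = grid
        self.meta = dict(meta or {})
        for name, df in self.levels.items():
            if df["area_id"].duplicated().any():
                raise ValueError(f"duplicate area_id within level {name}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        if self.grid is not None:
            return (0.0, 0.0, self.grid.nx * self.grid.cell_km,
                    self.grid.ny * self.grid.cell_km)
        xs, ys = [], []
        for df in self.levels.values():
            for g in df["geometry"]:
                if g is not None:
                    minx, miny, maxx, maxy = g.bounds
                    xs += [minx, maxx]
                    ys += [miny, maxy]
        return (min(xs), min(ys), max(xs), max(ys))

    def areas(self, level: str) -> pd.DataFrame:
        return self.levels[level]

    def centroids(self, level: str, age_group: str = "all") -> np.ndarray:
        df = self.levels[level]
        if age_group == "all":
            return df[["cx_all", "cy_all"]].to_numpy(float)
        if age_group == "under25":
            return df[["cx_u25", "cy_u25"]].to_numpy(float)
        raise ValueError(f"unknown age group {age_group!r}")

    def populations(self, level: str, age_group: str = "all") -> np.ndarray:
        col = "pop_all" if age_group == "all" else "pop_u25"
        return self.levels[level][col].to_numpy(np.int64)

    # ------------------------------------------------------------------ io
    def to_geojson(self, level: str) -> dict:
        feats = []
        for _, row in self.levels[level].iterrows():
            geom = row.get("geometry")
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom) if geom is not None else None,
                    "properties": {
                        "area_id": row["area_id"],
                        "level": row["level"],
                        "parent_id": row["parent_id"],
                        "pop_all": int(row["pop_all"]),
                        "pop_u25": int(row["pop_u25"]),
                        "cx_all": float(row["cx_all"]),
                        "cy_all": float(row["cy_all"]),
                        "cx_u25": float(row["cx_u25"]),
                        "cy_u25": float(row["cy_u25"]),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for level in self.levels:
            with open(d / f"{level.lower()}.geojson", "w") as fh:
                json.dump(self.to_geojson(level), fh, sort_keys=True)

    @classmethod
    def from_geojson(cls, paths: Mapping[str, str], mode: str = "lonlat") -> "Geography":
        levels = {}
        for level, path in paths.items():
            with open(path) as fh:
                fc = json.load(fh)
            rows = []
            for feat in fc["features"]:
                props = feat["properties"]
                geom = shape(feat["geometry"]) if feat.get("geometry") else None
                rows.append({**props, "geometry": geom})
            levels[level] = pd.DataFrame(rows)
        return cls(levels, mode=mode)


# ---------------------------------------------------------------------------
# centroids


def weighted_centroid(
    child_centroids: Sequence[tuple[float, float]] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Population-weighted mean of child centroids.

    Falls back to the unweighted mean when every weight is zero (an area
    whose stratum population vanishes still needs a well-defined centroid).
    """
    pts = np.asarray(child_centroids, dtype=float)
    w = np.asarray(weights, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise StructuralError("weighted_centroid requires at least one child")
    if np.any(w < 0):
        raise ValueError("negative centroid weight")
    total = w.sum()
    if total == 0:
        c = pts.mean(axis=0)
    else:
        c = (pts * w[:, None]).sum(axis=0) / total
    return (float(c[0]), float(c[1]))


def geometric_centroid(polygon) -> tuple[float, float]:
    """Area-weighted centroid of a polygon (shapely)."""
    if polygon is None or polygon.is_empty or polygon.area == 0:
        raise GeometryError("degenerate polygon has no geometric centroid")
    c = polygon.centroid
    return (float(c.x), float(c.y))


# ---------------------------------------------------------------------------
# filtering and joining


def filter_events(events: pd.DataFrame, geography: Geography) -> tuple[pd.DataFrame, int]:
    """Drop records without usable residential coordinates.

    Keeps events flagged coordinate-valid whose coordinates fall inside the
    geography's extent; returns the kept frame and the excluded count.
    """
    if len(events) == 0:
        return events.copy(), 0
    minx, miny, maxx, maxy = geography.extent
    x = events["lon"].to_numpy(float)
    y = events["lat"].to_numpy(float)
    ok = (
        events["coord_valid"].astype(bool).to_numpy()
        & np.isfinite(x)
        & np.isfinite(y)
        & (x >= minx)
        & (x <= maxx)
        & (y >= miny)
        & (y <= maxy)
    )
    kept = events.loc[ok].reset_index(drop=True)
    return kept, int(len(events) - len(kept))


def spatial_join(
    events: pd.DataFrame, geography: Geography, level: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate each event with the enclosing area at ``level``.

    On the synthetic grid the assignment is index arithmetic on half-open
    cells; with polygon geometries it uses ``covers`` with ties broken by
    ascending ``area_id`` so shared boundaries resolve deterministically.
    Events enclosed by no area are returned in the second frame, never
    silently dropped.
    """
    col = f"area_{level}"
    out = events.copy()
    if len(events) == 0:
        out[col] = pd.Series(dtype=object)
        return out, out.iloc[0:0]

    x = events["lon"].to_numpy(float)
    y = events["lat"].to_numpy(float)
    areas = geography.areas(level)

    if geography.grid is not None:
        grid = geography.grid
        ix, iy = grid.cell_of(x, y)
        inside = grid.inside(ix, iy)
        # the synthetic MB grid is laid out row-major: id index = iy*nx + ix
        mb_index = np.where(inside, iy * grid.nx + ix, -1)
        mb_ids = geography.areas("MB")["area_id"].to_numpy()
        assigned = np.where(inside, mb_ids[np.clip(mb_index, 0, None)], None)
        if level != "MB":
            assigned = _lift_to_level(assigned, geography, level)
    else:
        geoms = list(areas["geometry"])
        order = np.argsort(areas["area_id"].to_numpy())
        tree = STRtree([geoms[i] for i in order])
        from shapely.geometry import Point

        assigned = np.full(len(events), None, dtype=object)
        pts = [Point(px, py) for px, py in zip(x, y)]
        idx_pts, idx_areas = tree.query(pts, predicate="covered_by")
        # first match in ascending area_id order wins
        ids_sorted = areas["area_id"].to_numpy()[order]
        for p_i, a_i in zip(idx_pts, idx_areas):
            cur = assigned[p_i]
            cand = ids_sorted[a_i]
            if cur is None or cand < cur:
                assigned[p_i] = cand

    out[col] = assigned
    matched = out[col].notna().to_numpy()
    return out.loc[matched].reset_index(drop=True), out.loc[~matched].reset_index(drop=True)


def _lift_to_level(mb_ids: np.ndarray, geography: Geography, level: str) -> np.ndarray:
    """Map MB assignments up the hierarchy via parent pointers."""
    mb = geography.areas("MB").set_index("area_id")
    parent_of_mb = mb["parent_id"]
    if level == "SA1":
        table = parent_of_mb
    elif level == "SA2":
        sa1 = geography.areas("SA1").set_index("area_id")["parent_id"]
        table = parent_of_mb.map(sa1)
    else:
        raise ValueError(f"unknown level {level!r}")
    out = np.full(len(mb_ids), None, dtype=object)
    mask = np.array([v is not None for v in mb_ids])
    if mask.any():
        out[mask] = table.loc[np.asarray(mb_ids[mask], dtype=object)].to_numpy()
    return out


# ---------------------------------------------------------------------------
# case aggregation


def month_index(dates: pd.Series | Iterable, study_start: str) -> np.ndarray:
    """Integer month index with 0 at the study's first calendar month."""
    d = pd.to_datetime(pd.Series(list(dates)))
    start = pd.Period(study_start, freq="M")
    per = d.dt.to_period("M")
    return ((per.dt.year - start.year) * 12 + (per.dt.month - start.month)).to_numpy()


@dataclass
class CaseSeries:
    """Area x month case-count matrix for one level, stratum, and window.

    ``counts[a, m]`` is the number of events in area ``a`` during month
    ``months[m]``; ``populations`` is the matching per-area stratum
    population held constant over the window (single-census assumption).
    """

    level: str
    age_group: str
    area_ids: np.ndarray
    months: np.ndarray  # global month indices covered, consecutive
    counts: np.ndarray  # (n_areas, n_months) nonnegative ints
    populations: np.ndarray  # (n_areas,)
    event_ids: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=np.int64)
        if self.counts.shape != (len(self.area_ids), len(self.months)):
            raise ValueError("counts shape does not match areas x months")
        if (self.counts < 0).any():
            raise ValueError("negative case count")
        if len(self.populations) != len(self.area_ids):
            raise ValueError("populations misaligned with areas")

    @property
    def total_C(self) -> int:
        return int(self.counts.sum())

    @property
    def n_months(self) -> int:
        return len(self.months)

    def slice_months(self, start: int, end: int) -> "CaseSeries":
        """Sub-series for global months ``[start, end]`` inclusive."""
        lo = int(np.searchsorted(self.months, start))
        hi = int(np.searchsorted(self.months, end, side="right"))
        if lo >= hi:
            raise ValueError("empty month slice")
        ev = None
        if self.event_ids is not None:
            m = self.event_ids["month"].between(start, end)
            ev = self.event_ids.loc[m].reset_index(drop=True)
        return CaseSeries(
            level=self.level,
            age_group=self.age_group,
            area_ids=self.area_ids,
            months=self.months[lo:hi],
            counts=self.counts[:, lo:hi],
            populations=self.populations,
            event_ids=ev,
        )

    def to_long_frame(self) -> pd.DataFrame:
        a, m = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "area_id": self.area_ids[a],
                "month": self.months[m],
                "count": self.counts[a, m],
            }
        )


def aggregate_counts(
    joined: pd.DataFrame,
    geography: Geography,
    level: str,
    age_group: str,
    study_start: str,
    n_months: int,
) -> tuple[CaseSeries, pd.DataFrame]:
    """Build the area x month matrix for one level and age stratum.

    Events dated outside the study months are returned in the second frame
    (excluded from the matrix but reported).  The under-25 stratum keeps
    only ages strictly below 25.
    """
    col = f"area_{level}"
    if col not in joined.columns:
        raise ValueError(f"events not joined at level {level}")
    areas = geography.areas(level)
    ids = areas["area_id"].to_numpy()

    df = joined
    if age_group == "under25":
        df = df.loc[df["age"] < UNDER25_MAX_AGE]
    elif age_group != "all":
        raise ValueError(f"unknown age group {age_group!r}")

    mi = month_index(df["date"], study_start) if len(df) else np.array([], dtype=int)
    in_range = (mi >= 0) & (mi < n_months)
    out_of_range = df.loc[~in_range].reset_index(drop=True)
    df = df.loc[in_range]
    mi = mi[in_range]

    pos = pd.Series(np.arange(len(ids)), index=ids)
    rows = pos.loc[df[col].to_numpy(dtype=object)].to_numpy() if len(df) else np.array([], dtype=int)
    counts = np.zeros((len(ids), n_months), dtype=np.int64)
    np.add.at(counts, (rows, mi), 1)

    ev = pd.DataFrame(
        {
            "event_id": df["event_id"].to_numpy(),
            "area_id": df[col].to_numpy(),
            "month": mi,
        }
    )
    series = CaseSeries(
        level=level,
        age_group=age_group,
        area_ids=ids,
        months=np.arange(n_months),
        counts=counts,
        populations=geography.populations(level, age_group),
        event_ids=ev,
    )
    return series, out_of_range
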