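"""Synthetic register and geography generator.

The real register this pipeline was designed for is confidential, so every
test and example runs on synthetic data that reproduces its structure: a
three-level nested census geography (mesh blocks of 30-60 dwellings inside
SA1s of roughly 400 people inside SA2s of roughly 10,000), a statewide
Poisson baseline of suspected suicides distributed proportionally to
population, a small fraction of records without usable residential
coordinates, and optional injected space-time clusters whose location,
interval, and excess size are recorded as ground truth for recovery tests.

Geography is a planar grid in kilometres (Euclidean distances); the
production path accepts lon/lat boundary data instead.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import Geography, GeometryError, GridInfo, weighted_centroid

#: persons per dwelling used to convert mesh-block dwelling counts
PERSONS_PER_DWELLING = 2.5

#: default study start (month index 0)
DEFAULT_STUDY_START = "2015-01"


class ParameterError(ValueError):
    """Raised when a generator specification is invalid."""


@dataclass
class GeographySpec:
    """Nested synthetic geography: ``n_sa2`` SA2s of ``sa1_per_sa2`` SA1s of
    ``mb_per_sa1`` mesh blocks, laid out as contiguous rectangular blocks of
    grid cells ``cell_km`` on a side.

    Defaults follow the census hierarchy the generator emulates: SA2s of
    about 10,000 people built from SA1s of about 400, themselves built from
    mesh blocks of 30-60 dwellings (~75-150 people at 2.5 persons per
    dwelling, hence 4 mesh blocks per SA1 and 25 SA1s per SA2).
    """

    n_sa2: int = 10
    sa1_per_sa2: int = 25
    mb_per_sa1: int = 4
    sa2_pop_mean: float = 10_000.0
    under25_fraction: float = 0.30
    cell_km: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sa2", "sa1_per_sa2", "mb_per_sa1"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not (0.0 <= self.under25_fraction <= 1.0):
            raise ParameterError("under25_fraction must lie in [0, 1]")
        if self.cell_km <= 0 or self.sa2_pop_mean <= 0:
            raise ParameterError("cell_km and sa2_pop_mean must be positive")


@dataclass
class BaselineSpec:
    """Statewide baseline: ``annual_total`` events/year over ``n_months``
    months, Poisson-distributed across mesh blocks proportionally to
    population, with a fraction of records lacking valid coordinates.

    The defaults mirror the surveillance setting the pipeline targets:
    around 700 suicides per year observed over a 90-month study window,
    with roughly 2.5% of records lacking a usable residential address.
    """

    annual_total: float = 700.0
    n_months: int = 90
    invalid_coord_fraction: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.annual_total <= 0:
            raise ParameterError("annual_total must be positive")
        if self.n_months < 1:
            raise ParameterError("n_months must be >= 1")
        if not (0.0 <= self.invalid_coord_fraction < 1.0):
            raise ParameterError("invalid_coord_fraction must lie in [0, 1)")


@dataclass
class TruthCluster:
    """Ground truth for one injected space-time cluster."""

    center_area_id: str
    radius_km: float
    start_month: int
    end_month: int
    excess: int
    age_group: str = "all"

    def validate(self) -> None:
        if self.start_month > self.end_month:
            raise ParameterError("start_month must be <= end_month")
        if self.excess < 1:
            raise ParameterError("excess must be >= 1")
        if self.age_group not in ("all", "under25"):
            raise ParameterError(f"unknown age group {self.age_group!r}")

    def to_json(self) -> dict:
        return asdict(self)


def _grid_dims(n: int) -> tuple[int, int]:
    """Near-square (rows, cols) with rows*cols == n exactly."""
    r = int(math.isqrt(n))
    while n % r:
        r -= 1
    return r, n // r


def make_geography(spec: GeographySpec) -> Geography:
    """Generate the nested grid geography with stratified populations.

    Mesh-block populations are round(dwellings x 2.5) with dwellings uniform
    on 30-60, rescaled so the SA2 mean hits ``sa2_pop_mean``; the under-25
    population of each mesh block is binomial in the all-ages population.
    Populations at SA1/SA2 are exact sums over children, and stratum-specific
    centroids are population-weighted means of child centroids (geometric
    centroids at mesh-block level, where no finer population exists).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    r2, c2 = _grid_dims(spec.n_sa2)
    r1, c1 = _grid_dims(spec.sa1_per_sa2)
    r0, c0 = _grid_dims(spec.mb_per_sa1)
    nx, ny = c2 * c1 * c0, r2 * r1 * r0
    n_mb = spec.n_sa2 * spec.sa1_per_sa2 * spec.mb_per_sa1

    # MB table rows follow row-major grid cell order (iy*nx + ix), the order
    # the half-open grid join indexes into
    iy, ix = np.divmod(np.arange(nx * ny), nx)
    sa1_x, sa1_y = ix // c0, iy // r0
    sa2_x, sa2_y = sa1_x // c1, sa1_y // r1
    sa2_idx = sa2_y * c2 + sa2_x
    sa1_idx = sa2_idx * spec.sa1_per_sa2 + (sa1_y % r1) * c1 + (sa1_x % c1)

    dwellings = rng.integers(30, 61, size=n_mb)
    pop = np.rint(dwellings * PERSONS_PER_DWELLING).astype(np.int64)
    scale = spec.sa2_pop_mean * spec.n_sa2 / pop.sum()
    pop = np.maximum(np.rint(pop * scale).astype(np.int64), 0)
    pop_u25 = rng.binomial(pop, spec.under25_fraction)

    ck = spec.cell_km
    mb_ids = np.array([f"MB{k:06d}" for k in range(n_mb)])
    sa1_ids = np.array([f"SA1{k:05d}" for k in range(spec.n_sa2 * spec.sa1_per_sa2)])
    sa2_ids = np.array([f"SA2{k:04d}" for k in range(spec.n_sa2)])

    cx = (ix + 0.5) * ck
    cy = (iy + 0.5) * ck
    mb_geoms = [
        box(i * ck, j * ck, (i + 1) * ck, (j + 1) * ck) for i, j in zip(ix, iy)
    ]
    mb_df = pd.DataFrame(
        {
            "area_id": mb_ids,
            "level": "MB",
            "parent_id": sa1_ids[sa1_idx],
            "pop_all": pop,
            "pop_u25": pop_u25,
            "cx_all": cx,
            "cy_all": cy,
            "cx_u25": cx,
            "cy_u25": cy,
            "geometry": mb_geoms,
        }
    )

    sa1_df = _aggregate_level(
        mb_df, sa1_ids, "SA1", parent_ids=sa2_ids[np.arange(len(sa1_ids)) // spec.sa1_per_sa2]
    )
    sa2_df = _aggregate_level(sa1_df, sa2_ids, "SA2", parent_ids=None)

    geo = Geography(
        {"MB": mb_df, "SA1": sa1_df, "SA2": sa2_df},
        mode="planar",
        grid=GridInfo(nx=nx, ny=ny, cell_km=ck),
        meta={"spec": asdict(spec)},
    )
    return geo


def _aggregate_level(
    child_df: pd.DataFrame,
    ids: np.ndarray,
    level: str,
    *,
    parent_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate child areas into their parents: exact population sums,
    stratum-weighted centroids, unioned bounding geometry.

    ``ids`` are this level's area ids; ``parent_ids`` (aligned with ``ids``)
    point one level further up.
    """
    grand = parent_ids
    rows = []
    grouped = child_df.groupby("parent_id", sort=True)
    pid_order = {pid: k for k, pid in enumerate(ids)}
    for pid, grp in grouped:
        pall = int(grp["pop_all"].sum())
        pu25 = int(grp["pop_u25"].sum())
        cx_a, cy_a = weighted_centroid(
            grp[["cx_all", "cy_all"]].to_numpy(), grp["pop_all"].to_numpy()
        )
        cx_u, cy_u = weighted_centroid(
            grp[["cx_u25", "cy_u25"]].to_numpy(), grp["pop_u25"].to_numpy()
        )
        minx = min(g.bounds[0] for g in grp["geometry"])
        miny = min(g.bounds[1] for g in grp["geometry"])
        maxx = max(g.bounds[2] for g in grp["geometry"])
        maxy = max(g.bounds[3] for g in grp["geometry"])
        k = pid_order[pid]
        rows.append(
            {
                "area_id": pid,
                "level": level,
                "parent_id": grand[k] if grand is not None else None,
                "pop_all": pall,
                "pop_u25": pu25,
                "cx_all": cx_a,
                "cy_all": cy_a,
                "cx_u25": cx_u,
                "cy_u25": cy_u,
                "geometry": box(minx, miny, maxx, maxy),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("area_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# events


def make_baseline_events(
    geo: Geography,
    spec: BaselineSpec,
    study_start: str = DEFAULT_STUDY_START,
    under25_fraction: float | None = None,
) -> pd.DataFrame:
    """Draw the baseline event register under spatial homogeneity of risk.

    Monthly counts per mesh block are Poisson with mean
    ``annual_total/12 x pop_mb/pop_total``; each event gets a uniform
    coordinate inside its mesh-block rectangle, an age whose under-25 share
    matches the geography's stratum fraction in expectation, and, with
    probability ``invalid_coord_fraction``, missing coordinates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mb = geo.areas("MB")
    pop = mb["pop_all"].to_numpy(float)
    total = pop.sum()
    if total <= 0:
        raise ParameterError("geography has zero total population")
    if under25_fraction is None:
        under25_fraction = geo.meta.get("spec", {}).get("under25_fraction", 0.3)

    lam = (spec.annual_total / 12.0) * (pop / total)
    counts = rng.poisson(lam[:, None], size=(len(mb), spec.n_months))
    mb_row, month = np.nonzero(counts)
    reps = counts[mb_row, month]
    mb_row = np.repeat(mb_row, reps)
    month = np.repeat(month, reps)
    n = len(mb_row)

    ck = geo.grid.cell_km if geo.grid is not None else 1.0
    x0 = mb["cx_all"].to_numpy()[mb_row] - ck / 2
    y0 = mb["cy_all"].to_numpy()[mb_row] - ck / 2
    lon = x0 + rng.random(n) * ck
    lat = y0 + rng.random(n) * ck

    under = rng.random(n) < under25_fraction
    age = np.where(under, rng.integers(10, 25, size=n), rng.integers(25, 90, size=n))
    invalid = rng.random(n) < spec.invalid_coord_fraction
    lon = np.where(invalid, np.nan, lon)
    lat = np.where(invalid, np.nan, lat)

    start = pd.Period(study_start, freq="M")
    periods = pd.PeriodIndex([start + int(m) for m in month], freq="M")
    day = rng.integers(1, periods.days_in_month + 1)
    dates = pd.to_datetime(periods.to_timestamp()) + pd.to_timedelta(day - 1, unit="D")

    events = pd.DataFrame(
        {
            "event_id": [f"E{k:06d}" for k in range(n)],
            "date": dates.strftime("%Y-%m-%d"),
            "age": age,
            "lat": lat,
            "lon": lon,
            "coord_valid": ~invalid,
            "sex": rng.choice(["F", "M"], size=n, p=[0.26, 0.74]),
            "method": pd.array([None] * n, dtype=object),
        }
    )
    return events.sort_values("date", kind="stable").reset_index(drop=True)


def inject_cluster(
    events: pd.DataFrame,
    geo: Geography,
    truth: TruthCluster,
    seed: int = 0,
    study_start: str = DEFAULT_STUDY_START,
) -> tuple[pd.DataFrame, TruthCluster]:
    """Add exactly ``truth.excess`` events near a center over a month span.

    New events are placed uniformly over mesh blocks whose centroids lie
    within ``radius_km`` of the center area's centroid and uniformly over
    the truth months; ages respect the truth's age group.  Returns the
    augmented register and the unchanged truth record.
    """
    truth.validate()
    rng = np.random.default_rng(seed)

    center = _find_centroid(geo, truth.center_area_id)
    mb = geo.areas("MB")
    cxy = mb[["cx_all", "cy_all"]].to_numpy()
    dist = np.hypot(cxy[:, 0] - center[0], cxy[:, 1] - center[1])
    eligible = np.flatnonzero(dist <= truth.radius_km)
    if len(eligible) == 0:
        raise GeometryError("no mesh block within radius of the cluster center")

    n = truth.excess
    rows = rng.choice(eligible, size=n)
    ck = geo.grid.cell_km if geo.grid is not None else 1.0
    lon = cxy[rows, 0] - ck / 2 + rng.random(n) * ck
    lat = cxy[rows, 1] - ck / 2 + rng.random(n) * ck
    months = rng.integers(truth.start_month, truth.end_month + 1, size=n)
    if truth.age_group == "under25":
        age = rng.integers(10, 25, size=n)
    else:
        u25f = geo.meta.get("spec", {}).get("under25_fraction", 0.3)
        under = rng.random(n) < u25f
        age = np.where(under, rng.integers(10, 25, size=n), rng.integers(25, 90, size=n))

    start = pd.Period(study_start, freq="M")
    periods = pd.PeriodIndex([start + int(m) for m in months], freq="M")
    day = rng.integers(1, periods.days_in_month + 1)
    dates = pd.to_datetime(periods.to_timestamp()) + pd.to_timedelta(day - 1, unit="D")

    new = pd.DataFrame(
        {
            "event_id": [f"X{k:06d}" for k in range(n)],
            "date": dates.strftime("%Y-%m-%d"),
            "age": age,
            "lat": lat,
            "lon": lon,
            "coord_valid": True,
            "sex": rng.choice(["F", "M"], size=n, p=[0.26, 0.74]),
            "method": pd.array([None] * n, dtype=object),
        }
    )
    out = pd.concat([events, new], ignore_index=True)
    return out, truth


def _find_centroid(geo: Geography, area_id: str) -> tuple[float, float]:
    for level, df in geo.levels.items():
        hit = df.loc[df["area_id"] == area_id]
        if len(hit):
            return (float(hit["cx_all"].iloc[0]), float(hit["cy_all"].iloc[0]))
    raise KeyError(f"unknown area_id {area_id!r}")


# ---------------------------------------------------------------------------
# io


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": str}, keep_default_na=True)
    df["coord_valid"] = df["coord_valid"].astype(bool)
    return df


def write_truth_json(truths, path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_json() for t in truths], fh, indent=2, sort_keys=True)


def read_truth_json(path) -> list[TruthCluster]:
    with open(path) as fh:
        return [TruthCluster(**d) for d in json.load(fh)]
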