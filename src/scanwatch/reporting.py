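"""Report surfaces: cluster summary tables, detection timelines, exports.

The summary table mirrors the columns a surveillance report needs (level,
duration, number of areas, observed, expected, p, zone population) with
statistical-disclosure control: observed counts below a threshold are
rendered as ``nr`` with the p-value reported only as a bound and the zone
population rounded up, so small clusters cannot be located.  Timelines
show, for one detected cluster, the full monthly event history inside its
zone, the scanned epoch, the cluster interval, and the month at which a
live system would have flagged it.
"""
from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surveillance import DetectionRecord

#: disclosure grid for suppressed p-values
_P_BOUNDS = (0.01, 0.05, 0.10, 0.50, 1.0)


@dataclass
class SummaryRow:
    cluster: str
    level: str
    duration_months: int
    n_areas: int
    observed: str
    expected: float
    p_value: str
    population: str


@dataclass
class TimelineReport:
    """Month-by-month event history for one detected cluster group."""

    cluster_group_id: str
    months: np.ndarray
    in_boundary_counts: np.ndarray
    epoch_span: tuple[int, int]
    cluster_span: tuple[int, int]
    detection_month: int
    post_detection_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "count": self.in_boundary_counts})


def _fmt_p(p: float) -> str:
    return f"{p:.3f}".lstrip("0") if p is not None else ""


def _suppress_p(p: float) -> str:
    for b in _P_BOUNDS:
        if p <= b:
            return ">" + f"{b:.2f}".rstrip("0").lstrip("0")
    return ">1"


def make_summary_table(
    detections: list[DetectionRecord],
    suppression_threshold: int = 5,
    population_round: int = 50,
) -> pd.DataFrame:
    """One row per member result, grouped under its cluster label.

    Member results of group ``k`` are labelled ``ka, kb, ...`` in
    decreasing LLR.  Observed counts below ``suppression_threshold`` are
    suppressed: the count prints as ``nr``, the p-value as an upper bound
    from a coarse grid and the zone population rounded up to the nearest
    ``population_round``.
    """
    rows: list[SummaryRow] = []
    for gi, det in enumerate(detections, start=1):
        members = sorted(det.member_results, key=lambda r: -r.result.llr)
        for mi, tr in enumerate(members):
            r = tr.result
            label = f"{gi}{chr(ord('a') + mi)}" if mi < 26 else f"{gi}z{mi}"
            if suppression_threshold and r.observed < suppression_threshold:
                observed = "nr"
                p_txt = _suppress_p(r.p_value if r.p_value is not None else 1.0)
                pop = ">" + str(int(math.ceil(r.zone.zone_pop / population_round)) * population_round)
            else:
                observed = str(r.observed)
                p_txt = _fmt_p(r.p_value)
                pop = str(r.zone.zone_pop)
            rows.append(
                SummaryRow(
                    cluster=label,
                    level=tr.level,
                    duration_months=r.duration,
                    n_areas=r.n_areas,
                    observed=observed,
                    expected=round(r.expected, 3),
                    p_value=p_txt,
                    population=pop,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def make_timeline(
    group: DetectionRecord,
    event_table: pd.DataFrame,
    n_months: int,
) -> TimelineReport:
    """Full-study monthly in-zone counts plus detection annotations.

    ``event_table`` must carry ``event_id``, ``area_id`` and ``month`` for
    the representative's level and age stratum (the series' ``event_ids``
    frame is exactly this).
    """
    rep = group.representative
    members = set(rep.result.zone.member_area_ids)
    months = np.arange(n_months)
    counts = np.zeros(n_months, dtype=int)
    m = event_table["area_id"].isin(members) & event_table["month"].between(0, n_months - 1)
    vals = event_table.loc[m, "month"].to_numpy(int)
    np.add.at(counts, vals, 1)
    detection = group.first_detection_month
    return TimelineReport(
        cluster_group_id=group.cluster_group_id,
        months=months,
        in_boundary_counts=counts,
        epoch_span=(rep.epoch.start_month, rep.epoch.end_month),
        cluster_span=(rep.result.start_month, rep.result.end_month),
        detection_month=detection,
        post_detection_events=int(counts[detection + 1:].sum()),
    )


def plot_timeline(report: TimelineReport, path) -> None:
    """Bar timeline with epoch span, cluster span and detection marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.bar(report.months, report.in_boundary_counts, color="0.3", width=0.8)
    top = max(1, report.in_boundary_counts.max())
    e0, e1 = report.epoch_span
    c0, c1 = report.cluster_span
    ax.annotate("", xy=(e0, top * 1.15), xytext=(e1, top * 1.15),
                arrowprops=dict(arrowstyle="->", color="tab:blue"))
    ax.text(e0, top * 1.22, "epoch scanned", color="tab:blue", fontsize=8)
    ax.annotate("", xy=(c1, top * 1.02), xytext=(c0, top * 1.02),
                arrowprops=dict(arrowstyle="->", color="tab:red"))
    ax.text(c0, top * 1.07, "cluster", color="tab:red", fontsize=8)
    ax.axvline(report.detection_month, color="tab:green", ls="--", lw=1)
    ax.text(report.detection_month, top * 0.95, " detected", color="tab:green",
            fontsize=8, ha="left")
    ax.set_xlabel("study month")
    ax.set_ylabel("events in cluster area")
    ax.set_title(f"Cluster {report.cluster_group_id}")
    ax.set_ylim(0, top * 1.35)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_circles_geojson(detections: list[DetectionRecord], geography) -> dict:
    """Circle outlines of each representative zone, for mapping."""
    from shapely.geometry import Point, mapping

    feats = []
    for det in detections:
        r = det.representative.result
        level = det.representative.level
        df = geography.areas(level)
        row = df.loc[df["area_id"] == r.zone.center_area_id].iloc[0]
        center = Point(row["cx_all"], row["cy_all"])
        radius = max(r.zone.radius_km, 1e-6)
        circle = center.buffer(radius, quad_segs=32)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(circle),
                "properties": {
                    "cluster_group_id": det.cluster_group_id,
                    "level": level,
                    "radius_km": r.zone.radius_km,
                    "observed": r.observed,
                    "expected": round(r.expected, 4),
                    "p_value": r.p_value,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def detections_json(detections: list[DetectionRecord]) -> list[dict]:
    out = []
    for det in detections:
        r = det.representative.result
        out.append(
            {
                "cluster_group_id": det.cluster_group_id,
                "age_group": det.age_group,
                "first_detection_epoch": det.first_detection_epoch.ordinal,
                "first_detection_month": det.first_detection_month,
                "levels_seen": sorted(det.levels_seen),
                "n_member_results": len(det.member_results),
                "representative": {
                    "level": det.representative.level,
                    "center": r.zone.center_area_id,
                    "members": list(r.zone.member_area_ids),
                    "radius_km": round(r.zone.radius_km, 6),
                    "start_month": r.start_month,
                    "end_month": r.end_month,
                    "observed": r.observed,
                    "expected": round(r.expected, 6),
                    "llr": round(r.llr, 6),
                    "p_value": r.p_value,
                    "zone_pop": r.zone.zone_pop,
                },
            }
        )
    return out


def render_outputs(
    detections: list[DetectionRecord],
    event_tables: dict[tuple[str, str], pd.DataFrame],
    geography,
    n_months: int,
    outdir,
    suppression_threshold: int = 5,
    make_plots: bool = True,
) -> list[pathlib.Path]:
    """Write the full report bundle; returns the paths written.

    Layout: ``detections.json``, ``summary_table.csv``,
    ``timelines/<group_id>.csv`` (+ ``.png``), ``clusters.geojson``.
    File content is deterministic for identical inputs.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    if not detections:
        return written

    p = out / "detections.json"
    with open(p, "w") as fh:
        json.dump(detections_json(detections), fh, indent=2, sort_keys=True)
    written.append(p)

    table = make_summary_table(detections, suppression_threshold)
    p = out / "summary_table.csv"
    table.to_csv(p, index=False)
    written.append(p)

    p = out / "clusters.geojson"
    with open(p, "w") as fh:
        json.dump(cluster_circles_geojson(detections, geography), fh, sort_keys=True)
    written.append(p)

    tdir = out / "timelines"
    tdir.mkdir(exist_ok=True)
    for det in detections:
        key = (det.representative.level, det.age_group)
        ev = event_tables.get(key)
        if ev is None:
            continue
        rep = make_timeline(det, ev, n_months)
        p = tdir / f"{det.cluster_group_id}.csv"
        rep.to_frame().to_csv(p, index=False)
        written.append(p)
        if make_plots:
            png = tdir / f"{det.cluster_group_id}.png"
            plot_timeline(rep, png)
            written.append(png)
    return written
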