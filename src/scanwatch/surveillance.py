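"""Rolling prospective-surveillance simulation.

A live register delivers one new month of data at a time.  The simulation
replays that feed: each epoch is the most recent 24 months (by default),
stepped forward one month per scan, and every epoch is scanned at each
geographic level and age stratum.  Significant clusters from all runs are
then collated; because scans at different resolutions and in overlapping
epochs repeatedly rediscover the same group of deaths, results are grouped
by the Jaccard similarity of their enclosed event sets, and each group is
dated by the end month of the first epoch that revealed it — the moment a
live system would have raised the flag.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import AGE_GROUPS, CaseSeries, Geography, LEVELS, aggregate_counts, filter_events, spatial_join
from .scan import ClusterResult, ParameterError, PoissonScan, ScanParams, ZoneSystem

logger = logging.getLogger("scanwatch")


@dataclass(frozen=True)
class Epoch:
    """One rolling window of study months, inclusive on both ends."""

    start_month: int
    end_month: int
    ordinal: int

    @property
    def length(self) -> int:
        return self.end_month - self.start_month + 1


def build_epochs(
    first_study_month: int,
    last_study_month: int,
    epoch_len: int = 24,
    step: int = 1,
) -> list[Epoch]:
    """Rolling epochs from the first possible window to the study's end.

    The first epoch starts at the study's first month; subsequent epochs
    advance ``step`` months; the last epoch ends at the study's last month.
    """
    n = last_study_month - first_study_month + 1
    if n < epoch_len:
        raise ParameterError("study period shorter than one epoch")
    if step < 1 or epoch_len < 1:
        raise ParameterError("epoch_len and step must be >= 1")
    epochs = []
    start = first_study_month
    k = 0
    while start + epoch_len - 1 <= last_study_month:
        epochs.append(Epoch(start, start + epoch_len - 1, k))
        start += step
        k += 1
    return epochs


@dataclass
class TaggedResult:
    """A cluster result with its run provenance."""

    result: ClusterResult
    epoch: Epoch
    level: str
    age_group: str
    significant: bool


@dataclass
class DetectionRecord:
    """A deduplicated cluster: equivalent results grouped across runs."""

    cluster_group_id: str
    representative: TaggedResult
    member_results: list[TaggedResult]
    first_detection_epoch: Epoch
    first_detection_month: int
    levels_seen: frozenset
    age_group: str


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def group_equivalent(
    results: list[TaggedResult], jaccard_threshold: float = 0.5
) -> list[DetectionRecord]:
    """Partition results into groups of functionally equivalent clusters.

    Two results are equivalent when the Jaccard similarity of their
    enclosed event-id sets reaches the threshold; grouping is the
    transitive closure, run separately per age stratum.  Each group's
    representative is its highest-LLR member and its detection date is the
    end of the earliest member epoch.
    """
    records: list[DetectionRecord] = []
    for age_group in sorted({r.age_group for r in results}):
        sub = [r for r in results if r.age_group == age_group]
        n = len(sub)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if jaccard(sub[i].result.event_ids, sub[j].result.event_ids) >= jaccard_threshold:
                    parent[find(i)] = find(j)

        groups: dict[int, list[TaggedResult]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(sub[i])
        for members in groups.values():
            rep = max(members, key=lambda r: r.result.llr)
            first = min(members, key=lambda r: r.epoch.ordinal).epoch
            records.append(
                DetectionRecord(
                    cluster_group_id="",
                    representative=rep,
                    member_results=sorted(members, key=lambda r: (r.epoch.ordinal, r.level)),
                    first_detection_epoch=first,
                    first_detection_month=first.end_month,
                    levels_seen=frozenset(r.level for r in members),
                    age_group=age_group,
                )
            )
    records.sort(key=lambda d: (d.first_detection_epoch.ordinal, -d.representative.result.llr))
    for k, rec in enumerate(records):
        rec.cluster_group_id = f"{rec.age_group}-{k + 1:02d}"
    return records


def earliest_detection(group: DetectionRecord | list[TaggedResult]) -> tuple[int, int]:
    """(epoch ordinal, calendar month index) at which the group first fired.

    Detection happens at the end month of the first flagging epoch — the
    point at which that month's data would just have arrived.
    """
    members = group.member_results if isinstance(group, DetectionRecord) else group
    if not members:
        raise ValueError("empty cluster group")
    first = min(members, key=lambda r: r.epoch.ordinal).epoch
    return first.ordinal, first.end_month


# ---------------------------------------------------------------------------
# the sweep model


@dataclass
class RunLogEntry:
    epoch: int
    level: str
    age_group: str
    C: int
    max_llr: float
    best_p: float | None
    status: str


class RollingSurveillance:
    """Monthly-feed surveillance simulation over one event register.

    Prepares each level/stratum once (filter, join, aggregate, zones) and
    scans every epoch x level x age-group combination independently; runs
    that fail are logged, never abort the sweep.
    """

    def __init__(
        self,
        events: pd.DataFrame,
        geography: Geography,
        params: ScanParams | None = None,
        levels: tuple[str, ...] = LEVELS,
        age_groups: tuple[str, ...] = AGE_GROUPS,
        epoch_len: int = 24,
        step: int = 1,
        study_start: str = "2015-01",
        n_months: int = 90,
        jaccard_threshold: float = 0.5,
        cache: dict | None = None,
    ) -> None:
        self.events = events
        self.geography = geography
        self.params = params or ScanParams()
        self.levels = tuple(levels)
        self.age_groups = tuple(age_groups)
        self.epoch_len = epoch_len
        self.step = step
        self.study_start = study_start
        self.n_months = n_months
        self.jaccard_threshold = jaccard_threshold
        #: per-run result cache keyed by (epoch, level, stratum, params hash)
        self.cache = cache if cache is not None else {}

    def _params_hash(self) -> str:
        blob = json.dumps(self.params.__dict__, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def fit(self, seed: int = 0) -> "SurveillanceResults":
        epochs = build_epochs(0, self.n_months - 1, self.epoch_len, self.step)
        kept, n_excluded = filter_events(self.events, self.geography)

        # prepare once per level/stratum
        prepared: dict[tuple[str, str], tuple[CaseSeries, ZoneSystem]] = {}
        for level in self.levels:
            joined, unmatched = spatial_join(kept, self.geography, level)
            if len(unmatched):
                logger.warning("%d events unmatched at level %s", len(unmatched), level)
            for age_group in self.age_groups:
                series, oor = aggregate_counts(
                    joined, self.geography, level, age_group, self.study_start, self.n_months
                )
                zs = ZoneSystem(
                    series.area_ids,
                    self.geography.centroids(level, age_group),
                    series.populations,
                    self.params,
                    mode=self.geography.mode,
                )
                prepared[(level, age_group)] = (series, zs)

        phash = self._params_hash()
        tagged: list[TaggedResult] = []
        run_log: list[RunLogEntry] = []
        root = np.random.SeedSequence(seed)
        for li, level in enumerate(self.levels):
            for ai, age_group in enumerate(self.age_groups):
                series, zs = prepared[(level, age_group)]
                for ep in epochs:
                    key = (ep.ordinal, level, age_group, phash)
                    try:
                        if key in self.cache:
                            res_clusters, best_llr, C = self.cache[key]
                        else:
                            sub = series.slice_months(ep.start_month, ep.end_month)
                            C = sub.total_C
                            run_seed = int(
                                np.random.SeedSequence(
                                    entropy=seed, spawn_key=(ep.ordinal, li, ai)
                                ).generate_state(1)[0] % (2**31)
                            )
                            model = PoissonScan(sub, centroids=None,
                                                params=self.params, zone_system=zs)
                            res = model.fit(seed=run_seed)
                            res_clusters = res.clusters
                            best_llr = res_clusters[0].llr if res_clusters else 0.0
                            self.cache[key] = (res_clusters, best_llr, C)
                        best_p = res_clusters[0].p_value if res_clusters else None
                        for cl in res_clusters:
                            if cl.p_value is not None and cl.p_value <= self.params.report_ceiling:
                                tagged.append(
                                    TaggedResult(
                                        result=cl,
                                        epoch=ep,
                                        level=level,
                                        age_group=age_group,
                                        significant=cl.p_value <= self.params.alpha,
                                    )
                                )
                        run_log.append(
                            RunLogEntry(ep.ordinal, level, age_group, C,
                                        float(best_llr), best_p, "ok")
                        )
                    except Exception as exc:  # per-run isolation
                        logger.exception("scan run failed: %s", key)
                        run_log.append(
                            RunLogEntry(ep.ordinal, level, age_group, -1,
                                        float("nan"), None, f"error: {exc}")
                        )
        return SurveillanceResults(
            model=self,
            epochs=epochs,
            tagged_results=tagged,
            run_log=run_log,
            n_excluded=n_excluded,
        )


class SurveillanceResults:
    """All tagged scan results from one sweep, plus collation helpers."""

    def __init__(
        self,
        model: RollingSurveillance,
        epochs: list[Epoch],
        tagged_results: list[TaggedResult],
        run_log: list[RunLogEntry],
        n_excluded: int,
    ) -> None:
        self.model = model
        self.epochs = epochs
        self.tagged_results = tagged_results
        self.run_log = run_log
        self.n_excluded = n_excluded

    @property
    def n_runs(self) -> int:
        return len(self.run_log)

    def significant_results(self, alpha: float | None = None) -> list[TaggedResult]:
        a = self.model.params.alpha if alpha is None else alpha
        return [
            t for t in self.tagged_results
            if t.result.p_value is not None and t.result.p_value <= a
        ]

    def detections(self, alpha: float | None = None,
                   jaccard_threshold: float | None = None) -> list[DetectionRecord]:
        """Grouped significant clusters with earliest-detection dating."""
        thr = self.model.jaccard_threshold if jaccard_threshold is None else jaccard_threshold
        return group_equivalent(self.significant_results(alpha), thr)

    def run_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.run_log])

    def summary(self) -> str:
        det = self.detections()
        lines = [
            "Rolling scan surveillance",
            f"{self.n_runs} scan runs "
            f"({len(self.epochs)} epochs x {len(self.model.levels)} levels "
            f"x {len(self.model.age_groups)} age groups)",
            f"{self.n_excluded} events excluded for invalid coordinates",
            f"{len(self.significant_results())} significant results "
            f"-> {len(det)} distinct clusters (alpha={self.model.params.alpha})",
        ]
        for d in det:
            r = d.representative.result
            lines.append(
                f"  {d.cluster_group_id}: first flagged at end of month "
                f"{d.first_detection_month} (epoch {d.first_detection_epoch.ordinal}); "
                f"levels {sorted(d.levels_seen)}; obs {r.observed}, "
                f"exp {r.expected:.3f}, p {r.p_value}"
            )
        return "\n".join(lines)
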