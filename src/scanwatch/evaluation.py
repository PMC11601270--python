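"""Method-validation studies: null calibration and injected-cluster power.

These are the two standard checks for a scan-based surveillance system:
(a) under a spatially homogeneous null the Monte Carlo rank p-values must
be calibrated (p <= alpha in about alpha of scans), and (b) a cluster of
known location, interval and excess injected into synthetic baseline data
must be detected, grouped, and dated close to its true end.  Both run at
desk scale on the synthetic geography.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan import PoissonScan, ScanParams, ZoneSystem
from .surveillance import RollingSurveillance
from .synthetic import (
    BaselineSpec,
    GeographySpec,
    TruthCluster,
    inject_cluster,
    make_baseline_events,
    make_geography,
)


def _child_seed(root: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=root, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CalibrationResult:
    n_sims: int
    n_significant: int
    alpha: float
    p_values: np.ndarray

    @property
    def share(self) -> float:
        return self.n_significant / self.n_sims


def null_calibration(
    n_sims: int = 200,
    n_replicates: int = 199,
    alpha: float = 0.05,
    n_areas: int = 100,
    total_cases: int = 120,
    epoch_len: int = 24,
    max_pop_fraction: float = 0.1,
    seed: int = 0,
) -> CalibrationResult:
    """Share of null scans whose most likely cluster reaches ``alpha``.

    Each simulation draws one null case series (``total_cases`` distributed
    multinomially over area-months, proportional to population) on a
    single-level synthetic geography of ``n_areas`` areas, scans it, and
    records the most likely cluster's Monte Carlo p-value.  For a
    calibrated test the share with p <= alpha is alpha, up to binomial
    noise in ``n_sims``.
    """
    geo = make_geography(
        GeographySpec(n_sa2=n_areas, sa1_per_sa2=1, mb_per_sa1=1,
                      sa2_pop_mean=400, seed=_child_seed(seed, 0))
    )
    area_ids = geo.areas("MB")["area_id"].to_numpy()
    pops = geo.populations("MB", "all")
    cents = geo.centroids("MB", "all")
    params = ScanParams(max_pop_fraction=max_pop_fraction,
                        n_replicates=n_replicates, alpha=alpha)
    zs = ZoneSystem(area_ids, cents, pops, params, mode="planar")

    from .geo import CaseSeries

    T = epoch_len
    prob = np.repeat(pops / pops.sum() / T, T)
    rng = np.random.default_rng(_child_seed(seed, 1))
    p_values = np.empty(n_sims)
    for i in range(n_sims):
        counts = rng.multinomial(total_cases, prob).reshape(len(pops), T)
        series = CaseSeries(level="MB", age_group="all", area_ids=area_ids,
                            months=np.arange(T), counts=counts, populations=pops)
        model = PoissonScan(series, None, params, zone_system=zs)
        res = model.fit(seed=_child_seed(seed, 2, i))
        best = res.most_likely
        p_values[i] = best.p_value if best is not None else 1.0
    n_sig = int((p_values <= alpha).sum())
    return CalibrationResult(n_sims, n_sig, alpha, p_values)


@dataclass
class RecoveryOutcome:
    dataset_seed: int
    truth: TruthCluster
    detected: bool
    detection_month: int | None
    zone_contains_center: bool
    interval_overlaps: bool


@dataclass
class RecoveryResult:
    outcomes: list[RecoveryOutcome]

    @property
    def n_datasets(self) -> int:
        return len(self.outcomes)

    @property
    def n_recovered(self) -> int:
        return sum(o.detected for o in self.outcomes)

    @property
    def power(self) -> float:
        return self.n_recovered / self.n_datasets

    @property
    def max_detection_delay(self) -> int | None:
        delays = [o.detection_month - o.truth.end_month
                  for o in self.outcomes if o.detected]
        return max(delays) if delays else None


def _default_recovery_geography(seed: int) -> GeographySpec:
    # 144 mesh blocks (~18,000 people): large enough that a 1 km cluster
    # zone holds only a few percent of the population, as in a real region
    return GeographySpec(n_sa2=9, sa1_per_sa2=4, mb_per_sa1=4,
                         sa2_pop_mean=2000, seed=seed)


def recovery_study(
    n_datasets: int = 20,
    excess: int = 10,
    duration: int = 6,
    radius_km: float = 1.0,
    annual_total: float = 40.0,
    n_months: int = 30,
    epoch_len: int = 24,
    params: ScanParams | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """Inject one known cluster per dataset and run the full sweep.

    Each dataset gets a fresh synthetic geography and baseline register, a
    truth cluster of ``excess`` events over ``duration`` months around a
    randomly chosen mesh block, and a complete rolling surveillance sweep
    (every epoch x level x age group).  Recovery means: some significant
    detection's zone contains the truth center and its interval overlaps
    the truth interval.
    """
    params = params or ScanParams(max_pop_fraction=0.1, n_replicates=199,
                                  alpha=0.01)
    outcomes = []
    for d in range(n_datasets):
        ds = _child_seed(seed, 10, d)
        rng = np.random.default_rng(ds)
        geo = make_geography(_default_recovery_geography(ds))
        events = make_baseline_events(
            geo,
            BaselineSpec(annual_total=annual_total, n_months=n_months,
                         invalid_coord_fraction=0.02, seed=_child_seed(seed, 11, d)),
        )
        # truth window late enough that the first epoch does not pre-date it
        end = int(rng.integers(epoch_len - 3, n_months - 1))
        start = end - duration + 1
        center = str(rng.choice(geo.areas("MB")["area_id"].to_numpy()))
        truth = TruthCluster(center_area_id=center, radius_km=radius_km,
                             start_month=start, end_month=end, excess=excess)
        events, _ = inject_cluster(events, geo, truth,
                                   seed=_child_seed(seed, 12, d))
        model = RollingSurveillance(events, geo, params,
                                    epoch_len=epoch_len, n_months=n_months)
        res = model.fit(seed=_child_seed(seed, 13, d))
        outcomes.append(_judge(res, geo, truth))
    return RecoveryResult(outcomes)


def _judge(res, geo, truth: TruthCluster) -> RecoveryOutcome:
    center_row = geo.areas("MB").set_index("area_id").loc[truth.center_area_id]
    cx, cy = center_row["cx_all"], center_row["cy_all"]
    best = None
    for det in res.detections():
        r = det.representative.result
        level = det.representative.level
        members = geo.areas(level).set_index("area_id").loc[
            list(r.zone.member_area_ids)]
        contains = bool(members["geometry"].apply(
            lambda g: g.bounds[0] <= cx <= g.bounds[2]
            and g.bounds[1] <= cy <= g.bounds[3]).any())
        overlaps = (r.start_month <= truth.end_month
                    and r.end_month >= truth.start_month)
        if contains and overlaps:
            if best is None or det.first_detection_month < best[0]:
                best = (det.first_detection_month,)
    if best is None:
        return RecoveryOutcome(0, truth, False, None, False, False)
    return RecoveryOutcome(0, truth, True, best[0], True, True)
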