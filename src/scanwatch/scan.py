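"""Discrete Poisson spatiotemporal scan statistic.

The scan slides a cylindrical window over the study region: its base is a
circle around an area centroid (realised as the distance-ordered prefix of
areas, capped by a maximum radius and a maximum share of the population)
and its height is a span of consecutive months.  Under the null, case
counts are Poisson with mean proportional to population at risk, so the
expected count in a window is the overall rate applied to the window's
person-months (indirect standardisation).  Each window is scored with the
Poisson log-likelihood ratio

    LLR = c log(c/mu) + (C - c) log((C - c)/(C - mu))    for c > mu,

zero otherwise when only elevated-rate clusters are sought; ``c`` is the
observed count inside the window, ``mu`` its expectation and ``C`` the
grand total.  The maximum over all windows is the test statistic, and its
significance comes from Monte Carlo rank inference: the same maximisation
is applied to replicate datasets drawn multinomially under the null
(conditioning on ``C``) and the p-value is the candidate's rank within the
pooled set of R + 1 maxima.

``PoissonScan`` is the model object; ``PoissonScan.fit`` returns a
``ScanResults`` carrying ranked ``ClusterResult``s with p-values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import CaseSeries

try:  # jit-compiled replicate kernel; numpy path used when unavailable
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

EARTH_RADIUS_KM = 6371.0088


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """Window caps and inference settings for one scan.

    ``max_radius_km`` and ``max_pop_fraction`` cap the spatial window
    (whichever binds first); ``max_duration_months`` caps the temporal one.
    ``n_replicates`` is the Monte Carlo replicate count R, giving a p-value
    floor of 1/(R+1).  ``alpha`` is the significance call threshold and
    ``report_ceiling`` the loosest p-value still reported.
    """

    max_radius_km: float = 100.0
    max_pop_fraction: float = 0.01
    max_duration_months: int = 12
    n_replicates: int = 999
    alpha: float = 0.01
    report_ceiling: float = 1.0
    high_rate_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.max_pop_fraction <= 1.0):
            raise ParameterError("max_pop_fraction must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.max_duration_months < 1:
            raise ParameterError("max_duration_months must be >= 1")
        if self.max_radius_km <= 0:
            raise ParameterError("max_radius_km must be positive")


@dataclass(frozen=True)
class Zone:
    """A candidate spatial window: the center area plus its nearest
    neighbours in increasing centroid distance."""

    center_area_id: str
    member_area_ids: tuple[str, ...]
    radius_km: float
    zone_pop: int


@dataclass
class ClusterResult:
    """One scored space-time window, ranked within its scan."""

    zone: Zone
    start_month: int
    end_month: int
    observed: int
    expected: float
    llr: float
    p_value: float | None = None
    relative_risk: float = math.nan
    rank: int | None = None
    event_ids: frozenset = field(default_factory=frozenset)

    @property
    def duration(self) -> int:
        return self.end_month - self.start_month + 1

    @property
    def n_areas(self) -> int:
        return len(self.zone.member_area_ids)


# ---------------------------------------------------------------------------
# geometry


def _distances(centroids: np.ndarray, mode: str) -> np.ndarray:
    """Pairwise centroid distances in km (Euclidean or haversine)."""
    c = np.asarray(centroids, float)
    if mode == "planar":
        d = c[:, None, :] - c[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])
    lon = np.radians(c[:, 0])
    lat = np.radians(c[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


class ZoneSystem:
    """Distance-ordered prefix zones for every center, under the caps.

    For each center, areas are sorted by centroid distance (ties by
    ascending area id) and the zone grows one area at a time until the next
    addition would breach the radius or population cap; the singleton zone
    is always retained even if the center's own population exceeds the cap,
    so a single hot area can still be flagged.
    """

    def __init__(
        self,
        area_ids: Sequence[str],
        centroids: np.ndarray,
        populations: np.ndarray,
        params: ScanParams,
        mode: str = "planar",
    ) -> None:
        params.validate()
        self.area_ids = np.asarray(area_ids)
        self.populations = np.asarray(populations, dtype=np.int64)
        if (self.populations < 0).any():
            raise ParameterError("negative population")
        total = int(self.populations.sum())
        if total == 0:
            raise ParameterError("all populations are zero")
        self.total_pop = total
        self.params = params
        cap = params.max_pop_fraction * total

        dist = _distances(centroids, mode)
        n = len(self.area_ids)
        id_rank = np.argsort(np.argsort(self.area_ids))
        orders: list[np.ndarray] = []
        radii: list[np.ndarray] = []
        for i in range(n):
            order = np.lexsort((id_rank, dist[i]))
            # center itself sorts first (distance 0, but make it explicit)
            order = np.concatenate(([i], order[order != i]))
            cum = 0
            keep = []
            for j in order:
                if j != i:
                    if dist[i, j] > params.max_radius_km:
                        break
                    if cum + self.populations[j] > cap:
                        break
                cum += int(self.populations[j])
                keep.append(j)
            keep = np.asarray(keep, dtype=np.intp)
            orders.append(keep)
            radii.append(dist[i, keep])
        self._orders = orders
        self._radii = radii

        lmax = max(len(o) for o in orders)
        self._ord_pad = np.zeros((n, lmax), dtype=np.intp)
        self._mask = np.zeros((n, lmax), dtype=bool)
        for i, o in enumerate(orders):
            self._ord_pad[i, : len(o)] = o
            self._mask[i, : len(o)] = True
        pop_pad = np.where(self._mask, self.populations[self._ord_pad], 0)
        self._pop_prefix = np.cumsum(pop_pad, axis=1)  # (n, lmax)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def zones(self) -> list[Zone]:
        """Materialise the deduplicated zone list (for inspection/tests)."""
        seen: dict[frozenset, Zone] = {}
        for i, order in enumerate(self._orders):
            for l in range(1, len(order) + 1):
                members = frozenset(order[:l])
                if members in seen:
                    continue
                ids = tuple(self.area_ids[j] for j in order[:l])
                seen[members] = Zone(
                    center_area_id=str(self.area_ids[i]),
                    member_area_ids=ids,
                    radius_km=float(self._radii[i][l - 1]),
                    zone_pop=int(self._pop_prefix[i, l - 1]),
                )
        return list(seen.values())


def enumerate_zones(
    area_ids: Sequence[str],
    centroids: np.ndarray,
    populations: np.ndarray,
    params: ScanParams,
    mode: str = "planar",
) -> list[Zone]:
    """All distinct distance-ordered prefix zones under the caps."""
    return ZoneSystem(area_ids, centroids, populations, params, mode).zones()


# ---------------------------------------------------------------------------
# scoring


def expected_count(
    zone_pop: float, interval_months: int, total_C: int, total_pop: float, n_months: int
) -> float:
    """Null expectation for a window: overall rate x window person-months."""
    if total_pop == 0 or n_months == 0:
        return 0.0
    return total_C * (zone_pop * interval_months) / (total_pop * n_months)


def llr(c, mu, C, high_rate_only: bool = True):
    """Poisson window log-likelihood ratio; vectorised over c and mu.

    Conventions: 0*log(0) = 0; the statistic is 0 when c <= mu under
    high-rate-only scanning, and 0 when mu = 0 with c = 0.
    """
    c = np.asarray(c, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(c > C):
        raise ValueError("observed count exceeds the grand total")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t1 = np.where(c > 0, c * np.log(np.where(c > 0, c, 1) / np.where(mu > 0, mu, np.inf)), 0.0)
        rem = C - c
        rem_mu = C - mu
        t2 = np.where(
            rem > 0,
            rem * np.log(np.where(rem > 0, rem, 1) / np.where(rem_mu > 0, rem_mu, np.inf)),
            0.0,
        )
    out = t1 + t2
    out = np.where(np.isfinite(out), out, np.inf)
    # degenerate windows: no expectation and no cases
    out = np.where((mu == 0) & (c == 0), 0.0, out)
    if high_rate_only:
        out = np.where(c > mu, out, 0.0)
    else:
        out = np.maximum(out, 0.0)
    return out if out.shape else float(out)


def rank_p_value(candidate_llr: float, replicate_maxima: np.ndarray) -> float:
    """Monte Carlo rank p-value: the candidate's rank in the pooled set.

    With R replicate maxima, rank = 1 + #{maxima >= candidate} and
    p = rank/(R+1); a candidate ranked 50th among 1,000 statistics has
    p = 50/1000 = .05, and one beating every replicate has p = 1/(R+1).
    """
    rep = np.asarray(replicate_maxima, dtype=float)
    rank = 1 + int(np.sum(rep >= candidate_llr))
    return rank / (len(rep) + 1)


def _interval_index(T: int, max_dur: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All closed month intervals [s, e] with duration <= max_dur."""
    s, e = [], []
    for dur in range(1, min(max_dur, T) + 1):
        for start in range(0, T - dur + 1):
            s.append(start)
            e.append(start + dur - 1)
    s = np.asarray(s)
    e = np.asarray(e)
    return s, e, (e - s + 1)


def _make_max_llr_kernel():
    """Compile the replicate maximum-LLR kernel (loops fused, no temporaries)."""

    def kernel(draws, ord_pad, lens, pop_prefix, s_idx, e_idx, total_pop):
        R, A, T = draws.shape
        n = ord_pad.shape[0]
        nk = s_idx.shape[0]
        out = np.zeros(R)
        for r in range(R):
            Cf = 0.0
            for a in range(A):
                for t in range(T):
                    Cf += draws[r, a, t]
            best = 0.0
            acc = np.zeros(T)
            pref = np.zeros(T + 1)
            for i in range(n):
                L = lens[i]
                for t in range(T):
                    acc[t] = 0.0
                for l in range(L):
                    a = ord_pad[i, l]
                    for t in range(T):
                        acc[t] += draws[r, a, t]
                    for t in range(T):
                        pref[t + 1] = pref[t] + acc[t]
                    base = Cf * pop_prefix[i, l] / (total_pop * T)
                    for k in range(nk):
                        c = pref[e_idx[k] + 1] - pref[s_idx[k]]
                        mu = base * (e_idx[k] - s_idx[k] + 1)
                        if c > mu and mu > 0.0:
                            v = c * np.log(c / mu)
                            if Cf > c:
                                v += (Cf - c) * np.log((Cf - c) / (Cf - mu))
                            if v > best:
                                best = v
            out[r] = best
        return out

    if HAVE_NUMBA:
        return numba.njit(kernel, cache=False, fastmath=False)
    return kernel


_MAX_LLR_KERNEL = None


def _max_llr_kernel():
    global _MAX_LLR_KERNEL
    if _MAX_LLR_KERNEL is None:
        _MAX_LLR_KERNEL = _make_max_llr_kernel()
    return _MAX_LLR_KERNEL


# ---------------------------------------------------------------------------
# the model object


class PoissonScan:
    """Retrospective discrete Poisson space-time scan on one case series.

    Parameters
    ----------
    case_series
        Area x month counts with aligned populations for one level/stratum.
    centroids
        (n_areas, 2) centroid coordinates matching the series' area order.
    params
        Window caps and Monte Carlo settings.
    mode
        ``planar`` (km grid) or ``lonlat`` (degrees, great-circle).
    zone_system
        Optional precomputed ``ZoneSystem`` (reused across rolling epochs).
    """

    def __init__(
        self,
        case_series: CaseSeries,
        centroids: np.ndarray,
        params: ScanParams | None = None,
        mode: str = "planar",
        zone_system: ZoneSystem | None = None,
    ) -> None:
        self.case_series = case_series
        self.params = params or ScanParams()
        self.params.validate()
        self.mode = mode
        self.zone_system = zone_system or ZoneSystem(
            case_series.area_ids, centroids, case_series.populations, self.params, mode
        )

    # -------------------------------------------------------------- core
    def _window_llr(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """LLR over every (center, prefix, interval) window.

        ``counts`` has shape (..., n_areas, T); leading axes (e.g. Monte
        Carlo replicates) broadcast through.  Returns (llr, c, mu) with
        shape (..., n_centers, lmax, n_intervals); masked-out prefixes carry
        LLR -inf.
        """
        zs = self.zone_system
        T = counts.shape[-1]
        C = counts.sum(axis=(-2, -1))
        s_idx, e_idx, durs = _interval_index(T, self.params.max_duration_months)

        # month cumsums per (center, prefix): gather sorted rows then cumsum
        g = counts[..., zs._ord_pad, :]  # (..., n, lmax, T)
        g = np.where(zs._mask[..., None], g, 0)
        pref = np.cumsum(g, axis=-2)  # prefix over sorted areas
        mcum = np.concatenate(
            [np.zeros(pref.shape[:-1] + (1,), dtype=pref.dtype), np.cumsum(pref, axis=-1)],
            axis=-1,
        )
        c = mcum[..., e_idx + 1] - mcum[..., s_idx]  # (..., n, lmax, n_int)

        mu = (
            np.asarray(C)[..., None, None, None]
            * zs._pop_prefix[:, :, None]
            * durs[None, None, :]
            / (zs.total_pop * T)
        )
        ll = llr(c, mu, np.asarray(C)[..., None, None, None].astype(float),
                 self.params.high_rate_only)
        ll = np.where(zs._mask[..., None], ll, -np.inf)
        return ll, c, mu

    def max_llr(self, counts: np.ndarray) -> np.ndarray:
        """Maximum window LLR of one or a batch of count matrices."""
        ll, _, _ = self._window_llr(counts)
        return ll.max(axis=(-3, -2, -1))

    def _candidates(self) -> list[ClusterResult]:
        """Best interval per zone, ranked, non-overlapping secondaries."""
        zs = self.zone_system
        series = self.case_series
        counts = series.counts
        C = series.total_C
        if C == 0:
            return []
        T = series.n_months
        s_idx, e_idx, _ = _interval_index(T, self.params.max_duration_months)
        ll, c, mu = self._window_llr(counts)

        # per (center, prefix) best interval
        best_int = np.argmax(ll, axis=-1)
        ii, jj = np.meshgrid(np.arange(ll.shape[0]), np.arange(ll.shape[1]), indexing="ij")
        best_ll = ll[ii, jj, best_int]
        cands = []
        seen: set[frozenset] = set()
        flat = np.argsort(best_ll, axis=None)[::-1]
        for f in flat:
            i, l = np.unravel_index(f, best_ll.shape)
            if not zs._mask[i, l] or best_ll[i, l] <= 0:
                break
            members = frozenset(zs._orders[i][: l + 1].tolist())
            if members in seen:
                continue
            seen.add(members)
            k = best_int[i, l]
            ids = tuple(str(zs.area_ids[j]) for j in zs._orders[i][: l + 1])
            zone = Zone(
                center_area_id=str(zs.area_ids[i]),
                member_area_ids=ids,
                radius_km=float(zs._radii[i][l]),
                zone_pop=int(zs._pop_prefix[i, l]),
            )
            obs = int(c[i, l, k])
            exp = float(mu[i, l, k])
            rr = _relative_risk(obs, exp, C)
            cands.append(
                ClusterResult(
                    zone=zone,
                    start_month=int(series.months[s_idx[k]]),
                    end_month=int(series.months[e_idx[k]]),
                    observed=obs,
                    expected=exp,
                    llr=float(best_ll[i, l]),
                    relative_risk=rr,
                )
            )

        # greedy non-overlap selection in decreasing LLR
        cands.sort(key=lambda r: (-r.llr, r.zone.center_area_id, r.n_areas,
                                  r.start_month, r.end_month))
        chosen: list[ClusterResult] = []
        used: set = set()
        for cand in cands:
            mem = set(cand.zone.member_area_ids)
            if mem & used:
                continue
            used |= mem
            cand.rank = len(chosen) + 1
            chosen.append(cand)
        return chosen

    def null_replicates(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Conditional null datasets: C cases multinomial over area-months
        with probabilities proportional to the null expectations."""
        series = self.case_series
        A, T = series.counts.shape
        p = np.repeat(series.populations / self.zone_system.total_pop / T, T)
        R = self.params.n_replicates if size is None else size
        return rng.multinomial(series.total_C, p, size=R).reshape(R, A, T)

    def _null_replicate_maxima(self, rng: np.random.Generator) -> np.ndarray:
        """Max LLR of each conditional multinomial null replicate."""
        return self._null_replicate_maxima_from(self.null_replicates(rng))

    def _null_replicate_maxima_from(self, draws: np.ndarray) -> np.ndarray:
        zs = self.zone_system
        T = draws.shape[-1]
        s_idx, e_idx, _ = _interval_index(T, self.params.max_duration_months)
        lens = zs._mask.sum(axis=1).astype(np.int64)
        kernel = _max_llr_kernel()
        return kernel(
            draws.astype(np.float64),
            zs._ord_pad.astype(np.int64),
            lens,
            zs._pop_prefix.astype(np.float64),
            s_idx.astype(np.int64),
            e_idx.astype(np.int64),
            float(zs.total_pop),
        )

    def fit(self, seed: int | None = None) -> "ScanResults":
        """Run the scan and Monte Carlo inference; return ranked clusters."""
        candidates = self._candidates()
        rep_max = np.array([])
        if candidates and self.params.n_replicates >= 1:
            rng = np.random.default_rng(self.params.seed if seed is None else seed)
            rep_max = self._null_replicate_maxima(rng)
            for cand in candidates:
                cand.p_value = rank_p_value(cand.llr, rep_max)
        candidates = [
            c for c in candidates
            if c.p_value is None or c.p_value <= self.params.report_ceiling
        ]
        self._attach_events(candidates)
        return ScanResults(self, candidates, rep_max)

    def _attach_events(self, candidates: list[ClusterResult]) -> None:
        ev = self.case_series.event_ids
        if ev is None or len(ev) == 0:
            return
        for cand in candidates:
            members = set(cand.zone.member_area_ids)
            m = ev["area_id"].isin(members) & ev["month"].between(
                cand.start_month, cand.end_month
            )
            cand.event_ids = frozenset(ev.loc[m, "event_id"])


def _relative_risk(c: int, mu: float, C: int) -> float:
    if mu == 0:
        return math.inf if c > 0 else math.nan
    if C == c:
        return math.inf
    denom = (C - c) / (C - mu)
    return (c / mu) / denom if denom > 0 else math.inf


def monte_carlo(
    case_series: CaseSeries,
    zone_system: ZoneSystem,
    params: ScanParams,
    candidates: list[ClusterResult],
    seed: int | None = None,
) -> list[ClusterResult]:
    """Attach Monte Carlo rank p-values to candidate clusters.

    Each replicate redistributes the grand total C multinomially over
    area-months with probabilities proportional to the null expectations;
    the replicate statistic is that dataset's maximum window LLR, and every
    candidate is ranked against the same null-maximum distribution:
    p = rank/(R+1) with rank = 1 + #{replicate maxima >= candidate LLR}.
    """
    params.validate()
    model = PoissonScan(case_series, centroids=None, params=params,
                        zone_system=zone_system)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rep_max = model._null_replicate_maxima(rng)
    return [replace(c, p_value=rank_p_value(c.llr, rep_max)) for c in candidates]


class ScanResults:
    """Ranked clusters from one scan, with the null-maximum sample."""

    def __init__(
        self,
        model: PoissonScan,
        clusters: list[ClusterResult],
        replicate_maxima: np.ndarray,
    ) -> None:
        self.model = model
        self.clusters = clusters
        self.replicate_maxima = np.asarray(replicate_maxima)

    @property
    def most_likely(self) -> ClusterResult | None:
        return self.clusters[0] if self.clusters else None

    def significant(self, alpha: float | None = None) -> list[ClusterResult]:
        a = self.model.params.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= a]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": c.rank,
                "center": c.zone.center_area_id,
                "n_areas": c.n_areas,
                "radius_km": c.zone.radius_km,
                "start_month": c.start_month,
                "end_month": c.end_month,
                "duration": c.duration,
                "observed": c.observed,
                "expected": c.expected,
                "relative_risk": c.relative_risk,
                "llr": c.llr,
                "p_value": c.p_value,
                "zone_pop": c.zone.zone_pop,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        series = self.model.case_series
        head = (
            f"Discrete Poisson space-time scan "
            f"({series.level}, {series.age_group})\n"
            f"C = {series.total_C} cases over {series.n_months} months, "
            f"{len(series.area_ids)} areas; "
            f"{self.model.params.n_replicates} Monte Carlo replicates\n"
        )
        df = self.summary_frame()
        if df.empty:
            return head + "No elevated-rate clusters found.\n"
        return head + df.to_string(index=False, float_format=lambda v: f"{v:.4g}")
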