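"""Independent brute-force oracles for the scan engine.

Plain-Python re-derivations used only to check the vectorised engine:
exhaustive enumeration of distance-ordered prefix zones and of every
zone x month-interval window, scored with a directly transcribed
two-term Poisson log-likelihood ratio.
"""
from __future__ import annotations

import math


def brute_zones(area_ids, centroids, pops, max_radius_km, max_pop_fraction):
    """All distinct prefix zones as frozensets of area indices."""
    n = len(area_ids)
    total = sum(pops)
    cap = max_pop_fraction * total
    zones = set()
    detail = {}
    for i in range(n):
        d = [math.hypot(centroids[j][0] - centroids[i][0],
                        centroids[j][1] - centroids[i][1]) for j in range(n)]
        order = sorted(range(n), key=lambda j: (d[j], area_ids[j]))
        order = [i] + [j for j in order if j != i]
        cum = 0
        members = []
        for j in order:
            if j != i:
                if d[j] > max_radius_km or cum + pops[j] > cap:
                    break
            cum += pops[j]
            members.append(j)
            key = frozenset(members)
            if key not in zones:
                zones.add(key)
                detail[key] = (i, tuple(members), d[members[-1]], cum)
    return zones, detail


def brute_llr(c, mu, C):
    if c <= mu:
        return 0.0
    if mu == 0:
        return math.inf
    v = c * math.log(c / mu)
    if C > c:
        v += (C - c) * math.log((C - c) / (C - mu))
    return v


def brute_best_cluster(counts, centroids, pops, area_ids,
                       max_radius_km, max_pop_fraction, max_duration):
    """Exhaustive most-likely cluster over all zone x interval windows.

    Returns (members frozenset, (s, e), c, mu, llr) of the maximum, or
    None when no window has positive LLR.
    """
    n, T = len(counts), len(counts[0])
    C = sum(sum(row) for row in counts)
    total_pop = sum(pops)
    zones, detail = brute_zones(area_ids, centroids, pops,
                                max_radius_km, max_pop_fraction)
    best = None
    for key in zones:
        members = detail[key][1]
        zpop = detail[key][3]
        for s in range(T):
            for e in range(s, min(T, s + max_duration)):
                c = sum(counts[a][t] for a in members for t in range(s, e + 1))
                mu = C * zpop * (e - s + 1) / (total_pop * T)
                v = brute_llr(c, mu, C)
                if v > 0 and (best is None or v > best[4]):
                    best = (frozenset(members), (s, e), c, mu, v)
    return best
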