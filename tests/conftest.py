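import numpy as np
import pytest

import scanwatch as sw


@pytest.fixture(scope="session")
def small_geo():
    """64 mesh blocks in 16 SA1s in 4 SA2s, ~8,000 people."""
    spec = sw.GeographySpec(
        n_sa2=4, sa1_per_sa2=4, mb_per_sa1=4, sa2_pop_mean=2000, seed=1
    )
    return sw.make_geography(spec)


@pytest.fixture(scope="session")
def small_events(small_geo):
    spec = sw.BaselineSpec(
        annual_total=60, n_months=36, invalid_coord_fraction=0.02, seed=2
    )
    return sw.make_baseline_events(small_geo, spec)


@pytest.fixture(scope="session")
def small_series(small_geo, small_events):
    kept, _ = sw.filter_events(small_events, small_geo)
    joined, _ = sw.spatial_join(kept, small_geo, "MB")
    series, _ = sw.aggregate_counts(joined, small_geo, "MB", "all", "2015-01", 36)
    return series


def make_series(counts, pops, level="MB", age_group="all", months=None):
    """Hand-built CaseSeries for toy scan instances."""
    counts = np.asarray(counts)
    n, T = counts.shape
    ids = np.array([f"A{k:02d}" for k in range(n)])
    return sw.CaseSeries(
        level=level,
        age_group=age_group,
        area_ids=ids,
        months=np.arange(T) if months is None else np.asarray(months),
        counts=counts,
        populations=np.asarray(pops),
    )
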