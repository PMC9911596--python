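import numpy as np
import pytest

from vtcfret.burst import BinnedTrace, Burst, BurstSearchParams


def naive_burst_scan(total_counts, threshold, min_photons):
    """Independent linear-scan burst-search oracle.

    Walks the per-bin totals once, collecting maximal runs of bins at or
    above the threshold and keeping runs whose sum reaches the minimum
    photon count.  Returns (start, end, total) tuples, inclusive indices.
    """
    bursts = []
    run_start = None
    run_sum = 0
    for i, c in enumerate(list(total_counts) + [-1]):  # sentinel closes last run
        if c >= threshold and c >= 0:
            if run_start is None:
                run_start = i
                run_sum = 0
            run_sum += c
        else:
            if run_start is not None and run_sum >= min_photons:
                bursts.append((run_start, i - 1, run_sum))
            run_start = None
    return bursts


def random_trace(rng, n_bins=200, burst_prob=0.1):
    """A sparse random binned trace with occasional high-count stretches."""
    dd = rng.poisson(1.0, n_bins)
    da = rng.poisson(1.0, n_bins)
    aa = rng.poisson(1.0, n_bins)
    n_spikes = rng.integers(0, 6)
    for _ in range(n_spikes):
        start = rng.integers(0, n_bins - 5)
        width = rng.integers(1, 6)
        dd[start:start + width] += rng.poisson(8, width)
        da[start:start + width] += rng.poisson(8, width)
        aa[start:start + width] += rng.poisson(5, width)
    return BinnedTrace(1.0, dd.astype(np.int64), da.astype(np.int64),
                       aa.astype(np.int64))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cylinder():
    from vtcfret.fixtures import make_cylinder

    return make_cylinder(ring_step=1.0)


@pytest.fixture(scope="session")
def default_search():
    return BurstSearchParams()
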