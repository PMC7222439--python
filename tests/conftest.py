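import numpy as np
import pytest

from atcmap import SimConfig, simulate_cohort
from atcmap.cohort import Cohort
from atcmap.geomapper import log2_transform


def small_config(**over):
    """A reduced cohort: 2 chromosomes, 1 planted region, 60 samples.

    The dosage slope is raised to 1.0 so the r >= 0.6 screen keeps its power
    at this reduced sample size; hub sites are 10 per hub so per-chromosome
    cluster counts stay identifiable with only 2 hubs per chromosome.
    """
    base = dict(
        seed=11,
        n_samples=60,
        n_genes=120,
        genome=[("chr1", 40_000_000), ("chr2", 30_000_000)],
        planted_regions=[("chr1", 8_000_000, 14_000_000, 1.0, 20)],
        planted_hubs=[
            ("chr1", 2_000_000, 4_000_000),
            ("chr1", 20_000_000, 22_000_000),
            ("chr2", 10_000_000, 12_000_000),
            ("chr2", 24_000_000, 26_000_000),
        ],
        sites_per_hub=10,
        n_events_per_sample=10,
    )
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The baseline study conditions (200 samples, 3 planted regions)."""
    return simulate_cohort(SimConfig(seed=0))


def as_cohort(bundle) -> Cohort:
    return Cohort(
        expression=log2_transform(bundle.expression_raw),
        copy_number=bundle.copy_number,
        metadata=bundle.metadata,
    )


def interval_jaccard(a, b) -> float:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, e - s)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def brute_force_wcss(values: np.ndarray, k: int) -> float:
    """Minimal WCSS over *all* contiguous partitions of the sorted vector."""
    from itertools import combinations

    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size

    def ssq(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        cost = sum(ssq(xs[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, cost)
    return best
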