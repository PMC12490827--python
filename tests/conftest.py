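import numpy as np
import pytest

import fpcharter as fp


@pytest.fixture
def two_pattern_spec():
    """200 molecules: 30% TF-bound (20 bp footprint), 70% nucleosome-occupied."""
    region = fp.GenomicInterval("chrSim", 0, 300)
    tf = fp.Pattern("tf_bound", ((121, 140),))
    nuc = fp.Pattern("nucleosome", ((81, 230),))
    return fp.SimSpec(
        region=region,
        patterns=[tf, nuc],
        weights=[0.3, 0.7],
        n_molecules=200,
        flip_noise=0.05,
        seed=42,
        cytosine_positions=list(range(1, 301, 5)),
    )


@pytest.fixture
def separable_matrix():
    """Two noise-free, well-separated occupancy patterns, 10 molecules each."""
    region = fp.GenomicInterval("chrSim", 0, 200)
    spec = fp.SimSpec(
        region=region,
        patterns=[fp.Pattern("open"), fp.Pattern("closed", ((1, 200),))],
        weights=[0.5, 0.5],
        n_molecules=20,
        flip_noise=0.0,
        seed=7,
        cytosine_positions=list(range(1, 201, 10)),
    )
    calls, truth = fp.simulate_calls(spec)
    matrix = fp.read_meth_calls(calls, region)
    return matrix, truth


def brute_force_smooth(positions, values, window_bp):
    """Independent rolling-mean oracle: enumerate in-window neighbours."""
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window_bp / 2.0
    out = np.empty(len(positions))
    for i, p in enumerate(positions):
        mask = np.abs(positions - p) <= half
        out[i] = values[mask].mean()
    return out


def brute_force_pam_cost(dist, k):
    """Minimum PAM cost by exhaustive enumeration of medoid subsets."""
    from itertools import combinations

    n = dist.shape[0]
    return min(
        dist[:, list(meds)].min(axis=1).sum() for meds in combinations(range(n), k)
    )
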