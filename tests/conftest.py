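import math

import numpy as np
import pytest

from sevqc.pipeline import run_qc
from sevqc.simulate import (
    ReadSimConfig,
    build_transcript_pool,
    endogenous_only_spec,
    naive_media_spec,
    simulate_reads,
    synthetic_reference,
)

BASE_SEED = 1


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference(seed=BASE_SEED)


@pytest.fixture(scope="session")
def baseline_sim(reference):
    """2e5 error-free reads, all four factors endogenous only."""
    pool = build_transcript_pool(reference, endogenous_only_spec())
    cfg = ReadSimConfig(
        n_reads=200_000, substitution_error_rate=0.0, seed=BASE_SEED
    )
    reads, truth = simulate_reads(pool, cfg)
    return reads, truth


@pytest.fixture(scope="session")
def naive_sim(reference):
    """2e5 reads under the naive-media condition (exogenous SKM + viral)."""
    pool = build_transcript_pool(reference, naive_media_spec())
    cfg = ReadSimConfig(n_reads=200_000, seed=BASE_SEED + 1)
    reads, truth = simulate_reads(pool, cfg)
    return reads, truth


@pytest.fixture(scope="session")
def baseline_qc(reference, baseline_sim):
    reads, _ = baseline_sim
    return run_qc(reference, {"baseline": reads})


@pytest.fixture(scope="session")
def naive_qc(reference, naive_sim):
    reads, _ = naive_sim
    return run_qc(reference, {"naive": reads})


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle, written from the definition.

    The median is taken in log space (the size-factor procedure medians
    log-ratios), so an even number of qualifying features yields the
    geometric midpoint of the two central ratios.
    """
    n_features, n_samples = counts.shape
    keep = [g for g in range(n_features) if all(counts[g, j] > 0 for j in range(n_samples))]
    factors = []
    for j in range(n_samples):
        ratios = []
        for g in keep:
            geomean = np.prod([counts[g, jj] for jj in range(n_samples)]) ** (1.0 / n_samples)
            ratios.append(counts[g, j] / geomean)
        ratios.sort()
        m = len(ratios)
        if m % 2 == 1:
            med = ratios[m // 2]
        else:
            med = math.sqrt(ratios[m // 2 - 1] * ratios[m // 2])
        factors.append(med)
    return np.array(factors)
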