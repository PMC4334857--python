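import numpy as np
import pytest

from medipseq.peaks import call_peaks
from medipseq.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study (planted effects at fold 4), seed 1."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """Same study conditions with no differential effect (fold 1)."""
    return simulate_dataset(SimulationConfig(seed=3, effect_fold=1.0))


@pytest.fixture(scope="session")
def control_peaks(dataset):
    return call_peaks(dataset.control, dataset.annotation.chrom_sizes)


@pytest.fixture(scope="session")
def case_peaks(dataset):
    return call_peaks(dataset.cases[0], dataset.annotation.chrom_sizes)


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced genome for fast end-to-end pipeline tests."""
    return dict(
        n_chromosomes=1,
        chrom_length_bp=2_000_000,
        n_genes=60,
        n_cgis=40,
        reads_per_sample=60_000,
        n_case_samples=3,
        n_planted_hyper=10,
        n_planted_hypo=10,
    )


def poisson_tail_oracle(k: int, lam: float, tol: float = 1e-18) -> float:
    """Independent partial-sum oracle for P(X >= k), X ~ Poisson(lam).

    Sums e^-lam lam^i / i! upward from i = k until terms are negligible,
    via a stable term recurrence.
    """
    import math

    if k == 0:
        return 1.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > tol * max(total, 1e-300) or i < k + 10:
        total += term
        i += 1
        term *= lam / i
        if i > k + 100000:
            break
    return total


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: sort, p*m/i, cumulative min from top."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
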