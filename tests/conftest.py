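import numpy as np
import pandas as pd
import pytest

from finesgs import GenotypeMatrix, Landscape, SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_dataset():
    """One-patch error-free population: 40 founders + 60 offspring, 200 loci."""
    cfg = SimConfig(
        n_founders=40,
        n_patches=1,
        n_loci=200,
        n_generations=1,
        offspring_per_generation=60,
        genotyping_error=0.0,
        missing_rate=0.0,
        rng_seed=3,
        landscape=Landscape(patch_width=500.0, patch_height=500.0, offsets=((0.0, 0.0),)),
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def three_patch_dataset():
    """Default-style three-patch population with noise and missingness."""
    cfg = SimConfig(
        n_founders=30,
        n_patches=3,
        n_loci=120,
        n_generations=2,
        offspring_per_generation=30,
        genotyping_error=0.005,
        missing_rate=0.03,
        rng_seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture()
def toy_gm():
    """Tiny 5 x 3 genotype matrix with one missing call."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 1],
            [1, -1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix([f"s{i}" for i in range(5)], ["l0", "l1", "l2"], calls)


def brute_force_loiselle(calls):
    """Independent per-locus reference implementation of multilocus kinship.

    Written as a direct transcription of the estimator definition: per
    locus, per allele, sum (p_i - p)(p_j - p)/sum_a p_a(1-p_a) plus the
    1/(n_genes - 1) bias term (n_genes = gene copies sampled), averaged
    across loci with weight sum_a p_a(1-p_a).
    """
    calls = np.asarray(calls)
    n, L = calls.shape
    F = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0.0
            for l in range(L):
                col = calls[:, l]
                m = col != -1
                if col[i] == -1 or col[j] == -1 or m.sum() < 2:
                    continue
                p_alt = col[m].sum() / (2.0 * m.sum())
                if p_alt <= 0 or p_alt >= 1:
                    continue
                w = 0.0
                s = 0.0
                for freq, xi, xj in (
                    (p_alt, col[i] / 2.0, col[j] / 2.0),
                    (1 - p_alt, 1 - col[i] / 2.0, 1 - col[j] / 2.0),
                ):
                    s += (xi - freq) * (xj - freq)
                    w += freq * (1 - freq)
                fij = s / w + 1.0 / (2 * m.sum() - 1)
                num += w * fij
                den += w
            if den > 0:
                F[i, j] = num / den
    return F
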