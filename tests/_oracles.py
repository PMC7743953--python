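"""Independent reference implementations used only to check the package."""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_fraction(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional HWE test p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - hom_rare - h
        weights[h] = Fraction(2**h, factorial(hom_rare) * factorial(h) * factorial(hom_common))
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def mc_order_stat_means(n: int, n_draws: int, rng: np.random.Generator, chunk: int = 100_000):
    """Monte-Carlo E[Z_(j:n)] (ascending) with standard errors, chunked."""
    total = np.zeros(n)
    total_sq = np.zeros(n)
    done = 0
    while done < n_draws:
        take = min(chunk, n_draws - done)
        sample = np.sort(rng.standard_normal((take, n)), axis=1)
        total += sample.sum(axis=0)
        total_sq += (sample**2).sum(axis=0)
        done += take
    mean = total / n_draws
    var = total_sq / n_draws - mean**2
    return mean, np.sqrt(var / n_draws)
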