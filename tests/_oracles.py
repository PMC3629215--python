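"""Independent oracles: brute-force enumeration and forward simulation.

Everything here is deliberately written against different primitives than
the package uses (scipy.linalg.expm on the raw generator, itertools
enumeration, generation-by-generation Wright-Fisher ancestry), so
agreement is a genuine cross-check rather than a reimplementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.linalg import expm


def lineage_pmf_expm(n: int, t: float) -> np.ndarray:
    """P(m founders) via direct matrix exponential of the death generator."""
    rates = np.array([m * (m - 1) / 2.0 for m in range(1, n + 1)])
    Q = np.diag(-rates) + np.diag(rates[1:], k=-1)
    return expm(Q * t)[n - 1]


def lineage_pmf_wright_fisher(
    n: int, N: int, T: int, reps: int, seed: int = 0
) -> np.ndarray:
    """Distribution of distinct ancestors of n lineages after T generations
    of haploid Wright-Fisher reproduction in a population of size N.

    Corresponds to scaled drift time t = T / N.  Returns (pmf, SE) stacked.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n)
    ancestors = np.tile(np.arange(n), (reps, 1))  # (reps, n) ancestor ids
    for _ in range(T):
        parent_of = rng.integers(0, N, size=(reps, N))
        ancestors = np.take_along_axis(parent_of, ancestors, axis=1)
    for row in ancestors:
        counts[len(set(row)) - 1] += 1
    pmf = counts / reps
    se = np.sqrt(pmf * (1 - pmf) / reps)
    return np.vstack([pmf, se])


def drifted_count_prob_enumeration(c: np.ndarray, x: np.ndarray, t: float) -> float:
    """P(counts c | ancestral x, drift t) by exhaustive enumeration (n <= ~6).

    Sums over the founder count m, ordered founder type vectors and
    ordered family-size compositions; family sizes given m founders are
    uniform over the C(n-1, m-1) ordered compositions.
    """
    c = np.asarray(c, dtype=int)
    K = len(c)
    n = int(c.sum())
    pmf = lineage_pmf_expm(n, t)
    total = 0.0
    for m in range(1, n + 1):
        hit = 0.0
        for types in itertools.product(range(K), repeat=m):
            for sizes in _compositions(n, m):
                counts = np.zeros(K, dtype=int)
                for ty, s in zip(types, sizes):
                    counts[ty] += s
                if np.array_equal(counts, c):
                    hit += np.prod([x[ty] for ty in types])
        total += pmf[m - 1] * hit / comb(n - 1, m - 1)
    return total


def _compositions(n: int, m: int):
    """Ordered compositions of n into m positive parts."""
    if m == 1:
        yield (n,)
        return
    for first in range(1, n - m + 2):
        for rest in _compositions(n - first, m - 1):
            yield (first, *rest)


def drifted_counts_forward(
    x: np.ndarray, n: int, t: float, reps: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo sample of drifted haplogroup counts via the urn scheme."""
    rng = np.random.default_rng(seed)
    pmf = lineage_pmf_expm(n, t)
    K = len(x)
    out = np.empty((reps, K), dtype=int)
    for r in range(reps):
        m = rng.choice(n, p=pmf) + 1
        types = list(rng.choice(K, size=m, p=x))
        while len(types) < n:
            types.append(types[rng.integers(0, len(types))])
        out[r] = np.bincount(types, minlength=K)
    return out
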