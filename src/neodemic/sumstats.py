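"""Gene diversity and pairwise F_ST on aligned haploid sequence samples.

F_ST follows the pairwise-difference estimator common in HVS-I ancient-DNA
work: ``F_ST = 1 - H_w / H_b`` where ``H_w`` is the mean within-population
number of pairwise nucleotide differences, averaged over the two samples,
and ``H_b`` the mean between-population pairwise differences.  A haplotype
mode replaces the nucleotide difference with 0/1 haplotype non-identity.
Negative estimates are retained (ABC needs the raw statistic
distribution); the degenerate case ``H_b = 0`` is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neodemic.io import SequencePanel

__all__ = ["SumStats", "gene_diversity", "pairwise_fst", "sumstat_vector"]

#: Fixed order of the three ABC comparisons.
COMPARISONS = (("HG", "farmer"), ("HG", "modern"), ("farmer", "modern"))
STAT_NAMES = ("fst_hg_farmer", "fst_hg_modern", "fst_farmer_modern")


@dataclass
class SumStats:
    """The three pairwise F_ST statistics used for ABC, in fixed order."""

    fst_hg_farmer: float
    fst_hg_modern: float
    fst_farmer_modern: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fst_hg_farmer, self.fst_hg_modern,
                         self.fst_farmer_modern])

    @classmethod
    def from_array(cls, a) -> "SumStats":
        return cls(*map(float, a))


def _as_matrix(sample) -> np.ndarray:
    if isinstance(sample, SequencePanel):
        return sample.seqs
    return np.asarray(sample)


def _haplotype_codes(mat: np.ndarray) -> np.ndarray:
    _, codes = np.unique(mat, axis=0, return_inverse=True)
    return codes


def gene_diversity(sample) -> float:
    """Unbiased gene (haplotype) diversity H_e = n/(n-1) (1 - sum p_i^2)."""
    mat = _as_matrix(sample)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    _, counts = np.unique(_haplotype_codes(mat), return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _mean_pairwise_within(mat: np.ndarray, haplotype: bool) -> float:
    n = mat.shape[0]
    if haplotype:
        codes = _haplotype_codes(mat)
        diff = (codes[:, None] != codes[None, :]).astype(float)
    else:
        diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    iu = np.triu_indices(n, k=1)
    return float(diff[iu].mean())


def _mean_pairwise_between(a: np.ndarray, b: np.ndarray, haplotype: bool) -> float:
    if haplotype:
        both = np.vstack([a, b])
        codes = _haplotype_codes(both)
        ca, cb = codes[: len(a)], codes[len(a):]
        diff = (ca[:, None] != cb[None, :]).astype(float)
    else:
        diff = (a[:, None, :] != b[None, :, :]).sum(axis=2).astype(float)
    return float(diff.mean())


def pairwise_fst(a, b, mode: str = "sequence") -> float:
    """Pairwise F_ST between two samples of aligned sequences.

    ``mode='sequence'`` (default) uses mean pairwise nucleotide
    differences; ``mode='haplotype'`` uses 0/1 haplotype identity.
    """
    if mode not in ("sequence", "haplotype"):
        raise ValueError(f"unknown mode {mode!r}")
    a, b = _as_matrix(a), _as_matrix(b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each sample needs n >= 2")
    if mode == "sequence" and a.shape[1] != b.shape[1]:
        raise ValueError("alignment lengths differ")
    hap = mode == "haplotype"
    hw = 0.5 * (_mean_pairwise_within(a, hap) + _mean_pairwise_within(b, hap))
    hb = _mean_pairwise_between(a, b, hap)
    if hb == 0.0:
        return 0.0  # undifferentiated, degenerate
    return float(1.0 - hw / hb)


def sumstat_vector(panel: SequencePanel, mode: str = "sequence",
                   labels: tuple[str, str, str] = ("HG", "farmer", "modern")) -> SumStats:
    """The three pairwise F_ST values (HG–farmer, HG–modern, farmer–modern)."""
    hg_l, farm_l, mod_l = labels
    groups = {}
    for lab in labels:
        sub = panel.population(lab)
        if sub.n == 0:
            raise ValueError(f"panel lacks population {lab!r}")
        groups[lab] = sub.seqs
    return SumStats(
        fst_hg_farmer=pairwise_fst(groups[hg_l], groups[farm_l], mode),
        fst_hg_modern=pairwise_fst(groups[hg_l], groups[mod_l], mode),
        fst_farmer_modern=pairwise_fst(groups[farm_l], groups[mod_l], mode),
    )
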