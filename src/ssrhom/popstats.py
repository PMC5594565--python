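"""Diversity statistics and homoplasy metrics for haplotype matrices.

Three homoplasy metrics compare the infinite-sites (ISM) and stepwise
(SMM) codings of the same replicate:

* ``P = 1 - F_ISM / F_SMM`` — the classical haplotype-level homoplasy
  index (probability that two haplotypes identical in state are not
  identical by descent).
* ``MSH = 1 - mean_i(F^i_ISM / F^i_SMM)`` — mean size homoplasy, the
  per-locus average of the same ratio.
* ``DH = (pi_ISM - pi_SMM) / pi_ISM`` — distance homoplasy, the
  proportion of true pairwise mutational differences hidden by step
  cancellation.

All three are guaranteed to lie in [0, 1] per replicate: identity-by-descent
classes refine identity-by-state classes (so every SMM homozygosity is at
least the matching ISM one) and the net repeat displacement between two
haplotypes can never exceed the number of steps separating them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist

from .coalsim import PairedHaplotypes

__all__ = [
    "DiversityStats",
    "HomoplasyTriple",
    "SummaryStats",
    "diversity_stats",
    "stats_from_pair",
    "homoplasy_P",
    "mean_size_homoplasy",
    "distance_homoplasy",
    "homoplasy_triple",
    "abc_summaries",
]


class HomoplasyTriple(NamedTuple):
    P: float
    MSH: float
    DH: float


class SummaryStats(NamedTuple):
    """ABC summary statistics of an SMM repeat-count matrix."""

    V: float  # mean across loci of the variance in SSR size
    H: float  # expected heterozygosity averaged across loci
    a: int  # number of distinct haplotypes


@dataclass(frozen=True)
class DiversityStats:
    """Homozygosities and mean pairwise difference for one coding."""

    F_locus: np.ndarray  # per-SSR-locus homozygosity F^i
    F_hap: float  # whole-haplotype homozygosity F
    pi: float  # mean pairwise difference count

    @property
    def H_locus(self) -> np.ndarray:
        return 1.0 - self.F_locus

    @property
    def H_hap(self) -> float:
        return 1.0 - self.F_hap


def _row_homozygosity(rows: np.ndarray, corrected: bool) -> float:
    """Sum of squared frequencies over distinct rows (or scalar values)."""
    n = rows.shape[0]
    if rows.ndim == 1:
        _, counts = np.unique(rows, return_counts=True)
        counts = counts.astype(float)
    else:
        # Exact row-identity counting via byte keys; much faster than a
        # lexicographic row sort for wide 0/1 site matrices.
        rows = np.ascontiguousarray(rows)
        tally: dict[bytes, int] = {}
        for i in range(n):
            key = rows[i].tobytes()
            tally[key] = tally.get(key, 0) + 1
        counts = np.fromiter(tally.values(), dtype=float, count=len(tally))
    p = counts / n
    F = float(np.sum(p * p))
    if corrected:  # unbiased (Nei) estimator, behind a flag
        F = (n * F - 1.0) / (n - 1.0)
    return F


def diversity_stats(
    matrix: np.ndarray,
    coding: str,
    *,
    site_loci: np.ndarray | None = None,
    n_loci: int | None = None,
    corrected: bool = False,
) -> DiversityStats:
    """Compute F^i, F and pi from one haplotype matrix.

    Parameters
    ----------
    matrix
        ``n x L`` integer repeat counts for ``coding='smm'``; ``n x S`` 0/1
        site matrix for ``coding='ism'``.
    coding
        ``'ism'`` or ``'smm'``.
    site_loci
        For the ISM coding, the SSR locus of origin of every site column;
        per-locus homozygosities group the site columns by locus, so the
        "allele" at locus i is the tuple of that locus's site states.
    n_loci
        Number of SSR loci; required for ISM when ``site_loci`` is None
        (only legal for a 0-column matrix).
    corrected
        Apply the small-sample (n/(n-1)) correction to homozygosities.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("matrix must be 2-D with n >= 2 rows")
    n = matrix.shape[0]
    npairs = n * (n - 1) / 2.0

    if coding == "smm":
        L = matrix.shape[1]
        if L < 1:
            raise ValueError("SMM matrix needs at least one locus")
        F_locus = np.array(
            [_row_homozygosity(matrix[:, i], corrected) for i in range(L)]
        )
        pi = float(pdist(matrix, metric="cityblock").mean()) if L else 0.0
    elif coding == "ism":
        S = matrix.shape[1]
        if site_loci is None:
            if S != 0:
                raise ValueError("site_loci is required for a nonempty ISM matrix")
            if n_loci is None:
                raise ValueError("n_loci required when site_loci is None")
            L = n_loci
        else:
            site_loci = np.asarray(site_loci)
            if site_loci.shape != (S,):
                raise ValueError("site_loci must have one entry per ISM column")
            L = n_loci if n_loci is not None else int(site_loci.max(initial=-1)) + 1
            L = max(L, 1)
        F_locus = np.empty(L)
        for i in range(L):
            cols = matrix[:, site_loci == i] if S else matrix[:, :0]
            F_locus[i] = _row_homozygosity(cols, corrected) if cols.shape[1] else 1.0
        counts = matrix.sum(axis=0, dtype=np.int64) if S else np.zeros(0, dtype=np.int64)
        pi = float(np.sum(counts * (n - counts)) / npairs)
    else:
        raise ValueError(f"unknown coding {coding!r}")

    F_hap = _row_homozygosity(matrix if matrix.shape[1] else np.zeros((n, 1)), corrected)
    return DiversityStats(F_locus=F_locus, F_hap=F_hap, pi=pi)


def stats_from_pair(
    pair: PairedHaplotypes, corrected: bool = False
) -> tuple[DiversityStats, DiversityStats]:
    """DiversityStats for both codings of one replicate."""
    ism = diversity_stats(
        pair.ism,
        "ism",
        site_loci=pair.site_locus,
        n_loci=pair.model.L,
        corrected=corrected,
    )
    smm = diversity_stats(pair.smm, "smm", corrected=corrected)
    return ism, smm


def homoplasy_P(ism_stats: DiversityStats, smm_stats: DiversityStats) -> float:
    """Haplotype-level homoplasy index ``1 - F_ISM/F_SMM``."""
    return 1.0 - ism_stats.F_hap / smm_stats.F_hap


def mean_size_homoplasy(ism_stats: DiversityStats, smm_stats: DiversityStats) -> float:
    """Per-locus mean homoplasy ``1 - mean_i(F^i_ISM / F^i_SMM)``."""
    if ism_stats.F_locus.shape != smm_stats.F_locus.shape:
        raise ValueError("locus counts differ between codings")
    return float(1.0 - np.mean(ism_stats.F_locus / smm_stats.F_locus))


def distance_homoplasy(ism_stats: DiversityStats, smm_stats: DiversityStats) -> float:
    """Proportion of pairwise differences hidden by homoplasy.

    Defined as 0 when ``pi_ISM == 0`` (no mutations, no homoplasy).
    """
    if ism_stats.pi == 0.0:
        if smm_stats.pi > 0.0:
            raise AssertionError("pi_SMM > 0 with pi_ISM = 0 violates the step bound")
        return 0.0
    return (ism_stats.pi - smm_stats.pi) / ism_stats.pi


def homoplasy_triple(pair: PairedHaplotypes, corrected: bool = False) -> HomoplasyTriple:
    """P, MSH and DH of one paired replicate."""
    ism, smm = stats_from_pair(pair, corrected=corrected)
    return HomoplasyTriple(
        P=homoplasy_P(ism, smm),
        MSH=mean_size_homoplasy(ism, smm),
        DH=distance_homoplasy(ism, smm),
    )


def abc_summaries(smm_matrix: np.ndarray, ddof: int = 0) -> SummaryStats:
    """Summary statistics (V, H, a) of an SMM repeat-count matrix.

    V is the mean across loci of the per-locus variance of repeat counts
    (population-variance convention by default, ``ddof=1`` for the sample
    variance — use the same convention for observed data and simulations);
    H the mean per-locus expected heterozygosity ``1 - sum(p^2)``; ``a``
    the number of distinct haplotypes.
    """
    m = np.asarray(smm_matrix)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("matrix must be 2-D with n >= 2 rows")
    V = float(np.mean(m.var(axis=0, ddof=ddof)))
    H = float(
        np.mean([1.0 - _row_homozygosity(m[:, i], False) for i in range(m.shape[1])])
    )
    a = int(np.unique(m, axis=0).shape[0])
    return SummaryStats(V=V, H=H, a=a)
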