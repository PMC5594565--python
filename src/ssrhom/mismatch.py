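"""Mismatch-distribution least-squares inference and the TS statistic.

The mismatch distribution is the histogram of pairwise difference counts
among sampled haplotypes.  Under a sudden demographic expansion its
expectation is a Poisson wave riding on geometric equilibrium terms; a
least-squares fit of that expectation to the observed histogram estimates
``(theta0, theta1, tau)``.  This estimator assumes homoplasy-free data
("LSWH"), so fitting both codings of a paired replicate and comparing

    TS = (tau_ISM - tau_SMM) / tau_ISM

measures the relative underestimation of the expansion time caused by
homoplasy.  The SMM pairwise distance is the city-block distance on repeat
counts, which is provably identical to the Hamming distance of the binary
(one-column-per-repeat-unit) recoding used by classical mismatch software.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from scipy.special import gammainc, gammaln

__all__ = [
    "MismatchFit",
    "TSResult",
    "mismatch_histogram",
    "expected_mismatch",
    "fit_lswh",
    "ts_statistic",
    "filter_ts_outliers",
    "tau_to_years",
    "binary_coding",
    "write_arlequin",
]

TS_OUTLIER_THRESHOLD = -10.0


@dataclass(frozen=True)
class MismatchFit:
    """Least-squares mismatch fit of (theta0, theta1, tau)."""

    theta0_hat: float
    theta1_hat: float
    tau_hat: float
    sse: float
    observed: np.ndarray  # integer pair-count histogram
    expected: np.ndarray  # fitted probability vector over the same support
    converged: bool
    degenerate: bool = False  # monomorphic input


@dataclass(frozen=True)
class TSResult:
    """TS for one paired replicate, with the two underlying fits."""

    ts: float
    fit_ism: MismatchFit
    fit_smm: MismatchFit
    replicate: int = 0
    excluded: bool = False


def mismatch_histogram(matrix: np.ndarray, coding: str) -> np.ndarray:
    """Integer histogram of pairwise distances over all n(n-1)/2 pairs.

    ISM: number of differing sites.  SMM: sum over loci of absolute repeat
    differences (equal to the Hamming distance of the binary recoding).
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("matrix must be 2-D with n >= 2 rows")
    if coding not in ("ism", "smm"):
        raise ValueError(f"unknown coding {coding!r}")
    if matrix.shape[1] == 0:
        d = np.zeros(matrix.shape[0] * (matrix.shape[0] - 1) // 2, dtype=np.int64)
    else:
        d = pdist(matrix.astype(np.int64), metric="cityblock").astype(np.int64)
    return np.bincount(d)


def _geometric_equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    """Equilibrium mismatch probabilities theta^j / (1+theta)^(j+1)."""
    if theta <= 0.0:
        out = np.zeros_like(j, dtype=float)
        out[0] = 1.0
        return out
    logp = j * (np.log(theta) - np.log1p(theta)) - np.log1p(theta)
    return np.exp(logp)


def _poisson_pmf(j: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0.0:
        out = np.zeros_like(j, dtype=float)
        out[0] = 1.0
        return out
    return np.exp(j * np.log(lam) - lam - gammaln(j + 1.0))


def expected_mismatch(
    theta0: float,
    theta1: float,
    tau: float,
    j_max: int,
    renormalize: bool = True,
) -> np.ndarray:
    """Expected mismatch probabilities P(j differences), j = 0..j_max.

    Mixture over the pairwise coalescent time of the sudden-expansion
    model: an Exp(1) phase (scaled units) truncated at the epoch
    ``S = tau/theta1`` contributes geometric terms damped by the incomplete
    gamma, and pairs surviving past the epoch accumulate Poisson(tau)
    post-expansion mutations on top of an ancestral geometric(theta0)
    count.  Collapses to the pure equilibrium ``theta^j/(1+theta)^(j+1)``
    at ``tau = 0`` and to Poisson(tau) as ``theta0 -> 0, theta1 -> inf``.
    Tail mass beyond ``j_max`` is renormalized away by default.
    """
    if theta1 <= 0:
        raise ValueError("theta1 must be > 0")
    if theta0 < 0 or tau < 0:
        raise ValueError("theta0 and tau must be >= 0")
    j = np.arange(j_max + 1)
    S = tau / theta1
    # Post-expansion (equilibrium-at-theta1) phase, truncated at the epoch:
    # F_j(theta1) * P(Gamma(j+1) < (1+theta1) S) via the regularized lower
    # incomplete gamma.
    equil = _geometric_equilibrium(theta1, j) * gammainc(j + 1.0, (1.0 + theta1) * S)
    # Atom: Poisson(tau) new mutations convolved with ancestral geometric.
    tail = np.exp(-S) * np.convolve(
        _poisson_pmf(j, tau), _geometric_equilibrium(theta0, j)
    )[: j_max + 1]
    p = equil + tail
    if renormalize:
        tot = p.sum()
        if tot > 0:
            p = p / tot
    return p


def _sse(obs_freq: np.ndarray, theta0: float, theta1: float, tau: float) -> float:
    exp_p = expected_mismatch(theta0, theta1, tau, len(obs_freq) - 1)
    return float(np.sum((obs_freq - exp_p) ** 2))


# Deterministic multi-start scheme: a coarse grid refined by Nelder-Mead
# from the best grid points, ties broken by smallest tau.  The tau grid is
# denser at the low end, where least-squares surfaces develop competing
# local minima (a near-equilibrium fit vs. a recent-expansion fit).
_THETA0_GRID = np.array([0.0, 0.05, 0.1, 0.5, 1.0, 2.0])
_THETA1_GRID = np.geomspace(0.5, 300.0, 12)
_TAU_GRID = np.array(
    [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0, 6.5, 8.0, 10.0,
     12.5, 15.0, 20.0, 25.0, 30.0, 40.0]
)
_N_STARTS = 8


def fit_lswh(
    matrix: np.ndarray | None = None,
    coding: str = "smm",
    *,
    histogram: np.ndarray | None = None,
) -> MismatchFit:
    """Least-squares (homoplasy-blind) mismatch fit of (theta0, theta1, tau).

    Minimizes the sum of squared deviations between the observed relative
    mismatch frequencies and the sudden-expansion expectation.  Fully
    deterministic: fixed coarse grid, local refinement from the best
    ``_N_STARTS`` points, ties broken by smallest tau.  Either a haplotype
    ``matrix`` (with ``coding``) or a precomputed ``histogram`` of pair
    counts may be given.
    """
    if histogram is None:
        if matrix is None:
            raise ValueError("need a matrix or a histogram")
        histogram = mismatch_histogram(matrix, coding)
    hist = np.asarray(histogram, dtype=np.int64)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")

    max_d = int(np.max(np.nonzero(hist)[0])) if hist.any() else 0
    if max_d == 0:
        expected = np.zeros(11)
        expected[0] = 1.0
        return MismatchFit(
            theta0_hat=0.0,
            theta1_hat=_THETA1_GRID[0],
            tau_hat=0.0,
            sse=0.0,
            observed=hist.copy(),
            expected=expected,
            converged=True,
            degenerate=True,
        )

    j_max = max_d + 10
    obs = np.zeros(j_max + 1)
    upto = min(len(hist), j_max + 1)
    obs[:upto] = hist[:upto] / total

    # Coarse deterministic grid search.  The expected distribution is
    # p = equil(theta1, tau) + exp(-tau/theta1) * conv(Pois(tau), geo(theta0)),
    # so the Poisson vector, the theta0 convolutions and the theta1
    # equilibrium terms are shared across grid combinations.
    j = np.arange(j_max + 1, dtype=float)
    geo0 = {th0: _geometric_equilibrium(th0, j) for th0 in _THETA0_GRID}
    cands = []
    for tau in _TAU_GRID:
        pois = _poisson_pmf(j, tau)
        convs = {
            th0: np.convolve(pois, geo0[th0])[: j_max + 1] for th0 in _THETA0_GRID
        }
        for th1 in _THETA1_GRID:
            S = tau / th1
            equil = _geometric_equilibrium(th1, j) * gammainc(j + 1.0, (1.0 + th1) * S)
            damp = np.exp(-S)
            for th0 in _THETA0_GRID:
                p = equil + damp * convs[th0]
                tot = p.sum()
                if tot > 0:
                    p = p / tot
                sse = float(np.sum((obs - p) ** 2))
                cands.append((sse, tau, th0, th1))
    cands.sort(key=lambda c: (c[0], c[1]))

    def objective(x: np.ndarray) -> float:
        th0 = max(x[0], 0.0)
        th1 = np.exp(np.clip(x[1], -14.0, 7.0))  # keep theta1 in a sane range
        tau = max(x[2], 0.0)
        return _sse(obs, th0, th1, tau)

    best = None
    any_converged = False
    for sse0, tau, th0, th1 in cands[:_N_STARTS]:
        res = minimize(
            objective,
            x0=np.array([th0, np.log(th1), tau]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 250},
        )
        any_converged = any_converged or bool(res.success)
        th0_f = max(res.x[0], 0.0)
        th1_f = float(np.exp(np.clip(res.x[1], -14.0, 7.0)))
        tau_f = max(res.x[2], 0.0)
        key = (round(float(res.fun), 12), tau_f)
        if best is None or key < best[0]:
            best = (key, th0_f, th1_f, tau_f, float(res.fun))

    _, th0_f, th1_f, tau_f, sse_f = best
    return MismatchFit(
        theta0_hat=th0_f,
        theta1_hat=th1_f,
        tau_hat=tau_f,
        sse=sse_f,
        observed=hist.copy(),
        expected=expected_mismatch(th0_f, th1_f, tau_f, j_max),
        converged=any_converged,
    )


def ts_statistic(tau_ism: float, tau_smm: float) -> float:
    """Relative underestimation of the expansion time,
    ``(tau_ISM - tau_SMM) / tau_ISM``; undefined for ``tau_ISM = 0``."""
    if tau_ism <= 0.0:
        raise ValueError("TS is undefined when tau_ISM = 0")
    return (tau_ism - tau_smm) / tau_ism


def filter_ts_outliers(
    results: list[TSResult], threshold: float = TS_OUTLIER_THRESHOLD
) -> tuple[list[TSResult], list[TSResult]]:
    """Split TS results into (kept, excluded) by the ``ts < threshold`` rule."""
    kept, excluded = [], []
    for r in results:
        if r.ts < threshold:
            excluded.append(
                TSResult(
                    ts=r.ts,
                    fit_ism=r.fit_ism,
                    fit_smm=r.fit_smm,
                    replicate=r.replicate,
                    excluded=True,
                )
            )
        else:
            kept.append(r)
    return kept, excluded


def tau_to_years(tau: float, L: int, u: float, generation_time: float) -> float:
    """Convert a scaled expansion-time estimate into years.

    ``t = tau / (2 L u)`` generations, times the generation time in years.
    """
    if L < 1 or u <= 0 or generation_time <= 0:
        raise ValueError("need L >= 1, u > 0, generation_time > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau / (2.0 * L * u) * generation_time


def binary_coding(smm_matrix: np.ndarray) -> np.ndarray:
    """Expand repeat counts to the classical 0/1 presence coding.

    At each locus an allele with ``r`` repeats becomes ``r - min`` ones
    padded with zeros to the locus range; pairwise Hamming distances on the
    result equal the city-block distances on the repeat counts.
    """
    m = np.asarray(smm_matrix, dtype=np.int64)
    cols = []
    for i in range(m.shape[1]):
        lo, hi = int(m[:, i].min()), int(m[:, i].max())
        width = hi - lo
        if width == 0:
            continue
        block = (np.arange(width)[None, :] < (m[:, i] - lo)[:, None]).astype(np.uint8)
        cols.append(block)
    if not cols:
        return np.zeros((m.shape[0], 0), dtype=np.uint8)
    return np.hstack(cols)


def write_arlequin(smm_matrix: np.ndarray, path, title: str = "ssrhom export") -> None:
    """Write the binary-coded haplotypes as an Arlequin RFLP project file."""
    binary = binary_coding(smm_matrix)
    n = binary.shape[0]
    lines = [
        "[Profile]",
        f'Title="{title}"',
        "NbSamples=1",
        "DataType=RFLP",
        "GenotypicData=0",
        "[Data]",
        "[[Samples]]",
        'SampleName="pop1"',
        f"SampleSize={n}",
        "SampleData={",
    ]
    for i in range(n):
        hap = "".join(str(int(b)) for b in binary[i])
        lines.append(f"h{i + 1} 1 {hap}")
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
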