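"""Analytic pairwise-approximation expectations under the stepwise expansion.

The expectation of any pairwise diversity statistic is a mixture over the
coalescent time ``T`` of a random pair of haplotypes,

    E[lambda] = sum_x E[lambda | T = x] * P(T = x),

where looking back the pair coalesces at rate ``1/N`` per generation until
the expansion epoch ``t`` and is forced to coalesce exactly at ``t``
otherwise (the ancestral population is treated as vanishingly small).

Conditional moments given ``T`` follow from mutations being Poisson on the
two branches (total rate ``2u`` per locus per generation) and SMM steps
being an equiprobable +/-1 walk, whose net displacement is Skellam
distributed.  With ``m = 2uT`` per locus:

    ISM:  F^i = exp(-m)         F = exp(-L m)          pi = L m
    SMM:  F^i = exp(-m) I0(m)   F = [exp(-m) I0(m)]^L  pi = L m exp(-m) [I0(m)+I1(m)]

(``I_k`` are modified Bessel functions of the first kind; the SMM locus
homozygosity is the Skellam probability of zero net displacement and the
SMM pi is the mean absolute Skellam displacement.)

Because ``m = 2uT = (theta1/L) * (T/N)``, every mixture expectation depends
only on ``(theta1, tau, L)`` once written in the scaled variable
``s = T/N``: the pair-time density is ``e^-s`` on ``[0, tau/theta1)`` plus
an atom of mass ``e^-(tau/theta1)`` at the epoch.  ``expected_stat``
integrates in that scaled variable (Gauss-Legendre plus the atom), which
makes the result exactly independent of the arbitrary ``u`` used for
per-generation discretization; the discrete per-generation pmf of Eq-style
bookkeeping is still available via :func:`coal_time_pmf` and converges to
the same value as ``N`` grows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ive

from .coalsim import ExpansionModel
from .popstats import HomoplasyTriple

__all__ = [
    "CoalTimePMF",
    "ConditionalMoments",
    "coal_time_pmf",
    "conditional_moments",
    "mixture_over_pmf",
    "expected_stat",
    "expected_stats",
    "expected_sample_stats",
    "expected_homoplasy",
    "STAT_NAMES",
]

STAT_NAMES = ("F_ism", "F_smm", "Fi_ism", "Fi_smm", "pi_ism", "pi_smm")

_GAUSS_POINTS = 256
_gl_nodes, _gl_weights = np.polynomial.legendre.leggauss(_GAUSS_POINTS)


@dataclass(frozen=True)
class CoalTimePMF:
    """Discrete per-generation pmf of the pairwise coalescent time.

    ``x`` holds representative times in generations (1..t), ``mass`` the
    probability attached to each, with the forced-coalescence atom at
    ``x = t`` carrying the remainder.  For very large ``t`` the grid is
    strided: each entry then represents a block of generations with its
    exact total mass and mass-weighted mean time.
    """

    x: np.ndarray
    mass: np.ndarray
    N: float
    t: int

    @property
    def atom_mass(self) -> float:
        return float(self.mass[-1])

    def mean(self) -> float:
        return float(np.sum(self.x * self.mass))


def coal_time_pmf(
    theta1: float,
    tau: float,
    L: int,
    u: float,
    max_points: int = 1 << 21,
) -> CoalTimePMF:
    """Pairwise coalescent-time pmf on the per-generation grid.

    ``N = theta1/(2Lu)`` and ``t = tau/(2Lu)`` (rounded to an integer
    generation).  Mass ``(1/N) e^(-x/N)`` sits at each generation
    ``x = 1..t-1``; the remainder is an atom at ``t``.
    """
    if theta1 <= 0 or u <= 0 or L < 1 or tau < 0:
        raise ValueError("need theta1 > 0, u > 0, L >= 1, tau >= 0")
    N = theta1 / (2 * L * u)
    t = int(round(tau / (2 * L * u)))
    if t <= 1:
        # Degenerate: all mass in the atom (t = 0 means immediate coalescence).
        return CoalTimePMF(
            x=np.array([float(max(t, 0))]), mass=np.array([1.0]), N=N, t=max(t, 0)
        )

    m = t - 1  # number of pre-epoch generations
    if m <= max_points:
        x = np.arange(1, t, dtype=float)
        mass = (1.0 / N) * np.exp(-x / N)
    else:
        # Stride into blocks with exact block masses and mass-weighted times.
        edges = np.unique(np.linspace(1, t, max_points + 1).astype(np.int64))
        x_parts, mass_parts = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            xs = np.arange(lo, hi, dtype=float)
            w = (1.0 / N) * np.exp(-xs / N)
            tot = w.sum()
            x_parts.append(np.sum(xs * w) / tot if tot > 0 else xs.mean())
            mass_parts.append(tot)
        x = np.asarray(x_parts)
        mass = np.asarray(mass_parts)

    atom = 1.0 - mass.sum()
    x = np.append(x, float(t))
    mass = np.append(mass, max(atom, 0.0))
    return CoalTimePMF(x=x, mass=mass, N=N, t=t)


@dataclass(frozen=True)
class ConditionalMoments:
    """The six pairwise moments given coalescent time ``T`` (generations)."""

    F_ism: np.ndarray | float  # haplotype homozygosity, ISM
    F_smm: np.ndarray | float
    Fi_ism: np.ndarray | float  # per-locus homozygosity
    Fi_smm: np.ndarray | float
    pi_ism: np.ndarray | float  # expected pairwise differences
    pi_smm: np.ndarray | float

    def get(self, stat: str):
        return getattr(self, stat)


def conditional_moments(T, u: float, L: int) -> ConditionalMoments:
    """Evaluate all six conditional moments at time(s) ``T`` generations.

    Uses exponentially scaled Bessel functions so large ``2uT`` is safe.
    """
    if u <= 0 or L < 1:
        raise ValueError("need u > 0 and L >= 1")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be >= 0")
    m = 2.0 * u * T
    return _moments_from_m(m, L)


def _moments_from_m(m, L: int) -> ConditionalMoments:
    """Moments in terms of the per-locus mutation argument ``m = 2uT``."""
    m = np.asarray(m, dtype=float)
    exp_m = np.exp(-m)
    smm_locus = ive(0, m)  # = exp(-m) * I0(m)
    smm_pi = m * (ive(0, m) + ive(1, m))
    return ConditionalMoments(
        F_ism=exp_m**L,
        F_smm=smm_locus**L,
        Fi_ism=exp_m,
        Fi_smm=smm_locus,
        pi_ism=L * m,
        pi_smm=L * smm_pi,
    )


def mixture_over_pmf(pmf: CoalTimePMF, values: np.ndarray) -> float:
    """Mix per-time conditional values over the discrete pmf."""
    values = np.asarray(values, dtype=float)
    if values.shape != pmf.x.shape:
        raise ValueError("values must align with the pmf grid")
    return float(np.sum(values * pmf.mass))


def _scaled_mixture(model: ExpansionModel):
    """All six expectations via the u-free scaled integral.

    In ``s = T/N`` the density is ``e^-s`` on ``[0, S)`` with an atom
    ``e^-S`` at ``S = tau/theta1``, and ``m(s) = (theta1/L) s``.
    """
    S = model.t_scaled
    rate = model.theta1 / model.L
    if S == 0.0:
        mom = _moments_from_m(0.0, model.L)
        return {name: float(np.asarray(mom.get(name))) for name in STAT_NAMES}
    # Gauss-Legendre on [0, S]
    s = 0.5 * S * (_gl_nodes + 1.0)
    w = 0.5 * S * _gl_weights * np.exp(-s)
    mom = _moments_from_m(rate * s, model.L)
    atom_w = np.exp(-S)
    atom = _moments_from_m(rate * S, model.L)
    out = {}
    for name in STAT_NAMES:
        out[name] = float(
            np.sum(np.asarray(mom.get(name)) * w) + atom_w * float(np.asarray(atom.get(name)))
        )
    return out


def expected_stat(stat: str, model: ExpansionModel) -> float:
    """Expectation of one pairwise diversity statistic under the model.

    ``stat`` is one of ``F_ism, F_smm, Fi_ism, Fi_smm, pi_ism, pi_smm``.
    The result depends only on ``(theta1, tau, L)``; the ancestral
    population is treated as coalescing instantly at the epoch (theta0
    approximately 0), as the analytic approximation assumes.
    """
    if stat not in STAT_NAMES:
        raise ValueError(f"unknown stat {stat!r}; choose from {STAT_NAMES}")
    return _scaled_mixture(model)[stat]


def expected_stats(model: ExpansionModel) -> dict[str, float]:
    """All six expected diversity statistics as a dict."""
    return _scaled_mixture(model)


def expected_sample_stats(model: ExpansionModel, n: int | None = None) -> dict[str, float]:
    """Expected values of the *sample* diversity estimators for ``n`` haplotypes.

    The plain homozygosity estimator ``sum(p_hat^2)`` over an exchangeable
    sample of ``n`` haplotypes has exact expectation
    ``1/n + (1 - 1/n) * F_pair`` where ``F_pair`` is the probability that a
    random pair is identical; the mean pairwise difference is unbiased.
    These are the quantities a simulated replicate mean should be compared
    with (the "dashed line" against the points).
    """
    n = model.n if n is None else n
    if n < 2:
        raise ValueError("n must be >= 2")
    e = _scaled_mixture(model)
    out = dict(e)
    for name in ("F_ism", "F_smm", "Fi_ism", "Fi_smm"):
        out[name] = 1.0 / n + (1.0 - 1.0 / n) * e[name]
    return out


def expected_homoplasy(
    model: ExpansionModel, finite_sample: bool = False
) -> HomoplasyTriple:
    """Expected P, MSH and DH as ratios of expectations.

    ``E[P] = 1 - E[F_ISM]/E[F_SMM]``, ``E[MSH] = 1 - E[F^i_ISM]/E[F^i_SMM]``
    (all loci exchangeable) and ``E[DH] = (E[pi_ISM] - E[pi_SMM])/E[pi_ISM]``,
    with DH defined as 0 at ``tau = 0``.  With ``finite_sample=True`` the
    homozygosity expectations are replaced by the exact ``model.n``-sample
    estimator expectations, which is the curve comparable to metrics
    computed from simulated samples.
    """
    e = expected_sample_stats(model) if finite_sample else _scaled_mixture(model)
    P = 1.0 - e["F_ism"] / e["F_smm"]
    MSH = 1.0 - e["Fi_ism"] / e["Fi_smm"]
    DH = 0.0 if e["pi_ism"] == 0.0 else (e["pi_ism"] - e["pi_smm"]) / e["pi_ism"]
    return HomoplasyTriple(P=P, MSH=MSH, DH=DH)
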