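"""Rejection ABC for (theta0, theta1, tau) and posterior-predictive homoplasy.

Homoplasy itself is unobservable in real SSR data (the homoplasy-free ISM
coding does not exist for an observed sample), but every ABC simulation
carries both codings, so each *accepted* simulation contributes a (P, MSH,
DH) draw: the posterior predictive distribution of homoplasy.  Plain
rejection is used — draw parameters from the priors, simulate, compute the
summaries (V, H, a) on the SMM matrix, and keep the draws closest to the
observed summaries in standardized Euclidean distance.  Point estimates
are marginal KDE modes; intervals are equal-tailed percentiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .coalsim import ExpansionModel, simulate_replicate
from .popstats import HomoplasyTriple, SummaryStats, abc_summaries, homoplasy_triple

__all__ = [
    "Prior",
    "PriorSpec",
    "DEFAULT_PRIORS",
    "ReferenceTable",
    "ABCPosterior",
    "CalibrationReport",
    "build_reference_table",
    "abc_rejection",
    "posterior_mode",
    "posterior_predictive_homoplasy",
    "relative_bias",
    "credible_coverage",
    "parametric_bootstrap_ci",
]

PARAM_NAMES = ("theta0", "theta1", "tau")
METRIC_NAMES = ("P", "MSH", "DH")
DEFAULT_LEVELS = (0.50, 0.75, 0.90)


@dataclass(frozen=True)
class Prior:
    """One marginal prior: uniform or log-uniform on (low, high)."""

    dist: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.dist!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if not self.low < self.high:
            raise ValueError("need low < high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform needs a positive lower bound")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size))


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior over (theta0, theta1, tau).

    With ``expansion_only=True`` (default) the theta0 draw is truncated at
    the theta1 draw, i.e. the model space is restricted to expansions
    (theta0 <= theta1); sampling is then log-uniform on
    [theta0.low, min(theta0.high, theta1_draw)] per draw.
    """

    theta0: Prior
    theta1: Prior
    tau: Prior
    expansion_only: bool = True

    def __post_init__(self) -> None:
        if self.tau.low < 0:
            raise ValueError("tau prior lower bound must be >= 0")
        if self.expansion_only and self.theta0.low >= self.theta1.low:
            raise ValueError(
                "expansion_only coupling needs theta0.low < theta1.low"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """(size, 3) array of draws in (theta0, theta1, tau) order."""
        th1 = self.theta1.sample(rng, size)
        if self.expansion_only:
            hi = np.minimum(self.theta0.high, th1)
            if self.theta0.dist == "loguniform":
                th0 = np.exp(
                    rng.uniform(np.log(self.theta0.low), np.log(hi), size)
                )
            else:
                th0 = rng.uniform(self.theta0.low, hi, size)
        else:
            th0 = self.theta0.sample(rng, size)
        return np.column_stack([th0, th1, self.tau.sample(rng, size)])


#: Wide-but-finite defaults for a chloroplast-SSR dataset of unknown history:
#: expansion models with theta0 log-uniform below the drawn theta1.
DEFAULT_PRIORS = PriorSpec(
    theta0=Prior("loguniform", 1e-5, 300.0),
    theta1=Prior("loguniform", 0.1, 300.0),
    tau=Prior("uniform", 0.0, 30.0),
)


@dataclass(frozen=True)
class ReferenceTable:
    """Precomputed ABC reference table (reusable across observed datasets)."""

    params: np.ndarray  # (n_sims, 3): theta0, theta1, tau
    summaries: np.ndarray  # (n_sims, 3): V, H, a
    homoplasy: np.ndarray  # (n_sims, 3): P, MSH, DH
    n: int
    L: int
    priors: PriorSpec
    seed: int

    @property
    def n_sims(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class ABCPosterior:
    """Accepted draws, point estimates and equal-tailed credible intervals."""

    params: np.ndarray  # accepted (theta0, theta1, tau)
    homoplasy: np.ndarray  # accepted (P, MSH, DH): the posterior predictive
    tolerance: float  # distance of the last accepted simulation
    modes: dict[str, float]
    intervals: dict[str, dict[float, tuple[float, float]]]
    accept_fraction: float

    @property
    def n_accepted(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class CalibrationReport:
    """Relative bias and credible-interval coverage over many datasets."""

    relative_bias: dict[str, float]
    coverage: dict[str, dict[float, float]]
    estimates: dict[str, np.ndarray]
    truths: dict[str, np.ndarray]


def build_reference_table(
    priors: PriorSpec,
    n_sims: int,
    n: int,
    L: int,
    seed: int,
    keep_homoplasy: bool = True,
) -> ReferenceTable:
    """Simulate the ABC reference table: parameters, summaries, homoplasy.

    One paired replicate per prior draw; summaries (V, H, a) come from the
    SMM matrix (what real data would show) and the homoplasy triple from
    both codings (what real data cannot show).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_sims + 1)
    rng = np.random.default_rng(children[0])
    params = priors.sample(rng, n_sims)
    summaries = np.empty((n_sims, 3))
    homo = np.empty((n_sims, 3)) if keep_homoplasy else np.zeros((0, 3))
    for i, child in enumerate(children[1:]):
        th0, th1, tau = params[i]
        model = ExpansionModel(theta0=th0, theta1=th1, tau=tau, L=L, n=n)
        pair = simulate_replicate(model, np.random.default_rng(child))
        summaries[i] = abc_summaries(pair.smm)
        if keep_homoplasy:
            homo[i] = homoplasy_triple(pair)
    return ReferenceTable(
        params=params, summaries=summaries, homoplasy=homo, n=n, L=L, priors=priors, seed=seed
    )


def _equal_tailed(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return (
        float(np.percentile(draws, 100 * lo)),
        float(np.percentile(draws, 100 * (1.0 - lo))),
    )


def abc_rejection(
    observed: SummaryStats | np.ndarray,
    priors: PriorSpec | None = None,
    n_sims: int = 100_000,
    accept_fraction: float = 0.005,
    n: int | None = None,
    L: int | None = None,
    seed: int = 0,
    table: ReferenceTable | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> ABCPosterior:
    """Plain rejection ABC against a (possibly shared) reference table.

    Accepts the ``accept_fraction`` of simulations closest to ``observed``
    in Euclidean distance after dividing each summary by its standard
    deviation across the table; a summary with zero spread is dropped with
    a warning.  Deterministic given ``seed`` (table construction is the
    only stochastic step).
    """
    if not 0.0 < accept_fraction <= 1.0:
        raise ValueError("accept_fraction must be in (0, 1]")
    if table is None:
        if priors is None:
            priors = DEFAULT_PRIORS
        if n is None or L is None:
            raise ValueError("n and L are required when no table is given")
        if n_sims < 1000:
            raise ValueError("n_sims must be >= 1000")
        table = build_reference_table(priors, n_sims, n, L, seed)

    obs = np.asarray(observed, dtype=float)
    sd = table.summaries.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            "summary statistic(s) with zero spread dropped from the ABC distance",
            RuntimeWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all summaries have zero spread across the table")
    z = (table.summaries[:, keep] - obs[keep]) / sd[keep]
    dist = np.sqrt(np.sum(z * z, axis=1))

    n_accept = max(1, int(round(accept_fraction * table.n_sims)))
    order = np.argsort(dist, kind="stable")[:n_accept]
    acc_params = table.params[order]
    acc_homo = table.homoplasy[order] if table.homoplasy.size else np.zeros((0, 3))

    modes: dict[str, float] = {}
    intervals: dict[str, dict[float, tuple[float, float]]] = {}
    for k, name in enumerate(PARAM_NAMES):
        modes[name] = posterior_mode(acc_params[:, k])
        intervals[name] = {lv: _equal_tailed(acc_params[:, k], lv) for lv in levels}
    if acc_homo.size:
        for k, name in enumerate(METRIC_NAMES):
            modes[name] = posterior_mode(acc_homo[:, k])
            intervals[name] = {lv: _equal_tailed(acc_homo[:, k], lv) for lv in levels}

    return ABCPosterior(
        params=acc_params,
        homoplasy=acc_homo,
        tolerance=float(dist[order[-1]]),
        modes=modes,
        intervals=intervals,
        accept_fraction=accept_fraction,
    )


def posterior_mode(draws: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 512-point grid.

    Deterministic; identical draws (zero variance) return that value.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size == 0:
        raise ValueError("draws must be a nonempty 1-D sample")
    lo, hi = float(draws.min()), float(draws.max())
    if lo == hi:
        return lo
    kde = gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def posterior_predictive_homoplasy(post: ABCPosterior) -> HomoplasyTriple:
    """Marginal modes of the accepted simulations' (P, MSH, DH) draws."""
    if not post.homoplasy.size:
        raise ValueError("posterior carries no homoplasy draws")
    return HomoplasyTriple(
        P=posterior_mode(post.homoplasy[:, 0]),
        MSH=posterior_mode(post.homoplasy[:, 1]),
        DH=posterior_mode(post.homoplasy[:, 2]),
    )


def relative_bias(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Mean over datasets of (estimate - truth) / truth (zero truths dropped)."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must align")
    ok = tru != 0
    if not ok.all():
        warnings.warn("zero truths excluded from relative bias", RuntimeWarning, stacklevel=2)
    if not ok.any():
        raise ValueError("all truths are zero")
    return float(np.mean((est[ok] - tru[ok]) / tru[ok]))


def credible_coverage(
    posteriors: list[ABCPosterior],
    truths: dict[str, np.ndarray],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> CalibrationReport:
    """Coverage of equal-tailed intervals and relative bias of the modes.

    ``truths`` maps quantity names (any of theta0/theta1/tau/P/MSH/DH) to a
    per-dataset array of true values.
    """
    if len(posteriors) < 1:
        raise ValueError("need at least one posterior")
    coverage: dict[str, dict[float, float]] = {}
    bias: dict[str, float] = {}
    estimates: dict[str, np.ndarray] = {}
    for name, truth in truths.items():
        truth = np.asarray(truth, dtype=float)
        if truth.shape != (len(posteriors),):
            raise ValueError(f"truths[{name!r}] must have one value per dataset")
        est = np.array([p.modes[name] for p in posteriors])
        estimates[name] = est
        coverage[name] = {}
        for lv in levels:
            inside = [
                lo <= t <= hi
                for t, (lo, hi) in zip(truth, (p.intervals[name][lv] for p in posteriors))
            ]
            coverage[name][lv] = float(np.mean(inside))
        if np.all(truth != 0):
            bias[name] = relative_bias(est, truth)
    return CalibrationReport(
        relative_bias=bias, coverage=coverage, estimates=estimates, truths=truths
    )


def parametric_bootstrap_ci(
    estimator,
    fitted: ExpansionModel,
    B: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile parametric-bootstrap confidence interval.

    Simulates ``B`` paired datasets at the fitted parameters, applies
    ``estimator(pair) -> float`` to each, and returns
    ``(low, high, failure_fraction)`` where low/high are the alpha/2 and
    1-alpha/2 empirical percentiles (linear interpolation).  Estimator
    failures (exceptions or NaN) are dropped and counted.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    ss = np.random.SeedSequence(seed)
    values = []
    failures = 0
    for child in ss.spawn(B):
        pair = simulate_replicate(fitted, np.random.default_rng(child))
        try:
            v = float(estimator(pair))
        except Exception:
            failures += 1
            continue
        if np.isnan(v):
            failures += 1
            continue
        values.append(v)
    if not values:
        raise RuntimeError("estimator failed on every bootstrap replicate")
    values = np.asarray(values)
    lo = float(np.percentile(values, 100 * alpha / 2.0))
    hi = float(np.percentile(values, 100 * (1.0 - alpha / 2.0)))
    return lo, hi, failures / B
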