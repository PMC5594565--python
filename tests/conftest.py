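import numpy as np
import pytest
from hypothesis import settings

import ssrhom as s
from ssrhom import abc as abcmod
from ssrhom.io_cli import run_ts_experiment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

TAU_GRID = [1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0, 13.5, 15.0]


@pytest.fixture(scope="session")
def mixed_replicates():
    """A bag of replicates across assorted models, for property checks."""
    out = []
    rng_seeds = iter(range(100, 10_000))
    for theta1 in (2.0, 30.0, 80.0):
        for tau in (0.5, 6.0, 15.0):
            model = s.ExpansionModel(
                theta0=theta1 / 1000, theta1=theta1, tau=tau, L=4, n=40
            )
            out.extend(s.simulate_paired_dataset(model, 12, next(rng_seeds)))
    return out


@pytest.fixture(scope="session")
def plateau_grid_sims():
    """100 replicates of the (theta1=30, theta0=0.03, n=150, L=6) design at
    each expansion time on the standard tau grid."""
    sims = {}
    for ti, tau in enumerate(TAU_GRID):
        model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=tau, L=6, n=150)
        sims[tau] = s.simulate_paired_dataset(model, 100, 31_000 + ti)
    return sims


@pytest.fixture(scope="session")
def ts_scaled_experiment():
    """Scaled TS experiment: 30 replicates per tau over the standard grid,
    LSWH fits on both codings of every replicate."""
    frame, corr = run_ts_experiment(
        theta0=0.03,
        theta1=30.0,
        taus=TAU_GRID,
        loci=6,
        n=150,
        reps_per_tau=30,
        seed=20_170_911,
    )
    return frame, corr


@pytest.fixture(scope="session")
def abc_table():
    """Shared ABC reference table for the calibration experiments."""
    return abcmod.build_reference_table(
        abcmod.DEFAULT_PRIORS, 30_000, n=150, L=6, seed=424_242
    )


@pytest.fixture(scope="session")
def abc_calibration(abc_table):
    """100 pseudo-observed datasets (10 per tau) analysed against the shared
    table; returns truths, estimates and the full posteriors."""
    posts, truths = [], {"tau": [], "P": [], "MSH": [], "DH": []}
    accept_fraction = 500 / abc_table.n_sims
    for ti, tau in enumerate(TAU_GRID):
        model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=tau, L=6, n=150)
        for pair in s.simulate_paired_dataset(model, 10, 77_000 + ti):
            trip = s.homoplasy_triple(pair)
            post = abcmod.abc_rejection(
                s.abc_summaries(pair.smm),
                table=abc_table,
                accept_fraction=accept_fraction,
            )
            posts.append(post)
            truths["tau"].append(tau)
            truths["P"].append(trip.P)
            truths["MSH"].append(trip.MSH)
            truths["DH"].append(trip.DH)
    truths = {k: np.asarray(v) for k, v in truths.items()}
    estimates = {
        name: np.array([p.modes[name] for p in posts]) for name in ("P", "MSH", "DH")
    }
    return posts, truths, estimates
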