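"""Structural, distributional and bookkeeping checks for the simulator."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import chisquare

import ssrhom as s
from ssrhom.coalsim import MutationEvent, MutationSet


def pair_tmrca(gen, a, b):
    """Coalescent time of leaves a and b by walking to their MRCA."""
    anc_a = set()
    v = a
    while v != -1:
        anc_a.add(v)
        v = gen.parent[v]
    v = b
    while v not in anc_a:
        v = gen.parent[v]
    return gen.time[v]


def two_leaf_genealogy(tmrca=1.0):
    return s.Genealogy(
        n=2, parent=np.array([2, 2, -1]), time=np.array([0.0, 0.0, tmrca])
    )


@pytest.mark.parametrize(
    "model",
    [
        s.ExpansionModel(theta0=0.03, theta1=30.0, tau=6.0, L=6, n=25),
        s.ExpansionModel(theta0=0.0, theta1=10.0, tau=2.0, L=3, n=12),
        s.ExpansionModel(theta0=5.0, theta1=5.0, tau=0.0, L=2, n=8),
    ],
)
def test_genealogy_is_valid_binary_ultrametric(model):
    for seed in (0, 1, 2):
        gen = s.simulate_genealogy(model, seed)
        assert gen.num_nodes == 2 * model.n - 1
        gen.validate()  # single root, leaves at 0, nonneg branch lengths


def test_constant_size_pairwise_tmrca_mean_is_one():
    """n=2, no expansion in sight: mean TMRCA is 1 N1-generation unit."""
    model = s.ExpansionModel(theta0=30.0, theta1=30.0, tau=1e12, L=1, n=2)
    t = [s.simulate_genealogy(model, seed).tmrca() for seed in range(4000)]
    # Exp(1) has sd 1 -> SE = 1/sqrt(4000)
    assert abs(np.mean(t) - 1.0) < 3 / np.sqrt(4000)


def test_fraction_of_pairs_surviving_to_the_epoch():
    """P(pair TMRCA >= epoch) = exp(-epoch) for epoch = tau/theta1 = 0.5."""
    model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=15.0, L=6, n=150)
    rng = np.random.default_rng(7)
    hits = []
    for _ in range(1500):
        gen = s.simulate_genealogy(model, rng)
        hits.append(pair_tmrca(gen, 0, 1) >= model.t_scaled)
    p = np.mean(hits)
    expected = np.exp(-0.5)
    se = np.sqrt(expected * (1 - expected) / 1500)
    assert abs(p - expected) < 4 * se


def test_instant_coalescence_when_theta0_is_zero():
    model = s.ExpansionModel(theta0=0.0, theta1=30.0, tau=6.0, L=6, n=60)
    gen = s.simulate_genealogy(model, 3)
    gen.validate()
    assert gen.tmrca() <= model.t_scaled + 1e-12


def test_mutation_count_matches_branch_length_times_rate():
    model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=6.0, L=6, n=40)
    gen = s.simulate_genealogy(model, 11)
    B = gen.total_branch_length()
    rng = np.random.default_rng(12)
    counts = [len(s.place_mutations(gen, model, rng)) for _ in range(600)]
    mean_expected = B * model.theta1 / 2
    se = np.sqrt(mean_expected / 600)  # Poisson
    assert abs(np.mean(counts) - mean_expected) < 4 * se


def test_locus_assignment_uniform_and_signs_symmetric():
    model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=6.0, L=6, n=40)
    gen = s.simulate_genealogy(model, 21)
    rng = np.random.default_rng(22)
    loci, signs = [], []
    while len(loci) < 10_000:
        ev = s.place_mutations(gen, model, rng)
        loci.extend(ev.locus)
        signs.extend(ev.sign)
    loci = np.asarray(loci[:10_000])
    signs = np.asarray(signs[:10_000])
    counts = np.bincount(loci, minlength=model.L)
    assert chisquare(counts).pvalue > 0.01
    assert set(np.unique(signs)) <= {-1, 1}
    assert abs(signs.mean()) < 4 / np.sqrt(len(signs))  # mean 0, sd 1


def test_single_event_bookkeeping():
    """One +/-1 event at a known branch flips exactly the carrier leaves."""
    gen = two_leaf_genealogy()
    model = s.ExpansionModel(theta0=0.03, theta1=1.0, tau=1.0, L=3, n=2)
    events = MutationSet.from_events([MutationEvent(branch=0, locus=2, sign=1, ordinal=0)])
    pair = s.realize_haplotypes(gen, events, model)
    assert pair.ism.tolist() == [[1], [0]]
    expected = np.full((2, 3), s.coalsim.SMM_BASELINE)
    expected[0, 2] += 1
    assert np.array_equal(pair.smm, expected)


def test_opposite_steps_cancel_only_in_smm():
    """A +1 and a -1 on the path between the two leaves at one locus: the
    canonical homoplasy event (ISM distance 2, SMM distance 0)."""
    gen = two_leaf_genealogy()
    model = s.ExpansionModel(theta0=0.03, theta1=1.0, tau=1.0, L=1, n=2)
    events = MutationSet.from_events(
        [
            MutationEvent(branch=0, locus=0, sign=1, ordinal=0),
            MutationEvent(branch=1, locus=0, sign=1, ordinal=1),
        ]
    )
    pair = s.realize_haplotypes(gen, events, model)
    assert int(np.abs(pair.ism[0].astype(int) - pair.ism[1].astype(int)).sum()) == 2
    assert int(np.abs(pair.smm[0] - pair.smm[1]).sum()) == 0


def test_zero_events_gives_monomorphic_matrices():
    gen = two_leaf_genealogy()
    model = s.ExpansionModel(theta0=0.03, theta1=1.0, tau=1.0, L=2, n=2)
    pair = s.realize_haplotypes(gen, MutationSet.from_events([]), model)
    assert pair.ism.shape == (2, 0)
    assert np.all(pair.smm == s.coalsim.SMM_BASELINE)


def test_event_on_nonexistent_branch_fails():
    gen = two_leaf_genealogy()
    model = s.ExpansionModel(theta0=0.03, theta1=1.0, tau=1.0, L=2, n=2)
    bad = MutationSet.from_events([MutationEvent(branch=99, locus=0, sign=1, ordinal=0)])
    with pytest.raises(ValueError, match="nonexistent branch"):
        s.realize_haplotypes(gen, bad, model)


def test_step_cancellation_bound_holds_per_pair(mixed_replicates):
    """ISM Hamming distance >= SMM city-block distance for every pair."""
    for pair in mixed_replicates[::4]:
        d_ism = pdist(pair.ism.astype(np.int64), metric="cityblock")
        d_smm = pdist(pair.smm, metric="cityblock")
        assert np.all(d_ism >= d_smm)


def test_segregating_sites_increase_with_tau():
    means = []
    for ti, tau in enumerate([1.5, 4.5, 7.5, 10.5, 15.0]):
        model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=tau, L=6, n=50)
        pairs = s.simulate_paired_dataset(model, 100, 900 + ti)
        means.append(np.mean([p.num_sites for p in pairs]))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_dataset_determinism_and_shape():
    model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=6.0, L=6, n=20)
    a = s.simulate_paired_dataset(model, 5, 123)
    b = s.simulate_paired_dataset(model, 5, 123)
    assert len(a) == 5
    for x, y in zip(a, b):
        assert np.array_equal(x.ism, y.ism)
        assert np.array_equal(x.smm, y.smm)
        assert np.array_equal(x.site_locus, y.site_locus)
    assert len(s.simulate_paired_dataset(model, 1, 0)) == 1
    c = s.simulate_paired_dataset(model, 5, 124)
    assert not all(np.array_equal(x.ism, y.ism) for x, y in zip(a, c))


def test_mutationset_sequence_protocol():
    ev = MutationSet.from_events(
        [MutationEvent(0, 1, 1, 0), MutationEvent(2, 0, -1, 1)]
    )
    assert len(ev) == 2
    assert ev[1] == MutationEvent(2, 0, -1, 1)
    assert [e.locus for e in ev] == [1, 0]


def test_model_invariants_enforced():
    with pytest.raises(ValueError):
        s.ExpansionModel(theta0=-1.0, theta1=30.0, tau=6.0)
    with pytest.raises(ValueError):
        s.ExpansionModel(theta0=0.0, theta1=0.0, tau=6.0)
    with pytest.raises(ValueError):
        s.ExpansionModel(theta0=0.0, theta1=30.0, tau=6.0, n=1)
    m = s.ExpansionModel(
        theta0=0.03, theta1=30.0, tau=6.0, L=6, u=5.5e-5, generation_time_years=42.5
    )
    assert m.N1 == pytest.approx(30.0 / (2 * 6 * 5.5e-5))
    assert m.t_generations == pytest.approx(6.0 / (2 * 6 * 5.5e-5))


def test_pairwise_tmrca_distribution_matches_msprime():
    """Independent oracle: msprime with the same two-epoch demography."""
    msprime = pytest.importorskip("msprime")
    model = s.ExpansionModel(theta0=0.3, theta1=30.0, tau=9.0, L=6, n=2)
    epoch = model.t_scaled
    demography = msprime.Demography()
    demography.add_population(initial_size=1.0)
    demography.add_population_parameters_change(
        time=epoch, initial_size=model.theta0 / model.theta1
    )
    ts_reps = msprime.sim_ancestry(
        samples=2,  # two haploid lineages; time unit = N1 generations
        demography=demography,
        ploidy=1,
        num_replicates=3000,
        random_seed=42,
    )
    oracle = np.array([t.first().time(t.first().root) for t in ts_reps])
    ours = np.array(
        [s.simulate_genealogy(model, seed).tmrca() for seed in range(3000)]
    )
    assert abs(ours.mean() - oracle.mean()) < 4 * oracle.std() / np.sqrt(1500)
    assert abs(np.median(ours) - np.median(oracle)) < 0.1
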