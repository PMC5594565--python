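"""Coalescent simulation of linked SSR haplotypes under a stepwise expansion.

The demographic model is a haploid population (chloroplast genomes are
effectively haploid and non-recombining) that grew instantaneously from
effective size ``N0`` to ``N1``, ``t`` generations ago.  It is parameterized
by three scaled quantities,

    theta0 = 2*L*N0*u,   theta1 = 2*L*N1*u,   tau = 2*L*t*u,

where ``u`` is the per-locus per-generation mutation rate and ``L`` the
number of completely linked SSR loci.  Internally time is measured in units
of ``N1`` generations: the coalescence rate for ``k`` lineages is
``k*(k-1)/2`` until the expansion epoch at ``tau/theta1`` looking back, and
is multiplied by ``theta1/theta0`` beyond it.  The total mutation rate per
lineage per time unit is ``L*u*N1 = theta1/2``, so every simulated quantity
depends only on ``(theta0, theta1, tau, L, n)``.

Each genealogy is mutated once and the same events are coded twice:

* **ISM** — infinite sites: every event is a new 0/1 column, carried by the
  leaves below the branch it fell on.  No homoplasy is possible.
* **SMM** — stepwise mutation: each event moves the repeat count of its
  locus by +1 or -1 (equiprobable); steps on the path between two samples
  can cancel, which is exactly the homoplasy the metrics quantify.

Because both codings share one set of events, the per-replicate homoplasy
metrics P, MSH and DH are exactly computable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SMM_BASELINE",
    "ExpansionModel",
    "Genealogy",
    "MutationEvent",
    "MutationSet",
    "PairedHaplotypes",
    "simulate_genealogy",
    "place_mutations",
    "realize_haplotypes",
    "simulate_paired_dataset",
]

#: Ancestral repeat count for the SMM coding.  Arbitrary large constant so
#: repeat counts stay positive in practice; negative counts are permitted
#: mathematically (a warning is emitted) because truncation would break the
#: symmetry of the stepwise model.
SMM_BASELINE = 50


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ExpansionModel:
    """Stepwise demographic expansion parameterization.

    Parameters
    ----------
    theta0, theta1, tau
        Scaled ancestral diversity ``2*L*N0*u``, current diversity
        ``2*L*N1*u`` and expansion time ``2*L*t*u``.
    L
        Number of completely linked SSR loci.
    n
        Sample size (number of haplotypes).
    u
        Optional absolute per-locus per-generation mutation rate; only
        needed to convert scaled quantities into generations/years.
    generation_time_years
        Optional years per generation, for time conversions.
    """

    theta0: float
    theta1: float
    tau: float
    L: int = 1
    n: int = 2
    u: float | None = None
    generation_time_years: float | None = None

    def __post_init__(self) -> None:
        if self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")
        if self.theta1 <= 0:
            raise ValueError("theta1 must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.u is not None:
            if not (self.u > 0 and np.isfinite(self.u)):
                raise ValueError("u must be positive and finite")
            if not (np.isfinite(self.N1) and self.N1 > 0):
                raise ValueError("derived N1 must be positive and finite")

    @property
    def t_scaled(self) -> float:
        """Expansion epoch looking back, in units of N1 generations."""
        return self.tau / self.theta1

    @property
    def N1(self) -> float:
        if self.u is None:
            raise ValueError("u is not set")
        return self.theta1 / (2 * self.L * self.u)

    @property
    def N0(self) -> float:
        if self.u is None:
            raise ValueError("u is not set")
        return self.theta0 / (2 * self.L * self.u)

    @property
    def t_generations(self) -> float:
        if self.u is None:
            raise ValueError("u is not set")
        return self.tau / (2 * self.L * self.u)


@dataclass(frozen=True)
class Genealogy:
    """A binary coalescent tree over ``n`` leaves.

    Nodes ``0..n-1`` are the leaves (time 0); internal nodes are numbered in
    order of creation, so every parent id exceeds its children's ids and the
    root is node ``2n-2``.  Times are in units of N1 generations.
    """

    n: int
    parent: np.ndarray  # (2n-1,) int; root has parent -1
    time: np.ndarray  # (2n-1,) float

    @property
    def num_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.num_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.num_nodes)
        nonroot = np.arange(self.num_nodes - 1)
        bl[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_masks(self) -> np.ndarray:
        """Boolean (num_nodes, n) matrix: leaves descending from each node."""
        masks = np.zeros((self.num_nodes, self.n), dtype=bool)
        idx = np.arange(self.n)
        masks[idx, idx] = True
        parent = self.parent
        for c in range(self.num_nodes - 1):  # parents always have larger ids
            masks[parent[c]] |= masks[c]
        return masks

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def validate(self) -> None:
        if self.parent.shape != (self.num_nodes,) or self.time.shape != (self.num_nodes,):
            raise ValueError("inconsistent node table")
        if np.count_nonzero(self.parent == -1) != 1 or self.parent[self.root] != -1:
            raise ValueError("genealogy must have a single root, last node")
        if np.any(self.time[: self.n] != 0):
            raise ValueError("leaves must sit at time 0 (ultrametric)")
        if np.any(self.branch_lengths() < 0):
            raise ValueError("negative branch length")


class MutationEvent(NamedTuple):
    """One mutation: a branch, a locus, a +/-1 repeat step and a unique id."""

    branch: int
    locus: int
    sign: int
    ordinal: int


@dataclass(frozen=True)
class MutationSet(Sequence):
    """Column-oriented container of mutation events (sequence of MutationEvent)."""

    branch: np.ndarray
    locus: np.ndarray
    sign: np.ndarray

    def __len__(self) -> int:
        return len(self.branch)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return MutationEvent(int(self.branch[i]), int(self.locus[i]), int(self.sign[i]), i)

    def __iter__(self) -> Iterator[MutationEvent]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_events(cls, events: Sequence[MutationEvent]) -> "MutationSet":
        return cls(
            branch=np.asarray([e.branch for e in events], dtype=np.int64),
            locus=np.asarray([e.locus for e in events], dtype=np.int64),
            sign=np.asarray([e.sign for e in events], dtype=np.int64),
        )


@dataclass(frozen=True)
class PairedHaplotypes:
    """One replicate: ISM and SMM codings of the same mutated genealogy.

    ``ism`` is an ``n x S`` 0/1 matrix (one column per mutation event),
    ``smm`` an ``n x L`` integer repeat-count matrix, and ``site_locus``
    maps each ISM column to the SSR locus its event occurred at.
    """

    ism: np.ndarray
    smm: np.ndarray
    site_locus: np.ndarray
    model: ExpansionModel
    seed: object = None

    @property
    def n(self) -> int:
        return self.smm.shape[0]

    @property
    def num_sites(self) -> int:
        return self.ism.shape[1]


def simulate_genealogy(model: ExpansionModel, seed) -> Genealogy:
    """Draw one genealogy under the stepwise expansion model.

    The coalescence rate for ``k`` lineages is ``k(k-1)/2`` per N1-generation
    unit up to the expansion epoch ``tau/theta1`` looking back, then
    ``k(k-1)/2 * theta1/theta0``.  With ``theta0 == 0`` all surviving
    lineages merge instantly at the epoch (zero-length internal branches),
    matching the analytic approximation that all remaining pairs coalesce
    exactly at the expansion time.
    """
    rng = as_rng(seed)
    n = model.n
    num_nodes = 2 * n - 1
    parent = np.full(num_nodes, -1, dtype=np.int64)
    time = np.zeros(num_nodes)
    horizon = model.t_scaled
    ratio = model.theta1 / model.theta0 if model.theta0 > 0 else np.inf

    # Candidate waiting times for every merge (k = n..2 lineages) in the
    # recent phase; by memorylessness the overshoot past the epoch can be
    # discarded and the remaining merges redrawn at the ancestral rate.
    ks = np.arange(n, 1, -1, dtype=float)
    base_rate = ks * (ks - 1) / 2.0
    pre_times = np.cumsum(rng.exponential(1.0 / base_rate))
    m = int(np.searchsorted(pre_times, horizon, side="left"))
    merge_times = np.empty(n - 1)
    merge_times[:m] = pre_times[:m]
    if m < n - 1:
        if np.isinf(ratio):
            merge_times[m:] = horizon  # instant-coalescence mode at the epoch
        else:
            merge_times[m:] = horizon + np.cumsum(
                rng.exponential(1.0 / (base_rate[m:] * ratio))
            )

    # Uniform random pair choice at every merge.
    u = rng.random((n - 1, 2))
    active: list[int] = list(range(n))
    for step in range(n - 1):
        k = n - step
        i = int(u[step, 0] * k)
        j = int(u[step, 1] * (k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        nxt = n + step
        parent[active[i]] = nxt
        parent[active[j]] = nxt
        time[nxt] = merge_times[step]
        active[i] = nxt
        del active[j]

    return Genealogy(n=n, parent=parent, time=time)


def place_mutations(gen: Genealogy, model: ExpansionModel, seed) -> MutationSet:
    """Drop mutations on the genealogy.

    Each branch of length ``b`` (N1-generation units) receives a
    Poisson(``b * theta1/2``) number of events; each event is assigned a
    locus uniformly on ``[0, L)`` and an independent equiprobable +/-1 step.
    """
    rng = as_rng(seed)
    lengths = gen.branch_lengths()
    counts = rng.poisson(lengths * (model.theta1 / 2.0))
    total = int(counts.sum())
    branch = np.repeat(np.arange(gen.num_nodes), counts)
    locus = rng.integers(0, model.L, size=total)
    sign = rng.integers(0, 2, size=total) * 2 - 1
    return MutationSet(branch=branch, locus=locus, sign=sign)


def realize_haplotypes(
    gen: Genealogy,
    events: MutationSet | Sequence[MutationEvent],
    model: ExpansionModel,
    seed: object = None,
) -> PairedHaplotypes:
    """Code the shared mutation events as ISM and SMM haplotype matrices."""
    if not isinstance(events, MutationSet):
        events = MutationSet.from_events(list(events))
    if len(events) and (events.branch.min() < 0 or events.branch.max() >= gen.num_nodes):
        raise ValueError("mutation event references a nonexistent branch")
    if len(events) and (events.locus.min() < 0 or events.locus.max() >= model.L):
        raise ValueError("mutation event references a nonexistent locus")

    masks = gen.leaf_masks()
    ism = masks[events.branch].T.astype(np.uint8)  # (n, S)

    delta = np.zeros((gen.num_nodes, model.L), dtype=np.int64)
    np.add.at(delta, (events.branch, events.locus), events.sign)
    net = masks.T.astype(np.int64) @ delta
    smm = SMM_BASELINE + net
    if smm.size and smm.min() < 0:
        warnings.warn(
            "SMM repeat counts went negative; the symmetric stepwise model "
            "does not truncate them",
            RuntimeWarning,
            stacklevel=2,
        )
    return PairedHaplotypes(
        ism=ism, smm=smm, site_locus=events.locus.copy(), model=model, seed=seed
    )


def simulate_replicate(model: ExpansionModel, seed) -> PairedHaplotypes:
    """One genealogy + mutations + both codings, from a single RNG stream."""
    rng = as_rng(seed)
    gen = simulate_genealogy(model, rng)
    events = place_mutations(gen, model, rng)
    return realize_haplotypes(gen, events, model, seed=seed)


def simulate_paired_dataset(
    model: ExpansionModel, reps: int, seed: int
) -> list[PairedHaplotypes]:
    """``reps`` independent replicates with per-replicate seeds spawned
    deterministically from the master seed (numpy SeedSequence spawning)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for r, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        gen = simulate_genealogy(model, rng)
        events = place_mutations(gen, model, rng)
        out.append(realize_haplotypes(gen, events, model, seed=(seed, r)))
    return out
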