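# Methods

## The model

`ssrhom` studies homoplasy in haplotypes of completely linked microsatellite
(SSR) loci — typically chloroplast SSRs, which are effectively haploid and
non-recombining — under a **stepwise demographic expansion**: a haploid
population of effective size `N0` grew instantaneously to `N1` at `t`
generations before sampling. With per-locus per-generation mutation rate `u`
and `L` linked loci, everything is parameterized by three scaled numbers:

```
theta0 = 2*L*N0*u      theta1 = 2*L*N1*u      tau = 2*L*t*u
```

Internally the coalescent runs in units of `N1` generations: `k` lineages
coalesce at rate `k(k-1)/2` back to the expansion epoch at `tau/theta1`, and
at rate `k(k-1)/2 * theta1/theta0` beyond it. The total mutation rate per
lineage per time unit is `theta1/2`; each mutation picks one of the `L` loci
uniformly and a `+1`/`-1` repeat step with equal probability. With
`theta0 = 0` all lineages surviving to the epoch merge instantly there
(zero-length ancestral branches), which is also the approximation the
analytic expectations make.

Every simulated genealogy is mutated **once** and the same events are coded
two ways:

* **ISM** (infinite sites): each event is a new 0/1 column carried by the
  leaves below its branch. Homoplasy is impossible by construction.
* **SMM** (stepwise mutation): each event shifts its locus's repeat count by
  its step. Steps on the path between two samples can cancel — the homoplasy
  whose consequences the package quantifies. The ancestral repeat count is an
  arbitrary constant (50); negative counts are possible in principle and are
  only warned about, because truncating them would break the symmetry of the
  walk.

Because both codings share one event set, the three homoplasy metrics are
exactly computable per replicate:

* `P = 1 - F_ISM/F_SMM` (haplotype-level homoplasy index),
* `MSH = 1 - mean_i(F^i_ISM/F^i_SMM)` (mean size homoplasy, per-locus),
* `DH = (pi_ISM - pi_SMM)/pi_ISM` (distance homoplasy; defined as 0 when
  `pi_ISM = 0`),

where `F` are homozygosities (plain `sum p^2`; the `n/(n-1)`-corrected form
is available behind a flag but the uncorrected form is the default because it
cancels identically in the ratios when the identity classes coincide,
guaranteeing `P = 0` in the no-homoplasy limit) and `pi` the mean pairwise
difference (ISM: differing sites; SMM: city-block distance on repeat counts,
which provably equals the Hamming distance of the classical binary 0/1-fill
recoding). Per-locus ISM homozygosity groups the site columns by locus of
origin, so the "allele" at locus `i` is the tuple of that locus's site
states. All three metrics are guaranteed to lie in `[0, 1]` on every
replicate: identity-by-descent classes refine identity-by-state classes, and
the net repeat displacement between two haplotypes can never exceed the
number of steps separating them.

## Analytic expectations

For a random pair of haplotypes the coalescent time `T` (in `N1`-generation
units, scaled variable `s`) has density `e^-s` on `[0, S)` with an atom
`e^-S` at the epoch `S = tau/theta1`. Given `T`, per-locus mutation counts
are Poisson with mean `m = 2uT = (theta1/L) s` and the SMM net displacement
is Skellam, which gives closed conditional moments:

```
ISM:  F^i = e^-m        F = e^-Lm           pi = L m
SMM:  F^i = e^-m I0(m)  F = [e^-m I0(m)]^L  pi = L m e^-m [I0(m) + I1(m)]
```

(`I_k`: modified Bessel functions, evaluated in exponentially scaled form so
large `m` cannot overflow). These closed forms were validated against a
direct Monte-Carlo oracle (Poisson step counts, equiprobable signs) before
being relied on; the test suite keeps that check.

Expectations are mixtures of the conditional moments over the pair-time
density. The per-generation bookkeeping (a discrete pmf with mass
`(1/N) e^(-x/N)` at generations `x = 1..t-1` and the remainder at `t`)
depends on the arbitrary `u` chosen to discretize; `expected_stat` therefore
evaluates the mixture in the scaled variable by 256-point Gauss–Legendre
quadrature plus the atom, which is the `u -> 0` limit of the discrete sum
and exactly independent of `u`. The discrete pmf remains available
(`coal_time_pmf`, with block-striding for very large `N*t`) and its mixture
converges to the quadrature value as `N` grows — a property the suite
asserts.

Expected homoplasy metrics are ratios of expectations (`E[P] = 1 -
E[F_ISM]/E[F_SMM]`, etc.). Two caveats documented deliberately:

* These are pairwise quantities. The sample estimator `sum p_hat^2` over `n`
  haplotypes has exact expectation `1/n + (1 - 1/n) F_pair`;
  `expected_sample_stats` / `expected_homoplasy(..., finite_sample=True)`
  apply that correction, and that is the curve comparable to simulated
  replicate means. At `n = 150` the difference matters for `P` (about 0.02
  on the plateau).
* The ratio-of-expectations is not the expectation of the per-replicate
  ratio; simulated means of `P` can differ from the analytic curve by a
  Jensen gap of a similar size. The suite compares the six diversity
  statistics (where the correspondence is exact) at 3 standard errors, and
  the metrics at the plateau level.

## Expansion-time estimation and TS

The mismatch distribution (histogram of pairwise differences) under a sudden
expansion has expectation

```
F_j = Fhat_j(theta1) * P[Gamma(j+1) < (1+theta1) S]
    + e^-S * (Poisson(tau) ∗ Fhat(theta0))_j ,     Fhat_j(theta) = theta^j/(1+theta)^(j+1)
```

— the equilibrium geometric terms damped by a regularized incomplete gamma,
plus a Poisson wave convolved with the ancestral equilibrium. This form was
derived directly from the pair-time mixture and is algebraically identical to
the classical sudden-expansion mismatch expectation; it collapses to the pure
geometric at `tau = 0` and to Poisson(`tau`) in the star-genealogy limit, and
matches an `n = 2` simulation oracle bin by bin.

`fit_lswh` minimizes the unweighted sum of squared deviations between the
observed relative mismatch frequencies and this expectation over
`(theta0, theta1, tau)` — the classical least-squares estimator that assumes
no homoplasy. Because the reference implementation of that estimator is a GUI
program with an unspecified optimizer, the fit here is a fully specified
deterministic scheme: a fixed coarse grid (`theta0 in {0, 0.05, 0.1, 0.5,
1, 2}`, 12 log-spaced `theta1` in [0.5, 300], 17 `tau` values in [0, 40],
denser below `tau = 5` where the least-squares surface develops competing
local minima) refined by Nelder–Mead from the best eight grid points, ties
broken by smallest `tau`.
Histogram support runs to the maximum observed distance plus 10, with the
truncated tail renormalized. Monomorphic data short-circuit to `tau_hat = 0`
with a degenerate-fit flag. Validation is by parameter recovery
(self-consistency on exact frequencies; recovery of `tau` on homoplasy-free
simulated data), not bit-level agreement with any external program.

Fitting both codings of a paired replicate gives
`TS = (tau_ISM - tau_SMM)/tau_ISM`, the relative underestimation of the
expansion time caused by homoplasy. Replicates with `tau_ISM = 0` are
flagged and skipped; replicates with `TS < -10` (pathological SMM fits) are
excluded, mirroring the outlier rule of the original experiment. Scaled
estimates convert to years as `tau/(2Lu) * generation_time`.

## ABC estimation of homoplasy

Homoplasy is unobservable in real data (no ISM coding exists for an observed
sample), but every ABC simulation carries both codings. Plain rejection ABC:
draw `(theta0, theta1, tau)` from the priors, simulate a paired replicate of
the observed dimensions, compute the summaries `V` (mean across loci of the
repeat-count variance; population-variance convention — whichever convention
is chosen must match between observed data and simulations), `H` (mean
per-locus heterozygosity) and `a` (number of distinct haplotypes) on the SMM
matrix, and accept the fraction of draws closest to the observed summaries in
Euclidean distance after dividing each summary by its standard deviation
across the reference table. Each accepted simulation contributes its
`(P, MSH, DH)`: the posterior predictive distribution of homoplasy. Point
estimates are modes of a Gaussian KDE (Silverman bandwidth, 512-point grid);
intervals are equal-tailed percentiles, consistent with the parametric
bootstrap convention used for confidence intervals.

Defaults chosen where the original algorithm details are unavailable, stated
as this package's own design: reference tables of 100,000 rows with
acceptance fraction 0.005 (500 accepted); summaries standardized by table
standard deviation; no regression post-adjustment (plain rejection matches
the acceptance-step framing; an adjustment could be added but is out of
scope). Default priors are wide but finite: `tau ~ U[0, 30]`,
`theta1 ~ logU[0.1, 300]`, and `theta0 ~ logU[1e-5, theta1]` truncated at the
drawn `theta1` — the model space is expansions, and letting `theta0` exceed
`theta1` (contractions) systematically inflates posterior-predictive
homoplasy. All priors are user-settable; the truncation can be disabled.

Calibration machinery: `relative_bias` (mean of `(estimate - truth)/truth`,
exact-zero truths excluded with a warning), `credible_coverage` (fraction of
datasets whose truth falls in the equal-tailed interval at 50/75/90%), and
`parametric_bootstrap_ci` (percentile interval from re-estimating on `B`
datasets simulated at the fitted parameters; estimator failures are dropped
and counted). A known behaviour, documented rather than patched: the relative
bias of `P` is heavy-tailed, because datasets from old expansions can have
true per-replicate `P` near zero (nearly all haplotypes distinct under both
codings) while the posterior-predictive mode sits at the model's plateau
(~0.05–0.1), producing single-dataset ratios of +20 that can flip the sign of
a 100-dataset mean. Its magnitude is stable (~0.13); its sign is not.

## Synthetic data and what the tests show

The package bundles no real genotypes. The fixture generator emulates an
observed chloroplast-SSR table — 88 haplotypes at 7 loci from an expanded
conifer population (`tau = 5.6`, `theta1 = 30`, `theta0 = theta1/1000`),
SMM coding only, exactly what field data would provide — and arbitrary design
points of the simulation study (defaults `theta1 = 30`, `theta0 = 0.03`,
`n = 150`, `L = 6`, the standard `tau` grid 1.5..15). The generator is the
model itself, so passing tests demonstrate internal consistency of simulator,
theory and estimators under stepwise mutation with complete linkage and
complete haplotypes; they do not probe multi-step or length-constrained SSR
mutation, genotyping error, missing data, population structure or
recombination, none of which the model includes.

Problem sizes used by the test suite and the acceptance script are the
package's own desk-scale choices: 100 replicates per `tau` for the
plateau/agreement experiments (250 where the 3-SE normal band needs a
better-behaved batch mean), the full 1000-replicate TS experiment, and a
shared 50,000-row reference table with 500 accepted draws for the ABC
calibration (100 pseudo-observed datasets, 10 per `tau`).

## Numerical notes

* RNG: one `numpy` `SeedSequence` per entry point; per-replicate generators
  are spawned children, so replicate streams are independent and runs are
  bit-reproducible given `(parameters, seed)`.
* The genealogy sampler draws all candidate inter-coalescence waits at once
  and discards the overshoot at the epoch (valid by memorylessness);
  statistically equivalent to sequential drawing and ~4x faster.
* Mutation placement is branch-local Poisson (not a global count partitioned
  afterwards), keeping streaming determinism.
* Row-identity counting uses exact byte-key hashing rather than lexicographic
  sorting; `ive` (scaled Bessel) avoids overflow; the mismatch expectation is
  computed in log space where geometric/Poisson terms underflow.
* Degenerate inputs: `tau = 0` gives a point-mass pair-time at 0 (all
  expectations collapse correctly); monomorphic matrices give `F = 1`,
  `pi = 0`, `a = 1`; `P`/`MSH` denominators are strictly positive for finite
  samples; `DH` at `pi_ISM = 0` is 0 by definition.

## Known limitations

* The analytic expectations are pairwise approximations with `theta0`
  treated as 0; with `theta0 = theta1/1000` the residual discrepancy is well
  below Monte-Carlo noise at 100 replicates, but large `theta0` violates the
  approximation.
* The least-squares mismatch fit is a reimplementation of the classical
  estimator's objective, not of any specific program's optimizer; only
  statistical behaviour, not bit-level output, is comparable.
* Rejection ABC posteriors are conservative (slightly over-wide intervals)
  for the demographic parameters; coverage for the homoplasy measures is
  near nominal.
* The maximum-pseudolikelihood homoplasy-aware estimator of expansion time
  is out of scope (an external comparator), as are sequence-level homoplasy
  (MASH), population structure, and non-stepwise SSR mutation models.
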