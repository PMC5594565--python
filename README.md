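# ssrhom

Homoplasy metrics and demographic inference for linked SSR haplotypes.

Chloroplast microsatellites (cpSSRs) are a workhorse marker for dating plant
population expansions, but their stepwise mutation process hides mutations:
a `+1` and a `-1` step at the same locus cancel, so two haplotypes can be
identical in state without being identical by descent (homoplasy). That
hidden variation systematically biases expansion-time estimates downward.
`ssrhom` is a toolkit for quantifying this effect and for estimating
homoplasy itself from data:

* **Paired simulation.** A coalescent simulator for the stepwise expansion
  model (`theta0 = 2LN0u`, `theta1 = 2LN1u`, `tau = 2Ltu`) that codes the
  *same* genealogy and mutation events both as infinite-sites haplotypes
  (hISM, homoplasy-free) and stepwise-mutation repeat counts (hSMM), making
  homoplasy exactly measurable per replicate.
* **Three metrics.** The classical homoplasy index
  `P = 1 - F_ISM/F_SMM`, its per-locus average `MSH` (mean size homoplasy),
  and the distance homoplasy `DH = (pi_ISM - pi_SMM)/pi_ISM` — the fraction
  of true pairwise mutational differences hidden by cancellation — plus
  closed-form expectations of all of them under the expansion model.
* **Underestimation of expansion time.** A deterministic least-squares
  mismatch-distribution estimator of `(theta0, theta1, tau)` (the classical
  homoplasy-blind method), and the statistic
  `TS = (tau_ISM - tau_SMM)/tau_ISM` that measures how much homoplasy
  shrinks the estimate. `MSH` and `DH` track `TS` strongly; `P` does not.
* **Rejection ABC.** Estimates `(theta0, theta1, tau)` from an observed SSR
  haplotype table via summaries `(V, H, a)`, and — because every accepted
  simulation carries both codings — the *posterior predictive* distribution
  of `P`, `MSH` and `DH`: an estimate of homoplasy from data in which it is
  unobservable. Includes calibration tools (KDE modes, relative bias,
  credible coverage, parametric bootstrap CIs).

See `docs/methods.md` for the model, formulas and numerical choices.

## Worked example

Simulate an expansion (`theta1 = 30`, `theta0 = 0.03`, `tau = 9`, 150
haplotypes, 6 linked loci), measure homoplasy, and compare with theory:

```python
>>> import ssrhom as s
>>> model = s.ExpansionModel(theta0=0.03, theta1=30.0, tau=9.0, L=6, n=150)
>>> pairs = s.simulate_paired_dataset(model, reps=100, seed=42)
>>> import numpy as np
>>> trips = np.array([s.homoplasy_triple(p) for p in pairs])
>>> print(np.round(trips.mean(axis=0), 3))        # mean [P, MSH, DH]
[0.109 0.31  0.39 ]
>>> th = s.expected_homoplasy(model, finite_sample=True)
>>> print(round(th.P, 3), round(th.MSH, 3), round(th.DH, 3))
0.113 0.284 0.399
```

About 39% of the mutational differences between haplotypes are invisible in
the SMM coding at this expansion age (`DH = 0.39`), and the simulated means
sit on the analytic curves. Fitting the mismatch distribution of both
codings shows what that does to inference:

```python
>>> pair = pairs[0]
>>> tau_ism = s.fit_lswh(pair.ism, "ism").tau_hat
>>> tau_smm = s.fit_lswh(pair.smm, "smm").tau_hat
>>> print(round(tau_ism, 2), round(tau_smm, 2), round(s.ts_statistic(tau_ism, tau_smm), 2))
9.6 4.77 0.5
```

The homoplasy-blind fit on the stepwise coding recovers roughly half the
true expansion time. Converting a scaled estimate to years (7 loci,
`u = 5.5e-5`, 42.5-year generations):

```python
>>> print(round(s.tau_to_years(4.074, L=7, u=5.5e-5, generation_time=42.5)))
224864
```

The same analyses are available from the shell:

```sh
ssrhom simulate --theta1 30 --theta0 0.03 --tau 9 --loci 6 --n 150 --reps 10 --seed 1 --out out/
ssrhom theory --theta1 30 --tau 9 --loci 6
ssrhom fixtures --kind pinus_like --seed 3 --out fx/   # synthetic 88x7 table
ssrhom abc fx/pinus_like.tsv --n-sims 100000 --seed 1 --out abc_out/
```

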