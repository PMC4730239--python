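# Methods

## The model

An admixed population is described generation by generation.  A K × T
gene-flow matrix **M** = (mᵢ(t)) gives the fraction of the gene pool
replaced by migrants from ancestral population *i* at generation *t*
(*t* = 1 founds the population, *t* = T is the present).  The matrix must
satisfy: all entries in [0, 1]; the founding column sums to exactly 1;
every later column sums to at most 1, the remainder
h(t) = 1 − Σᵢ mᵢ(t) being inherited from the previous generation.

From **M** alone we derive, per ancestry *i*:

- the ancestry proportion Hᵢ(t) = Hᵢ(t−1)·h(t) + mᵢ(t), Hᵢ(0) = 0;
- the cohort survival sᵢ(t) = mᵢ(t)·Πᵣ₌ₜ₊₁..T h(r), the share of
  present-day ancestry-*i* material that entered at generation *t*;
- the effective recombination rate uᵢ(t) = Σᵣ₌ₜ..T (1 − Hᵢ(r)):
  crossovers between same-ancestry segments do not change observable track
  lengths, so each meiosis contributes only the probability (1 − Hᵢ) of
  recombining against a different ancestry.

Ignoring chromosome ends and genetic drift, the cohort-(i, t) tracks are
exponential with rate uᵢ(t) (junctions per Morgan), and a cohort contributes
tracks in proportion to sᵢ(t)·uᵢ(t).  The ancestry-*i* track-length density
is therefore the mixture Σₜ wᵢ(t)·uᵢ(t)·e^(−uᵢ(t)l) with
wᵢ(t) ∝ sᵢ(t)·uᵢ(t); the mean is Hᵢ(T)/Σₜ sᵢ(t)uᵢ(t) and the tail
probability P(L > C) = Σₜ wᵢ(t)e^(−uᵢ(t)C).  Because local-ancestry callers
cannot resolve short tracks, inference uses the conditional density on
(C, ∞), i.e. the mixture renormalized by that tail probability.

**Time indexing.**  The founding cohort accumulates T effective-meiosis
terms (r = t..T inclusive).  This is the convention under which the
single-pulse model has rate (1−m)T, e.g. P(L > 2 cM) = e^(−0.9·200·0.02) ≈
2.7% at m = 0.1, T = 200; the alternative with T−1 terms gives 2.8% and a
systematic 1/T bias against the simulator below.  A cohort entering in the
sampling generation has u = 1 − Hᵢ(T) > 0 (it undergoes one meiosis before
being sampled), consistent with that choice.

## The four classical two-way models

All have parameters (m, T), with population 1 the minor ancestry (m ≤ 0.5):

- **HI**: founding column (m, 1−m), nothing after.  Closed form: a single
  exponential with rate (1−m)T.
- **GA**: inflow (m/t, (1−m)/t) at every generation t.  This schedule keeps
  H₁(t) = m in every generation and makes every cohort contribute exactly
  1/T of the present gene pool; the mixture has rates (1−m)k, k = 1..T,
  with weights ∝ k.
- **CGFR**: population 1 founds alone, column (1, 0); population 2 donates
  a constant fraction a per generation t = 2..T with (1−a)^(T−1) = m.
- **CGFD**: mirror image, a = 1 − (1−m)^(1/(T−1)).

All four give H₁(T) = m exactly.  T = 1 leaves the continuous models with
no post-founding generations; they collapse to HI.  The GA schedule and the
CGF exponent convention (T−1 inflow events) are deliberate design choices,
isolated in the builders so either is a one-line change; an off-by-one
alternative shifts the fitted time by at most about one generation.

**CGFR/CGFD exchangeability.**  The two CGF sub-models are the same
unlabeled process with donor and recipient swapped, and "population 1" is
*defined* as the minor ancestry of the data.  At m = 0.5 genetic drift
decides which ancestry ends up minor, so the correct description of a
simulated CGF dataset is CGFR exactly when the realized minor ancestry is
the recipient.  The benchmark scores selections against this realized
donor/recipient configuration (`benchmark.expected_model`).

## Inference

1. m̂ is estimated once by the total-length estimator (the mean-ratio
   estimator via E[L₁]/E[L₂] = m/(1−m) is available as an alternative) and
   the minor ancestry is designated population 1.
2. With m fixed at m̂, the admixture time of each candidate model is fitted
   by maximizing the conditional log-likelihood Σᵢ Σⱼ log fᵢ(lᵢⱼ | L > C)
   over integer T in 1..t_max (default 500).  Fitting the *truncated*
   density to thresholded data is what makes T̂ robust to the choice of C.
3. The four models have equal parameter counts (k = 2), so AIC = 2k − 2ℓ̂
   selection reduces to the highest likelihood; ties break toward the fixed
   order HI, GA, CGFR, CGFD.  An LRT helper is provided for nested pairs.
4. Bootstrap (default B = 100) resamples tracks with replacement,
   stratified by ancestry, reruns the whole selection per replicate, and
   reports the support rate of the full-data choice, the mean and the
   2.5/97.5-percentile interval of the replicate time estimates under the
   full-data model.  Fractional headline times arise as bootstrap means;
   the integer full-data MLE is reported alongside.

**Numerical choices.**  The time search evaluates a coarse geometric ladder
of ~45 candidate times and then every integer inside the winning bracket;
the log-likelihood is smooth and effectively unimodal in T for these
families at realistic sample sizes.  For ancestry samples larger than 2000
tracks the likelihood is evaluated on 1024 log-spaced length bins, each
represented by its count-weighted mean length — exact to second order in
the bin width; `log_likelihood` itself always scores every track.  Mixture
components with zero weight (s·u = 0) are dropped so all rates are positive
and log-densities finite; a threshold whose tail probability underflows is
rejected with advice to lower it.  Densities that underflow at some
candidate time simply make that candidate −∞; a model whose likelihood is
non-finite for every candidate is marked failed and excluded from
selection (and counts against bootstrap support).

## The simulator

A pool of 2N haploid chromosomes (an "individual" is a sampled pair)
evolves for T discrete generations.  Each generation, migrant chromosomes
of pure ancestry replace a fraction of the *parent* pool (deterministic
largest-remainder counts — the theory's h(t) bookkeeping is deterministic,
and stochastic inflow would only add drift noise), then the entire next
generation is produced by random mating: each offspring recombines two
distinct, uniformly chosen parents with a Poisson(map length) number of
crossovers at uniform positions (Haldane model, no interference).  The
founding pool mates immediately, so a cohort entering at generation t
undergoes exactly T − t + 1 meioses, matching the theory's uᵢ(t).
Coordinates are continuous Morgans on [0, L); segments are stored as right
edges, so per-chromosome coverage is exact by construction.  Defaults
mirror the standard design: N = 5000, L = 3 Morgan (≈ human chromosome 1),
400 sampled individuals, one chromosome per run with replicates standing in
for more chromosomes.  No selection, no mutation, no interference, no
hotspots.

What the simulator deliberately shares with the theory (and real data does
not): homogeneous ancestral populations, a uniform recombination map, and
perfectly observed tracks.  What it has and the theory ignores: finite
chromosome ends (an excess of long, end-truncated tracks, which dominates
at very small T) and genetic drift (the realized ancestry proportion
wanders around its expectation with variance ≈ m(1−m)·T/(2N)).  Passing
theory-vs-simulation tests therefore validates the derivation, not the
behavior of local-ancestry callers on real genotypes, which add their own
track-boundary errors.

## Benchmark design and scales

The full study design simulates each model over m ∈ {0.1..0.5} and
T ∈ {5, 10, 20, 30, …, 200} with 10 replicates at N = 5000 and 400 sampled
individuals.  The package's own benchmarks reproduce this at reduced scale,
chosen up front from a noise budget rather than tuned:

- *Selection grid* (sensitivity/specificity): the full time grid — the
  error-prone T ≤ 10 cells must keep their 2/21 weight or the sensitivity
  is not comparable — with 1 replicate per condition, N = 500, 200 sampled
  individuals.
- *Accuracy grid* (time errors): T ∈ {20, 40, 70, 100, 200}, 4 replicates,
  N = 2500, 100 sampled individuals.  Two error sources shape this choice.
  Chromosome-end truncation (knowingly ignored by the theory) inflates the
  fitted time by roughly 1/(6m(1−m)) generations — a constant, so its
  relative contribution scales as 1/T, and the averaged error is only
  comparable across designs if the time grid's mean(1/T) matches; the grid
  therefore spans the design's full 20..200 range rather than stopping
  early.  Drift contributes √(mT/(6N(1−m)))/√R per cell, so the population
  is kept large.  Per-cell errors are computed on the mean of the correctly
  selected replicates' estimates (replicate-mean errors are also what the
  full-scale error tables are consistent with); wrongly selected datasets
  are discarded, and a per-replicate mode is available.

Relative error is |T_true − T̂|/T_true, averaged over the time grid per
(model, proportion) cell.

## Known limitations

- No drift or finite-chromosome corrections: at T ≲ 10 the exponential
  approximation degrades (unrecombined whole chromosomes are
  over-represented) and both time estimates and model selection lose
  accuracy, most visibly for small proportions.
- Only the four two-parameter models are fitted; the general K × T matrix
  supports forward computation and simulation, not free-matrix estimation.
- Tracks are pooled across haplotypes and chromosomes without
  length weighting; genetic-map error and local-ancestry caller error are
  outside scope.
- The cM↔Morgan conversion uses the exact factor 100; files are written
  with 10 significant digits, so decimal-limited caller output round-trips
  exactly.
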