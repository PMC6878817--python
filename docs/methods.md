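# Methods

## Exclusivity mixture and likelihood-ratio test

A candidate gene set is scored by a two-component mixture over patient
rows: with probability γ (*coverage*) the patient carries the exclusivity
mechanism and exactly one member gene fires — gene k with probability
p_k = π_k / Σ_j π_j — while the remaining members still mutate at their
background rates π_j; with probability 1−γ all members mutate
independently at their background rates.  The relative frequencies P are
never free parameters: the proportionality p_k ∝ π_k makes them a derived
quantity, so the free parameters are (γ, π_1…π_m).  The exclusive
component places no mass on an all-zero row, so a patient without any
member mutation contributes only through the background component; at
γ = 1 such a row has zero likelihood, which the code reports as the
sentinel −1e308.

The LRT statistic is S = 2[ℓ(γ̂, Π̂) − ℓ(0, Π̂₀)].  Because γ = 0 lies on
the parameter boundary, the asymptotic null distribution is the mixture
0.5χ₀² + 0.5χ₁²: p = 0.5·Pr(χ₁² ≥ S) for S > 0 and p = 1 at S = 0 (the
conservative point-mass convention; S below 1e-8 counts as zero).

**Maximization.**  The likelihood depends on a patient row only through
its 0/1 pattern, so all fitting first collapses the N×m slice to at most
2^m weighted patterns.  The alternative is maximized by bounded L-BFGS-B
on the natural scale (parameters clipped to [1e-6, 1−1e-6]) with analytic
gradients, from five starts (γ ∈ {0, 0.25, 0.5, 0.75, 0.95}, π at the
column means); including γ = 0 guarantees the fit never falls below the
null, whose MLE (column means) is closed-form.  We use the natural rather
than a logit scale because the logit parametrization stalls near the γ = 0
boundary (≈4× more iterations in benchmarks).

**Reported γ̂.**  For m = 2 the three-parameter model reproduces any
negative-association 2×2 table exactly, so under independence the
maximizer's γ is an arbitrary point on a likelihood ridge.
`fit_alternative` therefore reports the *smallest* γ whose profile
likelihood (maximized over Π) is within 1e-8 of the maximum, found by
bisection.  This leaves S unchanged and makes γ̂ interpretable: bounded
and shrinking toward 0 with N under independence, unbiased under a true
planted mechanism (γ̂ = 0.6 ± 0.03 at N = 1000 in simulation).

## Search, global-null test, model selection

*Multiple-path (beam) search.*  Size 2 scores all pairs; each next level
extends every beam member with every absent gene, deduplicates, and keeps
the `beam_width` most significant sets (ties broken by statistic, then by
sorted label tuple — deterministic).  The per-size minimum nominal p is
recorded as p_k.  Features altered in fewer than 2 patients are excluded
(a singleton column cannot be meaningfully exclusive).

*Batch pre-ranking.*  Scoring thousands of candidate sets per level with
a quasi-Newton fit each is the pipeline's bottleneck, so levels are first
ranked by a vectorized fixed-iteration Adam fit over all candidates
simultaneously (all size-m sets share the 2^m pattern space); only the top
2×beam_width candidates are re-fitted exactly, and small levels are
refitted in full.  Exact scores are memoised on the pattern-count vector,
which permutation replicates of the same matrix hit heavily.  Reported
p-values always come from the exact fits; the approximate fit only decides
which candidates get one.

*Global-null (GNH) test.*  Each replicate shuffles every column
independently across patients — marginal frequencies preserved,
co-occurrence destroyed — and re-runs the search.  Q_k is the add-one
permutation p-value of the observed p_k; θ = min_k Q_k; the global p
compares θ with each replicate's leave-one-out θ.

*Model selection.*  Seeds are beam members at sizes with Q_k < α whose
own nominal p beats the α-quantile of the permuted p_k distribution (an
interpretation of per-size admission; documented as such).  Each seed
grows one gene at a time while the best expansion's nominal p stays below
p₀, the `fpr_target`-quantile (default 5%) of per-permutation minima of
expansion p-values with the candidate column shuffled — so a true set
grows spuriously in ≤5% of datasets (measured 2.5% over 200 simulated
datasets).  Finally, every reported set of size ≥3 must also beat the
calibrated p₀ of each leave-one-gene-out base (*backward validation*,
strongest base first): a set that entered through a contaminated seed
(true set plus one passenger) fails against the true set as base, while
genuine members all survive.  Without this check, chains starting from
contaminated seeds report supersets of the truth.  Up to 10 seeds per
size are expanded (configurable).

## Survival stage

*Cox model.*  Breslow-tie partial likelihood maximized by damped Newton
iterations to gradient norm < 1e-8; |β̂| > 15 raises a separation warning.
The implementation is in-package because the LOOCV-within-permutation
layer refits it tens of thousands of times; it matches lifelines'
`CoxPHFitter` to 4+ decimals on test data.  Follow-up is administratively
censored at 60 months by default (5-year mortality); age enters
dichotomized at 50 years; gender is coded male = 1.

*Stepwise selection.*  Forward by Rao score test (entry 0.05), backward
by Wald (stay 0.10), iterated to a fixed point; deterministic given data.

*Risk stratification.*  The prognostic index is the multivariable linear
predictor.  The cutoff maximizes the two-group log-rank statistic over
admissible splits (smaller group ≥ 10% of patients; ties toward balance),
evaluated on the **full-model** index values.  Each patient's *group* is
then assigned from their **out-of-fold** score: a leave-one-out refit of
the model without that patient (computed as an exact one-step jackknife
from the full-data MLE via down-dated risk-set sums; it matches full
per-fold Newton refits to <1e-3 in the scores and is an order of
magnitude faster).  The cutoff is *not* searched over the out-of-fold
scores: with a handful of binary covariates those scores form
covariate-pattern clusters plus O(1/n) leave-one-out jitter whose
direction encodes the patient's own outcome, and a cutoff inside a
cluster can separate deaths from censored patients spuriously (null
maximally-selected χ² approaching 100 in experiments).  The full-model
index has no within-cluster split candidates.

*Permutation-adjusted p.*  (time, event) pairs are permuted against the
covariate rows and the whole pipeline — full fit, LOOCV scores, cutoff,
grouping, log-rank — is re-run per replicate; the adjusted p is the
add-one proportion of replicates whose statistic reaches the observed
one.  The comparison uses the *signed* log-rank z of the high-score group
(excess mortality), because the pipeline's alternative is directional and
the residual self-influence leak under permutation is always inverted
(event patients look safer to models fitted without them); a two-sided
comparison mistakes that artifact for signal and collapses power.  With
this design the rejection rate under a true null is ≈5% (200-replicate
check) and a planted HR of 2.5 on a 35%-prevalence covariate is flagged
at adjusted p ≤ 0.05 in ≈95% of runs.

## Synthetic data

`simulate_matrix` draws rows from the same mixture the statistics fit,
including background mutations of non-fired members for covered patients
(`background_leak=True`, the likelihood-consistent default; the stricter
exactly-one-mutation mode is available for robustness experiments).
Coverage of the member set then has closed-form expectation
1 − (1−γ)(1−π)^m, which the tests verify.  `simulate_survival` draws
exponential or Weibull event times with multiplicative hazard exp(Σβx)
and independent uniform or exponential censoring.

`make_gbm_like_fixture` emulates a glioblastoma alteration panel:
261 patients, three planted MEGSs of sizes 3/3/4 with coverages
0.75/0.70/0.65 and member background 0.04, 27 passenger features at rate
0.06 (37 features total), and survival with HR 1.9 on the first set's
profile plus age (β = 0.45 on the ≥50 indicator) and gender (β = 0.30)
effects over an exponential baseline of 0.031/month with uniform(0, 90)
censoring — chosen so ≈81% of patients die within the 5-year horizon.
The planted sets are disjoint with independent coverage mechanisms, so
each is the unique exclusive structure on its genes and "recovery" is
well defined; when sets share a hub gene, mixtures of their members are
themselves genuinely exclusive and no method can single out the planted
partition — the overlapping-collection behavior that hub sharing produces
is exercised qualitatively in the unit tests instead.  The truth sidecar
(who is covered, which member fired, planted coefficients) is a separate
object the discovery code never reads.

What the generator does **not** emulate: gene-length- or
expression-dependent background rates, mutational signatures, CNV segment
structure, subtype heterogeneity, or correlated censoring.  Passing the
fixture tests therefore demonstrates correctness of the machinery under
the model's own assumptions, not robustness to real-data violations of
them.

## Numerical choices and scales

- Parameters clipped to [1e-6, 1−1e-6]; likelihood at a boundary defined
  by limit; S < 1e-8 treated as 0; convergence 1e-8 (log-likelihood /
  gradient norm).
- Permutation estimators are add-one: Q_k, global p and adjusted p never
  return 0; their floor is 1/(n_perm+1).
- Default problem sizes for the calibration experiments: the LRT null
  study uses 2000 replicates (N = 200, rate 0.1); the expansion-FPR study
  200 datasets × 200 permutations; the end-to-end fixture study 50 seeds
  with a reduced search (K = 4, beam 8, 20 GNH / 30 expansion
  permutations) and 200 survival permutations; the survival type-I study
  200 replicates × 100 permutations at N = 150.
- The LRT's boundary-mixture p-value is asymptotic.  At very sparse
  settings (expected co-occurrence counts of ~2, e.g. N = 200 with 10%
  rates) it is visibly anticonservative — Pr(p ≤ 0.05) ≈ 0.10 under the
  null — because the discrete co-occurrence count makes "zero observed
  co-mutations" a common event.  The share of zero statistics stays near
  the theoretical 0.5 (≈0.47).  Denser data (rates ≥ 0.3 or larger N)
  restore the nominal level.  This is a property of the approximation,
  not of the implementation, and it is why the discovery pipeline's
  decisions rest on permutation calibration (Q_k, θ, p₀) rather than on
  nominal p-values alone.

## Known limitations

- Binary alterations only; no weights, covariates or multi-allelic states
  in the exclusivity model.
- The beam search is exact only relative to its beam (equivalence with
  exhaustive enumeration is guaranteed — and tested — for small gene
  universes); for very large K·M the beam may miss global optima.
- Breslow tie handling only in the bundled Cox fitter (adequate for
  month-resolution survival data with modest ties).
- The stepwise variable set is selected once on the full data and only
  the coefficients are refit inside each LOOCV fold; re-selecting
  variables per fold would be stricter but is not implemented.
- One permutation scheme (independent within-column shuffles) for the
  discovery nulls; degree-preserving alternatives are not implemented.
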