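# Methods

## Model

The observed count matrix V ∈ ℕ₀^{N×M} collects, for N patients, the
number of somatic single-base substitutions in each of M = 96
trinucleotide contexts (6 strand-collapsed substitutions × 4 flanking 5'
bases × 4 flanking 3' bases).  It is factorized as V ≈ WH with
W ∈ ℝ₊^{N×K} (exposures) and H ∈ ℝ₊^{K×M} (signatures, reported
row-stochastic).

Two noise models are supported:

* **Poisson:** V_nm ~ Po(μ_nm), μ = WH.  Maximum likelihood is equivalent
  to minimizing the generalized Kullback–Leibler divergence
  D(V‖μ) = Σ[V log(V/μ) − V + μ], done with the classical multiplicative
  updates.
* **Negative Binomial, patient-specific dispersion:**
  V_nm ~ NB(α_n, μ_nm/(α_n+μ_nm)), so E[V_nm] = μ_nm and
  Var(V_nm) = μ_nm(1 + μ_nm/α_n).  Small α_n means strong
  overdispersion; α_n → ∞ recovers the Poisson model.  Patient-level
  (rather than mutation-type-level) dispersion is used because the
  variance heterogeneity in mutational counts is dominated by differences
  between patients (mutational burden), not between contexts.  The NB
  negative log-likelihood equals, up to constants in (W, H), the
  divergence

      d_N(V‖WH) = Σ_nm [ V log(V/μ) − (α_n+V) log((α_n+V)/(α_n+μ)) ],

  which is ≥ 0 with equality iff V = WH.

The NB log-likelihood uses the standard pmf normalization
Γ(V+α)/(Γ(V+1)Γ(α)) computed through log-gamma; with this convention the
V = 0 term reduces to α log(α/(α+μ)) exactly.

## Estimation

Both fits use majorization–minimization multiplicative updates.  For the
NB divergence (with dispersions fixed):

    H_km ← H_km · Σ_n W_nk V_nm/μ_nm  /  Σ_n W_nk (V_nm+α_n)/(μ_nm+α_n)
    W_nk ← W_nk · Σ_m H_km V_nm/μ_nm  /  Σ_m H_km (V_nm+α_n)/(μ_nm+α_n)

Each update minimizes a Jensen/tangent-line surrogate that touches d_N at
the current iterate, so the divergence is non-increasing step by step
(property-tested over random instances).  As α → ∞ the NB ratio terms
tend to 1 and the Poisson KL updates are recovered (tested at α = 10⁹ to
1e-4 relative).

**Fitting pipeline for the NB model.**  (i) Poisson NMF provides fitted
means; (ii) the dispersions are estimated from those means by maximum
likelihood; (iii) W and H are re-estimated under d_N with the dispersions
held fixed.  No dispersion/factor alternation loop is run — the
dispersion enters the model as a nuisance scale of the noise, and a
single estimation pass from the (consistent-mean) Poisson fit is the
procedure implemented; an optional `refit_dispersion` flag re-estimates
α once from the final NB fit for reporting.

**Dispersion MLE.**  For each patient (or pooled over all patients in
shared mode) the NB profile log-likelihood in α is maximized by
Newton–Raphson on θ = log α (enforcing positivity), initialized at the
method-of-moments estimate from Var = μ(1+μ/α), with at most 100 steps
and score tolerance 1e-8.  If the Newton step leaves the admissible range
(log α ∈ [log 1e-3, log 1e5]) a bounded golden-section maximization takes
over.  Data with no apparent overdispersion (score positive at the
ceiling) return the cap α = 1e5, read as "effectively Poisson"; the cap
is set well above dispersion values observed in real cohorts (estimates
above ~2.6·10⁴ occur for exceptionally well-behaved patients).

## Numerical choices

* ε-clamping: fitted means and update denominators floored at ε = 1e-10
  (standard KL-NMF practice to avoid 0/0).
* Initialization: W, H entries i.i.d. U(0,1], jointly rescaled so
  mean(WH) = mean(V); init i uses seed `seed + i`.  Five random
  initializations per fit by default; the best final divergence wins,
  ties broken by the lowest init index.
* Convergence: stop when |d_t − d_{t−1}| / max(1, d_{t−1}) < tol, with
  library defaults tol = 1e-8 and max_iter = 10,000.  The rank-selection
  drivers and the acceptance script pass tol = 1e-5..1e-6 and
  max_iter = 1500..3000 explicitly: at the benchmark problem sizes the
  dispersion estimates and chosen ranks are unchanged by the tighter
  defaults while fits run several times faster (checked on the α = 200
  scenario).
* H is normalized row-stochastic only at output time, with W rescaled so
  WH is unchanged; the updates themselves operate on unconstrained
  nonnegative factors.
* Hitting max_iter is logged, not an error; the best iterate is returned.

## Rank selection

**Held-out-patient CV (SigMoS).**  For each K: fit the full matrix; then
J = 10 times, sample ⌈0.1·N⌉ patients (without replacement, independently
per split — not a partition) as a test set, refit on the remaining
patients, align the training signatures to the full-data ones by optimal
cosine assignment (Hungarian algorithm), and predict the held-out rows as
W_test H_train using the *full-data* exposures of the test patients.
The median over splits of the held-out cost is the score of K; the
smallest-median K wins (ties toward smaller K).  Re-estimating test-set
exposures from H_train is deliberately avoided — it lets the test set be
overfit and destroys the selection signal.  The J splits are drawn once
and reused across the K grid, making the medians invariant to grid order
and the comparison across K paired.  The default cost is generalized KL;
Frobenius and Itakura–Saito are available behind a flag.  Costs are never
compared across noise models, because each cost favors the model whose
likelihood it resembles; model choice is done with residual diagnostics
instead.  The dispersion plays no role at cost time: the prediction is a
point prediction of the mean.

Training subsets can lack counts entirely for a rare context; the
signature probability MLE for an unobserved type is 0, so internally the
fit runs on the observed columns and zeros are reinserted (the public fit
API still rejects all-zero columns as malformed input).

**AIC/BIC.**  AIC = −2 lnL + 2 n_prm, BIC = −2 lnL + ln(n_obs) n_prm with
n_obs = N (the patient is the observation unit) and
n_prm = K(N+M) for Poisson, +N for patient-specific NB, +1 for shared NB.
The parameter-count convention is configurable in code since normalization
constraints could arguably reduce it by K; the comparison across K is
insensitive to that offset.

## Residual diagnostics

Raw residuals R = V − WH are compared against ±2σ bands with
σ² = μ (Poisson) or μ(1+μ/α_n) (NB, per-patient); the report also carries
the min/median/max of α across patients to draw the band envelope.
"Normalized" residuals are Pearson residuals R/σ — the only normalization
comparable against fixed reference quantiles — and are summarized by
empirical quantiles at configurable probabilities (default 0.025, 0.975)
against standard-normal quantiles.  The coverage fraction
(share of |R| ≤ 2σ) sits near 95% under a well-specified model at
moderate counts; a Poisson fit to overdispersed data shows materially
lower coverage and heavy-tailed quantiles.  Plotting is left to the user;
all diagnostics are emitted as tables.

## Simulation generator

The generator reproduces the standard benchmark design: K signatures
(catalog mode always includes the two "ubiquitous" signatures SBS1 and
SBS5 and samples the rest without replacement), exposures i.i.d.
NB(mean 6000, dispersion 1.5) — a heavy-tailed, realistic mutational
burden — expected counts W·H, and per-cell noise that is Poisson, NB with
fixed α (10 = strong, 200 = moderate overdispersion), or NB with
per-patient α ~ U(10, 500).  "Adding noise" means resampling each count
from the noise distribution with mean (WH)_nm: additive noise cannot have
mean zero on counts, and resampling preserves E[V] = WH and the NB
variance exactly.  Everything is driven by one seeded PCG64 stream
(`numpy.random.default_rng`), recorded in run manifests.

The built-in catalog is **synthetic**: 10 sparse Dirichlet profiles
(concentration 0.15) mixed with a 3% uniform background, labeled
SBS1..SBS10, generated at a fixed internal seed.  The background mirrors
the strict positivity of consensus catalogs and guarantees no mutation
type has zero probability cohort-wide.  The profiles are *not* the
published consensus signatures, so cosine similarities computed against
this catalog validate the machinery, not biological identity; users can
point every catalog-consuming entry point at a real COSMIC-style TSV.

What the generator does not emulate: correlated exposures across
signatures within a patient, hypermutator subpopulations, context-
composition (opportunity) biases of real genomes, and signature pairs
that are nearly collinear (e.g. the well-known aging pair).  Passing
tests on this generator therefore demonstrate correctness of estimation
and selection under the stated model, not performance on cohorts that
violate it.

## Problem sizes used in checks

The packaged checks run the benchmark at 100 patients × 96 contexts with
5 true signatures.  The dispersion-recovery summary uses 20 replicate
cohorts per dispersion level in `scripts/acceptance.py` and 5 in the test
suite; the rank-selection robustness check uses 10 cohorts in the script
and 4 in the suite (with binomially slackened thresholds).  These counts
keep a full from-scratch rerun in the ten-minute range on a single CPU
while leaving the acceptance directions unchanged.

## Known limitations

* Dispersion is per patient, not per mutation type; burden-driven
  heterogeneity dominates in practice, but context-specific variance is
  not captured.
* NMF solutions are non-unique; five restarts make the best-divergence
  solution stable in the tested regimes but global optimality is not
  guaranteed.
* The dispersions are estimated from Poisson-NMF means; when the Poisson
  fit absorbs part of the noise (moderate α, modest N·M per parameter)
  the dispersion is slightly overestimated — visible in the α = 200
  benchmark, where estimates concentrate around ~230–260 — without
  affecting rank selection.
* Counts are assumed precomputed; no VCF/MAF context extraction, and no
  indel or doublet contexts.
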