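# nbsig

Mutational-signature extraction for cancer genomics with a Negative
Binomial noise model, plus a robust, cross-validation-style procedure for
choosing the number of signatures.

## The problem

A cohort's mutational counts form a matrix **V** (N patients × 96 SBS
trinucleotide mutation types).  Non-negative matrix factorization writes
V ≈ WH, where the rows of **H** (K × 96) are *mutational signatures* —
probability vectors over mutation types — and **W** (N × K) holds each
patient's *exposures* to those signatures.  The standard approach assumes
V_nm ~ Poisson((WH)_nm) and picks K by AIC/BIC.  Real mutational counts,
however, are overdispersed: their variance exceeds the Poisson mean, and
the extra variance differs from patient to patient.  Under that
misspecification, likelihood-based rank selection inflates K with
"signatures" that only explain noise.

`nbsig` implements:

* **NB-NMF with patient-specific dispersion.**  V_nm ~ NB(α_n, μ/(α_n+μ))
  with μ = (WH)_nm, so E[V_nm] = μ and Var(V_nm) = μ(1 + μ/α_n).
  W and H are estimated with majorization–minimization multiplicative
  updates that minimize the divergence
  d_N(V‖WH) = Σ[V log(V/μ) − (α_n+V) log((α_n+V)/(α_n+μ))],
  which is the NB negative log-likelihood up to constants and reduces to
  the generalized Kullback–Leibler divergence (Poisson NMF) as α → ∞.
  The dispersions α_1..α_N are estimated by Newton–Raphson maximum
  likelihood from the Poisson-NMF fitted means and then held fixed.
* **SigMoS-style rank selection.**  For each candidate K, repeated random
  90/10 patient splits; signatures refitted on the training patients are
  combined with full-data exposures of the held-out patients to predict
  the test counts; the K with the lowest median held-out cost (generalized
  KL by default) wins.  This is markedly more robust to a wrong noise
  model than AIC/BIC.
* Classical AIC/BIC selection, residual diagnostics (±2σ bands, Pearson
  residuals, QQ data), cosine-similarity matching against a signature
  catalog, and a simulation generator with known ground truth.

## Worked example

```python
import numpy as np
from nbsig import (SimulationConfig, simulate_dataset, nb_nmf, poisson_nmf,
                   estimate_dispersion, sigmos, match_signatures)

# 100 patients, 5 true signatures, strongly overdispersed NB noise
cfg = SimulationConfig(n_patients=100, n_signatures=5,
                       noise="negbin_fixed", alpha=10, seed=100)
data = simulate_dataset(cfg)

# dispersion estimated from the Poisson-NMF fit
po = poisson_nmf(data.counts, K=5, n_inits=5, tol=1e-6, max_iter=3000, seed=0)
alpha = estimate_dispersion(data.counts, po.fitted_means, mode="shared")
print(f"shared alpha-hat = {alpha.values[0]:.2f}")        # 10.32 (truth: 10)

# NB-NMF recovers the true signatures
fit = nb_nmf(data.counts, K=5, mode="patient", seed=0, tol=1e-6, max_iter=3000)
_, sims = match_signatures(data.true_H, fit.H)
print(np.round(sims, 3))                                   # [0.99  0.992 0.995 0.993 0.991]

# rank selection by held-out patients (Poisson model, misspecified on purpose)
res = sigmos(data.counts, "poisson", range(2, 9), J=10, seed=1,
             tol=1e-5, max_iter=1500)
print(res.chosen_k)                                        # 5
```

The printed dispersion sits close to the generating value even though it
was estimated under the misspecified Poisson fit, and the held-out-patient
selector recovers the true K where AIC on the same data runs to the top of
the grid.

The same pipeline is scriptable from the shell:

```sh
nbsig simulate -n 100 -k 5 --noise negbin_fixed --alpha 10 --seed 100 -o sim/
nbsig fit sim/counts.tsv --model nb --k 5 -o fit/
nbsig select sim/counts.tsv --method sigmos --model poisson --k-min 2 --k-max 8 -o sel/
nbsig residuals sim/counts.tsv fit/ -o resid/
nbsig match fit/H.tsv -o matched/
```

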