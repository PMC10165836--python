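"""Poisson and patient-specific Negative Binomial NMF.

Model
-----
The observed count matrix V (N patients x M mutation types) is approximated
by a low-rank product WH.  Under the Poisson model V_nm ~ Po((WH)_nm) the
maximum-likelihood factorization minimizes the generalized Kullback-Leibler
(gKL) divergence and is found with the classical multiplicative updates.
Under the Negative Binomial model with patient-specific dispersion,

    V_nm ~ NB(alpha_n, (WH)_nm / (alpha_n + (WH)_nm)),

so that E[V_nm] = (WH)_nm and Var(V_nm) = (WH)_nm (1 + (WH)_nm / alpha_n),
the negative log-likelihood is (up to constants in W, H) the divergence

    d_N(V||WH) = sum_nm [ V log(V/Lambda)
                          - (alpha_n + V) log((alpha_n + V)/(alpha_n + Lambda)) ],

minimized by majorization-minimization multiplicative updates that reduce to
the Poisson updates as alpha -> infinity.

Fitting procedure: the dispersions are estimated once by Newton-Raphson
maximum likelihood from the Poisson-NMF fitted means, then held fixed while
W and H are re-estimated by the NB updates.  Every fit is the best of
``n_inits`` random initializations (default 5).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, polygamma, psi

from .containers import (
    CountMatrix,
    DispersionVector,
    ExposureMatrix,
    FactorizationFit,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

EPS = 1e-10
ALPHA_CAP = 1e5
ALPHA_FLOOR = 1e-3


def _values(V) -> np.ndarray:
    return np.asarray(V.values if hasattr(V, "values") else V, dtype=float)


def _alphas_column(alphas, n_rows: int) -> np.ndarray:
    a = np.atleast_1d(_values(alphas)).astype(float)
    if a.size == 1:
        a = np.full(n_rows, a[0])
    if a.size != n_rows:
        raise ValueError(f"expected {n_rows} dispersions, got {a.size}")
    if (a <= 0).any():
        raise ValueError("dispersions must be positive")
    return a[:, None]


# ---------------------------------------------------------------------------
# Divergences and likelihoods
# ---------------------------------------------------------------------------

def gkl_divergence(V, Lambda) -> float:
    """Generalized Kullback-Leibler divergence sum[V log(V/L) - V + L].

    The zero-count convention 0*log(0) := 0 applies; Lambda entries are
    floored at a small epsilon.
    """
    V = _values(V)
    L = np.maximum(_values(Lambda), EPS)
    if V.shape != L.shape:
        raise ValueError(f"shape mismatch {V.shape} vs {L.shape}")
    vlog = np.zeros_like(V)
    pos = V > 0
    vlog[pos] = V[pos] * np.log(V[pos] / L[pos])
    return float(np.sum(vlog - V + L))


def nb_divergence(V, Lambda, alphas) -> float:
    """Negative Binomial divergence d_N(V||Lambda) with per-row dispersions.

    Equals the NB negative log-likelihood up to additive constants in
    Lambda; zero with equality iff V == Lambda.
    """
    V = _values(V)
    L = np.maximum(_values(Lambda), EPS)
    if V.shape != L.shape:
        raise ValueError(f"shape mismatch {V.shape} vs {L.shape}")
    a = _alphas_column(alphas, V.shape[0])
    term1 = np.zeros_like(V)
    pos = V > 0
    term1[pos] = V[pos] * np.log(V[pos] / L[pos])
    term2 = (a + V) * np.log((a + V) / (a + L))
    return float(np.sum(term1 - term2))


def nb_loglik(V, Lambda, alphas) -> float:
    """NB log-likelihood of V given means Lambda and per-row dispersions."""
    V = _values(V)
    L = np.maximum(_values(Lambda), EPS)
    if V.shape != L.shape:
        raise ValueError(f"shape mismatch {V.shape} vs {L.shape}")
    a = _alphas_column(alphas, V.shape[0])
    A = np.broadcast_to(a, V.shape)
    binom = gammaln(V + A) - gammaln(V + 1) - gammaln(A)
    vlog = np.where(V > 0, V * np.log(L), 0.0)
    return float(np.sum(binom + vlog + A * np.log(A) - (V + A) * np.log(A + L)))


def poisson_loglik(V, Lambda) -> float:
    """Poisson log-likelihood sum[V log(L) - L - log V!]."""
    V = _values(V)
    L = np.maximum(_values(Lambda), EPS)
    vlog = np.where(V > 0, V * np.log(L), 0.0)
    return float(np.sum(vlog - L - gammaln(V + 1)))


# ---------------------------------------------------------------------------
# Multiplicative updates
# ---------------------------------------------------------------------------

def poisson_update_H(V, W, H) -> np.ndarray:
    V, W, H = _values(V), _values(W), _values(H)
    L = np.maximum(W @ H, EPS)
    return H * (W.T @ (V / L)) / np.maximum(W.T @ np.ones_like(V), EPS)

def poisson_update_W(V, W, H) -> np.ndarray:
    V, W, H = _values(V), _values(W), _values(H)
    L = np.maximum(W @ H, EPS)
    return W * ((V / L) @ H.T) / np.maximum(np.ones_like(V) @ H.T, EPS)


def nb_update_H(V, W, H, alphas) -> np.ndarray:
    """One MM multiplicative update of H under the NB divergence."""
    V, W, H = _values(V), _values(W), _values(H)
    a = _alphas_column(alphas, V.shape[0])
    L = np.maximum(W @ H, EPS)
    num = W.T @ (V / L)
    den = np.maximum(W.T @ ((V + a) / (L + a)), EPS)
    H_new = H * num / den
    if not np.isfinite(H_new).all():
        raise FloatingPointError("non-finite ratio in H update (epsilon clamping failed)")
    return H_new


def nb_update_W(V, W, H, alphas) -> np.ndarray:
    """One MM multiplicative update of W under the NB divergence."""
    V, W, H = _values(V), _values(W), _values(H)
    a = _alphas_column(alphas, V.shape[0])
    L = np.maximum(W @ H, EPS)
    num = (V / L) @ H.T
    den = np.maximum(((V + a) / (L + a)) @ H.T, EPS)
    W_new = W * num / den
    if not np.isfinite(W_new).all():
        raise FloatingPointError("non-finite ratio in W update (epsilon clamping failed)")
    return W_new


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _nb_profile_loglik(v, mu, alpha: float) -> float:
    # constants in alpha retained so profiles are comparable across alpha
    return float(
        np.sum(
            gammaln(v + alpha)
            - gammaln(alpha)
            - gammaln(v + 1)
            + np.where(v > 0, v * np.log(mu), 0.0)
            + alpha * np.log(alpha)
            - (v + alpha) * np.log(alpha + mu)
        )
    )


def _nb_score(v, mu, alpha: float) -> float:
    # d loglik / d alpha
    return float(
        np.sum(
            psi(v + alpha)
            - psi(alpha)
            + np.log(alpha)
            - np.log(alpha + mu)
            + 1.0
            - (alpha + v) / (alpha + mu)
        )
    )


def _nb_score_deriv(v, mu, alpha: float) -> float:
    return float(
        np.sum(
            polygamma(1, v + alpha)
            - polygamma(1, alpha)
            + 1.0 / alpha
            - 1.0 / (alpha + mu)
            - (mu - v) / (alpha + mu) ** 2
        )
    )


def _mle_alpha(v: np.ndarray, mu: np.ndarray, alpha_cap: float, tol: float) -> float:
    """MLE of one NB dispersion by Newton-Raphson on log(alpha).

    Initialized at the method-of-moments estimate; falls back to a bounded
    scalar maximization of the profile likelihood on log(alpha) when the
    Newton iteration leaves the admissible range.  Data showing zero or
    negative overdispersion hit the ``alpha_cap`` ceiling ("effectively
    Poisson").
    """
    v = v.ravel().astype(float)
    mu = np.maximum(mu.ravel().astype(float), EPS)
    # no overdispersion -> score is positive everywhere up to the cap
    if _nb_score(v, mu, alpha_cap) >= 0:
        return alpha_cap
    denom = np.sum((v - mu) ** 2 - mu)
    alpha = np.sum(mu**2) / denom if denom > 0 else 1.0
    alpha = float(np.clip(alpha, ALPHA_FLOOR, alpha_cap))
    theta = np.log(alpha)
    lo, hi = np.log(ALPHA_FLOOR), np.log(alpha_cap)
    for _ in range(100):
        alpha = np.exp(theta)
        s = _nb_score(v, mu, alpha)
        if abs(s) < tol:
            return float(alpha)
        fprime = _nb_score_deriv(v, mu, alpha) * alpha
        if not np.isfinite(fprime) or fprime >= 0:
            break
        step = s / fprime
        theta_new = theta - step
        if not np.isfinite(theta_new) or theta_new < lo or theta_new > hi:
            break
        theta = theta_new
    else:
        alpha = np.exp(theta)
        if abs(_nb_score(v, mu, alpha)) < np.sqrt(tol):
            return float(alpha)
    res = minimize_scalar(
        lambda t: -_nb_profile_loglik(v, mu, np.exp(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.clip(np.exp(res.x), ALPHA_FLOOR, alpha_cap))


def estimate_dispersion(
    V,
    Lambda,
    mode: str = "patient",
    alpha_cap: float = ALPHA_CAP,
    tol: float = 1e-8,
) -> DispersionVector:
    """Maximum-likelihood NB dispersions given fixed means Lambda.

    ``mode="patient"`` maximizes the per-patient likelihood row by row;
    ``mode="shared"`` maximizes the pooled likelihood over a single alpha
    applied to every patient.
    """
    V = _values(V)
    L = np.maximum(_values(Lambda), EPS)
    if V.shape != L.shape:
        raise ValueError(f"shape mismatch {V.shape} vs {L.shape}")
    if mode == "shared":
        alpha = _mle_alpha(V, L, alpha_cap, tol)
        return DispersionVector(
            np.full(V.shape[0], alpha), shared=True, alpha_cap=alpha_cap
        )
    if mode != "patient":
        raise ValueError(f"unknown dispersion mode {mode!r}")
    alphas = np.array(
        [_mle_alpha(V[n], L[n], alpha_cap, tol) for n in range(V.shape[0])]
    )
    return DispersionVector(alphas, shared=False, alpha_cap=alpha_cap)


# ---------------------------------------------------------------------------
# Fitting drivers
# ---------------------------------------------------------------------------

def _check_fit_inputs(V: np.ndarray, K: int) -> None:
    N, M = V.shape
    if not (1 <= K <= min(N, M)):
        raise ValueError(f"rank K={K} out of range [1, {min(N, M)}]")
    if (V.sum(axis=1) == 0).any():
        raise ValueError("count matrix has an all-zero patient row")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("count matrix has an all-zero mutation-type column")


def _init_wh(rng: np.random.Generator, N: int, M: int, K: int, v_mean: float):
    W = rng.uniform(0.0, 1.0, size=(N, K))
    H = rng.uniform(0.0, 1.0, size=(K, M))
    W, H = np.maximum(W, EPS), np.maximum(H, EPS)
    scale = np.sqrt(v_mean / max(np.mean(W @ H), EPS))
    return W * scale, H * scale


def _run_mm(V, W, H, alphas, tol, max_iter, divergence, update_H, update_W):
    trace = [divergence(V, W @ H)]
    for _ in range(max_iter):
        H = update_H(V, W, H) if alphas is None else update_H(V, W, H, alphas)
        W = update_W(V, W, H) if alphas is None else update_W(V, W, H, alphas)
        d = divergence(V, W @ H)
        trace.append(d)
        if abs(trace[-2] - d) / max(1.0, trace[-2]) < tol:
            break
    else:
        logger.info("MM updates hit max_iter=%d without meeting tol=%g", max_iter, tol)
    return W, H, np.array(trace)


def _best_of_inits(V, K, n_inits, tol, max_iter, seed, alphas, divergence, up_H, up_W):
    N, M = V.shape
    v_mean = float(V.mean())
    best = None
    for i in range(n_inits):
        rng = np.random.default_rng(seed + i)
        W0, H0 = _init_wh(rng, N, M, K, v_mean)
        W, H, trace = _run_mm(V, W0, H0, alphas, tol, max_iter, divergence, up_H, up_W)
        if best is None or trace[-1] < best[2][-1]:  # ties -> lowest init index
            best = (W, H, trace)
    return best


def _package_fit(V_cm, W, H, trace, model, K, n_inits, seed, dispersions):
    # output normalization: H row-stochastic, W rescaled so WH is unchanged
    row_sums = np.maximum(H.sum(axis=1), EPS)
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]
    sig_ids = [f"S{k + 1}" for k in range(K)]
    patient_ids = (
        V_cm.patient_ids
        if hasattr(V_cm, "patient_ids")
        else [f"P{n + 1}" for n in range(W.shape[0])]
    )
    mutation_types = (
        V_cm.mutation_types
        if hasattr(V_cm, "mutation_types")
        else [f"M{m + 1}" for m in range(H.shape[1])]
    )
    L = W @ H
    if model == "poisson":
        ll = poisson_loglik(_values(V_cm), L)
    else:
        ll = nb_loglik(_values(V_cm), L, dispersions.values)
    return FactorizationFit(
        W=ExposureMatrix(W, patient_ids, sig_ids),
        H=SignatureMatrix(H, sig_ids, mutation_types),
        model=model,
        rank=K,
        divergence_trace=trace,
        n_inits=n_inits,
        seed=seed,
        loglik=ll,
        dispersions=dispersions,
        n_iter=len(trace) - 1,
    )


def poisson_nmf(
    V,
    K: int,
    n_inits: int = 5,
    tol: float = 1e-8,
    max_iter: int = 10000,
    seed: int = 0,
) -> FactorizationFit:
    """Poisson NMF by gKL multiplicative updates, best of ``n_inits`` starts."""
    Vv = _values(V)
    _check_fit_inputs(Vv, K)
    W, H, trace = _best_of_inits(
        Vv, K, n_inits, tol, max_iter, seed, None,
        gkl_divergence, poisson_update_H, poisson_update_W,
    )
    return _package_fit(V, W, H, trace, "poisson", K, n_inits, seed, None)


def nb_nmf(
    V,
    K: int,
    mode: str = "patient",
    n_inits: int = 5,
    tol: float = 1e-8,
    max_iter: int = 10000,
    seed: int = 0,
    alpha_cap: float = ALPHA_CAP,
    refit_dispersion: bool = False,
) -> FactorizationFit:
    """Patient-specific (or shared) Negative Binomial NMF.

    Pipeline: (i) Poisson NMF supplies initial fitted means, (ii) the NB
    dispersions are estimated from those means by maximum likelihood,
    (iii) W and H are re-estimated by the NB MM updates with the dispersions
    held fixed.  ``refit_dispersion=True`` re-estimates the dispersions once
    from the final NB fit, for reporting.
    """
    Vv = _values(V)
    _check_fit_inputs(Vv, K)
    po = poisson_nmf(V, K, n_inits=n_inits, tol=tol, max_iter=max_iter, seed=seed)
    dispersions = estimate_dispersion(Vv, po.fitted_means, mode=mode, alpha_cap=alpha_cap)
    W, H, trace = _best_of_inits(
        Vv, K, n_inits, tol, max_iter, seed, dispersions.values,
        lambda v, l: nb_divergence(v, l, dispersions.values),
        nb_update_H, nb_update_W,
    )
    if refit_dispersion:
        dispersions = estimate_dispersion(Vv, W @ H, mode=mode, alpha_cap=alpha_cap)
    model = "negbin_patient" if mode == "patient" else "negbin_shared"
    return _package_fit(V, W, H, trace, model, K, n_inits, seed, dispersions)
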