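"""Rank selection for signature NMF.

Two families of procedures:

* ``sigmos`` — a cross-validation-style selector.  For each candidate rank
  K the chosen NMF is fitted to the full matrix; then, for each of J random
  90/10 patient splits, the NMF is refitted on the training patients and the
  held-out patients are predicted as W_test @ H_train, where W_test are the
  *full-data* exposures of the test patients with signatures re-aligned to
  the training fit by optimal cosine assignment.  The per-split held-out
  cost (generalized KL by default) is summarized by its median over splits,
  and the K with the lowest median wins.  Test-set exposures are
  deliberately NOT re-estimated from H_train (doing so overfits the test
  set).
* ``select_rank_ic`` — classical AIC/BIC on the fitted likelihood.

Costs are comparable across K within one model but never across models
(each cost function favors the model whose likelihood it matches).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import CountMatrix, FactorizationFit, SignatureMatrix
from .nmf import EPS, gkl_divergence, nb_nmf, poisson_nmf

logger = logging.getLogger(__name__)

_FIT_FUNCS = {
    "poisson": lambda V, K, **kw: poisson_nmf(V, K, **kw),
    "negbin_patient": lambda V, K, **kw: nb_nmf(V, K, mode="patient", **kw),
    "negbin_shared": lambda V, K, **kw: nb_nmf(V, K, mode="shared", **kw),
}


def _frobenius_cost(V, L) -> float:
    return float(np.sum((np.asarray(V, float) - np.asarray(L, float)) ** 2))


def _itakura_saito_cost(V, L) -> float:
    V = np.maximum(np.asarray(V, float), EPS)
    L = np.maximum(np.asarray(L, float), EPS)
    return float(np.sum(V / L - np.log(V / L) - 1.0))


COST_FUNCTIONS: Dict[str, Callable] = {
    "gkl": gkl_divergence,
    "frobenius": _frobenius_cost,
    "itakura_saito": _itakura_saito_cost,
}


# ---------------------------------------------------------------------------
# Signature matching
# ---------------------------------------------------------------------------

def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A, B = np.asarray(A, float), np.asarray(B, float)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("cosine similarity undefined for a zero row")
    return (A @ B.T) / np.outer(na, nb)


def match_signatures(H_ref: SignatureMatrix, H_query: SignatureMatrix):
    """Optimal one-to-one alignment of query signatures to reference ones.

    Returns ``(perm, sims)`` where ``perm[i]`` is the query row assigned to
    reference row i (so ``H_query.values[perm]`` is aligned with ``H_ref``)
    and ``sims[i]`` the cosine similarity of that pair.  The assignment
    maximizes total cosine similarity (Hungarian algorithm), not a greedy
    match.
    """
    A = H_ref.values if hasattr(H_ref, "values") else np.asarray(H_ref, float)
    B = H_query.values if hasattr(H_query, "values") else np.asarray(H_query, float)
    if A.shape != B.shape:
        raise ValueError(f"signature sets differ in shape: {A.shape} vs {B.shape}")
    sim = cosine_similarity_matrix(A, B)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    return perm, sim[np.arange(A.shape[0]), perm]


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

@dataclass
class InformationCriteria:
    loglik: float
    n_obs: int
    n_prm: int
    aic: float
    bic: float


def n_parameters(model: str, N: int, M: int, K: int) -> int:
    """Free-parameter count: K(N+M) for W,H plus the dispersion count."""
    base = K * (N + M)
    if model == "negbin_patient":
        return base + N
    if model == "negbin_shared":
        return base + 1
    return base


def information_criteria(fit: FactorizationFit, V: CountMatrix) -> InformationCriteria:
    """AIC = -2 lnL + 2 n_prm and BIC = -2 lnL + ln(n_obs) n_prm.

    The observation unit is the patient (n_obs = N), so the BIC penalty
    exceeds the AIC one whenever N >= 8.
    """
    N = len(fit.W.patient_ids)
    M = len(fit.H.mutation_types)
    Vv = V.values if hasattr(V, "values") else np.asarray(V)
    if Vv.shape != (N, M):
        raise ValueError("fit and count matrix shapes disagree")
    n_prm = n_parameters(fit.model, N, M, fit.rank)
    ll = fit.loglik
    return InformationCriteria(
        loglik=ll,
        n_obs=N,
        n_prm=n_prm,
        aic=-2.0 * ll + 2.0 * n_prm,
        bic=-2.0 * ll + math.log(N) * n_prm,
    )


def select_rank_ic(
    V: CountMatrix,
    nmf_method: str,
    k_grid: Sequence[int],
    criterion: str = "bic",
    seed: int = 0,
    full_output: bool = False,
    **fit_kwargs,
):
    """Classical rank selection: fit each K, return the argmin of AIC or BIC.

    Ties break toward the smallest K (parsimony).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    fit_func = _FIT_FUNCS[nmf_method]
    table = {}
    for K in sorted(set(int(k) for k in k_grid)):
        fit = fit_func(V, K, seed=seed, **fit_kwargs)
        ic = information_criteria(fit, V)
        table[K] = getattr(ic, criterion)
    chosen = min(table, key=lambda k: (table[k], k))
    return (chosen, table) if full_output else chosen


# ---------------------------------------------------------------------------
# Held-out-patient cross-validation (SigMoS)
# ---------------------------------------------------------------------------

def _fit_dropping_zero_types(fit_func, V: CountMatrix, K: int, **fit_kwargs):
    """Fit NMF, tolerating mutation-type columns with no counts.

    The public fit API rejects all-zero columns, but they arise naturally in
    the training subsets drawn inside ``sigmos`` (a rare context may be
    carried entirely by held-out patients).  The MLE signature probability
    for an unobserved type is 0, so we fit on the observed columns and
    reinsert zeros; row sums remain 1.

    Returns ``(fit, H_full)`` where ``H_full`` is K x M over all types.
    """
    Vv = V.values
    keep = Vv.sum(axis=0) > 0
    if keep.all():
        fit = fit_func(V, K, **fit_kwargs)
        return fit, fit.H.values
    V_red = CountMatrix(
        Vv[:, keep],
        V.patient_ids,
        [t for t, k in zip(V.mutation_types, keep) if k],
    )
    fit = fit_func(V_red, K, **fit_kwargs)
    H_full = np.zeros((K, Vv.shape[1]))
    H_full[:, keep] = fit.H.values
    return fit, H_full


@dataclass
class ModelSelectionResult:
    k_grid: list
    per_split_costs: Dict[int, np.ndarray]
    median_costs: Dict[int, float]
    chosen_k: int
    method: str
    cost_name: str
    J: int
    split_fraction: float
    seed: int


def sigmos(
    V: CountMatrix,
    nmf_method: str = "poisson",
    k_grid: Sequence[int] = range(2, 9),
    J: int = 10,
    split_fraction: float = 0.9,
    cost: str = "gkl",
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelectionResult:
    """Select the number of signatures by held-out-patient prediction.

    See the module docstring for the procedure.  The J train/test splits are
    drawn once and reused for every candidate K, so median costs do not
    depend on the order of ``k_grid``.
    """
    if nmf_method not in _FIT_FUNCS:
        raise ValueError(f"unknown NMF method {nmf_method!r}")
    if cost not in COST_FUNCTIONS:
        raise ValueError(f"unknown cost {cost!r}")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    cost_fn = COST_FUNCTIONS[cost]
    fit_func = _FIT_FUNCS[nmf_method]
    Vv = V.values
    N = Vv.shape[0]
    n_test = max(1, int(math.ceil((1.0 - split_fraction) * N)))
    if n_test >= N:
        raise ValueError("test set would contain every patient")
    n_train = N - n_test

    rng = np.random.default_rng(seed)
    splits = [rng.permutation(N)[:n_test] for _ in range(J)]
    fit_seed = int(rng.integers(0, 2**31 - 1))

    k_grid = sorted(set(int(k) for k in k_grid))
    per_split: Dict[int, np.ndarray] = {}
    medians: Dict[int, float] = {}
    for K in k_grid:
        if K > min(n_train, Vv.shape[1]):
            logger.warning("skipping K=%d: exceeds training dimensions", K)
            continue
        full_fit, H_full = _fit_dropping_zero_types(fit_func, V, K, seed=fit_seed, **fit_kwargs)
        costs = np.empty(J)
        for j, test_idx in enumerate(splits):
            train_mask = np.ones(N, dtype=bool)
            train_mask[test_idx] = False
            V_train = CountMatrix(
                Vv[train_mask],
                [V.patient_ids[i] for i in np.flatnonzero(train_mask)],
                V.mutation_types,
            )
            _, H_train = _fit_dropping_zero_types(
                fit_func, V_train, K, seed=fit_seed + 1 + j, **fit_kwargs
            )
            # align training signatures to the full-data ones so the
            # full-data exposures index the right rows of H_train
            perm, _ = match_signatures(H_full, H_train)
            H_aligned = H_train[perm]
            W_test = full_fit.W.values[test_idx]
            V_pred = W_test @ H_aligned
            costs[j] = cost_fn(Vv[test_idx], V_pred)
        per_split[K] = costs
        medians[K] = float(np.median(costs))
    if not medians:
        raise ValueError("every candidate K was skipped")
    chosen = min(medians, key=lambda k: (medians[k], k))
    return ModelSelectionResult(
        k_grid=list(per_split),
        per_split_costs=per_split,
        median_costs=medians,
        chosen_k=chosen,
        method=nmf_method,
        cost_name=cost,
        J=J,
        split_fraction=split_fraction,
        seed=seed,
    )
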