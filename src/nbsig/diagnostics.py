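"""Residual-based model checking and catalog comparison.

Raw residuals are R = V - WH; the model standard deviation is sqrt(mu)
under Poisson and sqrt(mu (1 + mu/alpha_n)) under the NB model with that
patient's dispersion.  Pearson (normalized) residuals R/sigma are compared
against +/- 2 sigma bands and standard-normal quantiles: overdispersed data
fitted with a Poisson model shows residuals spilling far outside the bands
and heavy-tailed normalized-residual quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import CountMatrix, FactorizationFit, SignatureMatrix
from .nmf import EPS
from .selection import cosine_similarity_matrix

DEFAULT_PROBS = (0.025, 0.975)
SIMILARITY_THRESHOLD = 0.8  # conventional cutoff for grouping similar signatures


@dataclass
class ResidualReport:
    fitted_means: np.ndarray
    raw_residuals: np.ndarray
    model_sd: np.ndarray
    normalized_residuals: np.ndarray
    band_multiplier: float
    coverage_fraction: float
    probs: tuple
    empirical_quantiles: np.ndarray
    theoretical_quantiles: np.ndarray
    # per-patient sd summaries (median/min/max of alpha across patients for
    # NB fits; identical curves under Poisson)
    sd_summary_alphas: Optional[dict] = None

    def to_frame(self, V: CountMatrix) -> pd.DataFrame:
        """Long-format table (patient, mutation type, mean, residual, sd, z)."""
        n, m = self.fitted_means.shape
        idx = pd.MultiIndex.from_product(
            [V.patient_ids, V.mutation_types], names=["patient", "mutation_type"]
        )
        return pd.DataFrame(
            {
                "fitted_mean": self.fitted_means.ravel(),
                "raw_residual": self.raw_residuals.ravel(),
                "model_sd": self.model_sd.ravel(),
                "normalized_residual": self.normalized_residuals.ravel(),
            },
            index=idx,
        )


def model_sd(fitted_means: np.ndarray, fit: FactorizationFit) -> np.ndarray:
    """Model standard deviation per cell under the fit's distribution."""
    mu = np.maximum(np.asarray(fitted_means, float), EPS)
    if fit.model == "poisson":
        return np.sqrt(mu)
    alpha = fit.dispersions.values[:, None]
    return np.sqrt(mu * (1.0 + mu / alpha))


def qq_data(
    normalized_residuals,
    probs: Sequence[float] = DEFAULT_PROBS,
    reference: str = "std_normal",
):
    """Empirical vs reference quantiles of the normalized residuals."""
    if reference != "std_normal":
        raise ValueError(f"unsupported reference {reference!r}")
    z = np.asarray(normalized_residuals, float).ravel()
    if z.size == 0:
        raise ValueError("empty residuals")
    probs = np.asarray(probs, float)
    return np.quantile(z, probs), norm.ppf(probs)


def residual_report(
    V: CountMatrix,
    fit: FactorizationFit,
    probs: Sequence[float] = DEFAULT_PROBS,
    band_multiplier: float = 2.0,
) -> ResidualReport:
    """Residual diagnostics for a fitted factorization.

    ``coverage_fraction`` is the share of cells whose raw residual falls
    inside +/- band_multiplier * sigma; under a well-specified model with
    moderate counts it should sit near the normal-approximation value
    (~95% at the default multiplier of 2).
    """
    Vv = np.asarray(V.values, float)
    mu = fit.fitted_means
    if Vv.shape != mu.shape:
        raise ValueError("fit and count matrix shapes disagree")
    sd = model_sd(mu, fit)
    raw = Vv - mu
    z = raw / sd
    coverage = float(np.mean(np.abs(raw) <= band_multiplier * sd))
    emp_q, theo_q = qq_data(z, probs)
    sd_summary = None
    if fit.dispersions is not None:
        a = fit.dispersions.values
        sd_summary = {
            "min": float(np.min(a)),
            "median": float(np.median(a)),
            "max": float(np.max(a)),
        }
    return ResidualReport(
        fitted_means=mu,
        raw_residuals=raw,
        model_sd=sd,
        normalized_residuals=z,
        band_multiplier=band_multiplier,
        coverage_fraction=coverage,
        probs=tuple(probs),
        empirical_quantiles=emp_q,
        theoretical_quantiles=theo_q,
        sd_summary_alphas=sd_summary,
    )


def catalog_similarity(
    H: SignatureMatrix,
    catalog: SignatureMatrix,
    threshold: float = SIMILARITY_THRESHOLD,
) -> pd.DataFrame:
    """Best catalog match per estimated signature (many-to-one allowed).

    Returns a table with columns (signature, best_match, cosine_similarity,
    above_threshold); similarities at or above ``threshold`` are flagged as
    plausible identifications.
    """
    if H.mutation_types != catalog.mutation_types:
        raise ValueError("mutation-type order differs between H and catalog")
    sim = cosine_similarity_matrix(H.values, catalog.values)
    best = sim.argmax(axis=1)
    best_sim = sim[np.arange(sim.shape[0]), best]
    return pd.DataFrame(
        {
            "signature": H.signature_ids,
            "best_match": [catalog.signature_ids[j] for j in best],
            "cosine_similarity": best_sim,
            "above_threshold": best_sim >= threshold,
        }
    )
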