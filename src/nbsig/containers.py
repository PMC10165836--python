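"""Labeled matrix containers for mutational-count factorization.

All containers are thin wrappers around a numpy array plus row/column
labels, validated on construction.  ``CountMatrix`` holds the observed
patients x mutation-types counts V, ``SignatureMatrix`` the row-stochastic
signature profiles H, ``ExposureMatrix`` the nonnegative loadings W and
``DispersionVector`` the per-patient Negative Binomial dispersions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-8


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(l) for l in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes[:5]}")
    return labels


@dataclass
class CountMatrix:
    """Observed mutational counts, patients as rows."""

    values: np.ndarray
    patient_ids: list[str]
    mutation_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("count matrix must be a non-empty 2-d array")
        if self.values.shape != (len(self.patient_ids), len(self.mutation_types)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.mutation_types)} types"
            )
        bad = ~np.isfinite(self.values) | (self.values < 0) | (self.values % 1 != 0)
        if bad.any():
            n, m = np.argwhere(bad)[0]
            raise ValueError(
                f"count matrix cell ({self.patient_ids[n]!r}, "
                f"{self.mutation_types[m]!r}) = {self.values[n, m]} is not a "
                "nonnegative integer"
            )
        self.values = self.values.astype(np.int64)
        self.patient_ids = _check_labels(self.patient_ids, "patient")
        self.mutation_types = _check_labels(self.mutation_types, "mutation-type")
        if len(self.mutation_types) != 96:
            logger.warning(
                "count matrix has %d mutation types (expected 96 for SBS96 data)",
                len(self.mutation_types),
            )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.mutation_types)


@dataclass
class SignatureMatrix:
    """Signatures as rows; each row is a probability vector over mutation types."""

    values: np.ndarray
    signature_ids: list[str]
    mutation_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("signature matrix must be a non-empty 2-d array")
        if self.values.shape != (len(self.signature_ids), len(self.mutation_types)):
            raise ValueError("signature matrix shape does not match labels")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("signature matrix entries must be finite and nonnegative")
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1.0).max() > ROW_SUM_TOL:
            k = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"signature {self.signature_ids[k]!r} row sums to {sums[k]:.10g}, not 1"
            )
        self.signature_ids = _check_labels(self.signature_ids, "signature")
        self.mutation_types = _check_labels(self.mutation_types, "mutation-type")

    @property
    def n_signatures(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_ids, columns=self.mutation_types)


@dataclass
class ExposureMatrix:
    """Nonnegative signature loadings, patients as rows."""

    values: np.ndarray
    patient_ids: list[str]
    signature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("exposure matrix must be a non-empty 2-d array")
        if self.values.shape != (len(self.patient_ids), len(self.signature_ids)):
            raise ValueError("exposure matrix shape does not match labels")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("exposure matrix entries must be finite and nonnegative")
        self.patient_ids = _check_labels(self.patient_ids, "patient")
        self.signature_ids = _check_labels(self.signature_ids, "signature")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.signature_ids)


@dataclass
class DispersionVector:
    """Per-patient NB dispersions alpha_n; ``shared`` marks alpha_1=...=alpha_N."""

    values: np.ndarray
    shared: bool = False
    alpha_cap: float = 1e5

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            raise ValueError("dispersions must be positive and finite")
        if (self.values > self.alpha_cap * (1 + 1e-12)).any():
            raise ValueError(f"dispersions exceed the configured ceiling {self.alpha_cap}")
        if self.shared and not np.all(self.values == self.values[0]):
            raise ValueError("shared dispersion vector has unequal entries")


@dataclass
class FactorizationFit:
    """Result bundle of one NMF fit (best of ``n_inits`` random starts)."""

    W: ExposureMatrix
    H: SignatureMatrix
    model: str  # "poisson" | "negbin_shared" | "negbin_patient"
    rank: int
    divergence_trace: np.ndarray
    n_inits: int
    seed: int
    loglik: float
    dispersions: Optional[DispersionVector] = None
    n_iter: int = field(default=0)

    def __post_init__(self) -> None:
        if self.model not in ("poisson", "negbin_shared", "negbin_patient"):
            raise ValueError(f"unknown model tag {self.model!r}")
        if (self.model == "poisson") != (self.dispersions is None):
            raise ValueError("dispersions must be present iff the model is Negative Binomial")
        self.divergence_trace = np.asarray(self.divergence_trace, dtype=float)
        d = self.divergence_trace
        if d.size and (np.diff(d) > 1e-8 * np.maximum(1.0, d[:-1])).any():
            raise ValueError("divergence trace is not non-increasing")

    @property
    def fitted_means(self) -> np.ndarray:
        return self.W.values @ self.H.values

    @property
    def final_divergence(self) -> float:
        return float(self.divergence_trace[-1])
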