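"""Synthetic mutational-count data with known signatures and dispersion.

The generator follows the standard benchmark design for signature
extraction: K row-stochastic signatures (two "ubiquitous" ones always
included when drawing from a catalog), exposures drawn i.i.d. from a
Negative Binomial with mean 6000 and dispersion 1.5 (a realistic per-patient
mutational-burden distribution), expected counts W @ H, and per-cell noise
that is Poisson, Negative Binomial with a fixed dispersion (typical values
10 = strong and 200 = moderate overdispersion), or Negative Binomial with a
per-patient dispersion drawn uniformly from a range (default (10, 500)).

The NB parameterization everywhere is mean mu and size alpha with
Var = mu (1 + mu / alpha); "adding noise" means resampling each count from
the noise distribution with mean (WH)_nm, which preserves E[V] = WH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import CountMatrix, DispersionVector, ExposureMatrix, SignatureMatrix
from .sbs96 import SBS96_TYPES

_CATALOG_SEED = 727  # internal: fixes the synthetic fixture catalog
_NOISE_MODELS = ("none", "poisson", "negbin_fixed", "negbin_patient")


@dataclass
class SimulationConfig:
    n_patients: int = 100
    n_signatures: int = 5
    exposure_mean: float = 6000.0
    exposure_dispersion: float = 1.5
    noise: str = "poisson"
    alpha: float = 10.0
    alpha_range: tuple[float, float] = (10.0, 500.0)
    signature_source: str = "catalog_file"  # or "dirichlet_random"
    forced_signatures: tuple[str, ...] = ("SBS1", "SBS5")
    catalog: Optional[SignatureMatrix] = None
    n_types: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in _NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.signature_source not in ("catalog_file", "dirichlet_random"):
            raise ValueError(f"unknown signature source {self.signature_source!r}")
        if min(self.exposure_mean, self.exposure_dispersion, self.alpha) <= 0:
            raise ValueError("exposure_mean, exposure_dispersion and alpha must be positive")
        lo, hi = self.alpha_range
        if not (0 < lo <= hi):
            raise ValueError("alpha_range must be positive and ordered")
        if self.n_patients < 1 or self.n_signatures < 1:
            raise ValueError("n_patients and n_signatures must be positive")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    true_W: ExposureMatrix
    true_H: SignatureMatrix
    config: SimulationConfig
    true_alphas: Optional[DispersionVector] = None

    @property
    def mean_matrix(self) -> np.ndarray:
        return self.true_W.values @ self.true_H.values


def _nb_draws(rng: np.random.Generator, mean, alpha) -> np.ndarray:
    """NB variates with mean ``mean`` and size ``alpha`` (Var = mu(1+mu/alpha))."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    p = alpha / (alpha + mean)  # success probability; mean 0 -> p = 1 -> draw 0
    return rng.negative_binomial(alpha, p)


def synthetic_catalog(n_signatures: int = 10, seed: int = _CATALOG_SEED) -> SignatureMatrix:
    """A synthetic stand-in signature catalog (labels SBS1..SBSn).

    The profiles are sparse Dirichlet draws over the 96 SBS contexts at a
    fixed internal seed, mixed with a 3% uniform background so every
    context has strictly positive probability: realistic in shape (each
    signature concentrated on a modest subset of contexts, mutually
    near-orthogonal, no exact zeros — consensus catalogs share these
    properties) but NOT the published consensus signatures.  Ships so that
    catalog-mode simulation and similarity reporting work fully offline.
    """
    if n_signatures > 96:
        raise ValueError("at most 96 synthetic signatures are supported")
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, 0.15), size=n_signatures)
    profiles = 0.97 * profiles + 0.03 / 96
    profiles /= profiles.sum(axis=1, keepdims=True)
    return SignatureMatrix(
        values=profiles,
        signature_ids=[f"SBS{i + 1}" for i in range(n_signatures)],
        mutation_types=list(SBS96_TYPES),
    )


def draw_signatures(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SignatureMatrix:
    """Draw the K true signatures.

    Catalog mode always includes the forced signatures (default SBS1 and
    SBS5, the two found across essentially all cancer types) and samples the
    remaining K-2 without replacement; ``dirichlet_random`` draws fresh
    sparse profiles.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K = config.n_signatures
    if config.signature_source == "dirichlet_random":
        vals = rng.dirichlet(np.full(config.n_types, 0.15), size=K)
        vals = 0.97 * vals + 0.03 / config.n_types
        vals /= vals.sum(axis=1, keepdims=True)
        types = (
            list(SBS96_TYPES)
            if config.n_types == 96
            else [f"M{m + 1}" for m in range(config.n_types)]
        )
        return SignatureMatrix(vals, [f"Sig{i + 1}" for i in range(K)], types)
    catalog = config.catalog if config.catalog is not None else synthetic_catalog()
    missing = [s for s in config.forced_signatures if s not in catalog.signature_ids]
    if missing:
        raise ValueError(f"forced signature(s) {missing} not in catalog")
    if K > catalog.n_signatures:
        raise ValueError(
            f"K={K} exceeds catalog size {catalog.n_signatures}"
        )
    forced = [s for s in config.forced_signatures][:K]
    pool = [s for s in catalog.signature_ids if s not in forced]
    extra = list(rng.choice(pool, size=K - len(forced), replace=False)) if K > len(forced) else []
    chosen = forced + extra
    idx = [catalog.signature_ids.index(s) for s in chosen]
    return SignatureMatrix(catalog.values[idx], chosen, catalog.mutation_types)


def draw_exposures(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> ExposureMatrix:
    """N x K i.i.d. integer NB exposures with the configured mean/dispersion."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    vals = _nb_draws(
        rng,
        np.full((config.n_patients, config.n_signatures), config.exposure_mean),
        config.exposure_dispersion,
    ).astype(float)
    return ExposureMatrix(
        vals,
        [f"P{n + 1}" for n in range(config.n_patients)],
        [f"S{k + 1}" for k in range(config.n_signatures)],
    )


def apply_noise(
    mean_matrix: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    patient_ids: Optional[Sequence[str]] = None,
    mutation_types: Optional[Sequence[str]] = None,
):
    """Resample each count from the noise distribution with mean (WH)_nm.

    Returns ``(CountMatrix, DispersionVector | None)``; the dispersion
    vector is returned for the NB noise models.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mu = np.asarray(mean_matrix, dtype=float)
    if (mu < 0).any():
        raise ValueError("mean matrix must be nonnegative")
    N, M = mu.shape
    alphas = None
    if config.noise == "none":
        counts = np.rint(mu).astype(np.int64)
    elif config.noise == "poisson":
        counts = rng.poisson(mu)
    elif config.noise == "negbin_fixed":
        counts = _nb_draws(rng, mu, config.alpha)
        alphas = DispersionVector(np.full(N, config.alpha), shared=True, alpha_cap=np.inf)
    else:  # negbin_patient
        a = rng.uniform(*config.alpha_range, size=N)
        counts = _nb_draws(rng, mu, a[:, None])
        alphas = DispersionVector(a, shared=False, alpha_cap=np.inf)
    cm = CountMatrix(
        counts,
        list(patient_ids) if patient_ids is not None else [f"P{n + 1}" for n in range(N)],
        list(mutation_types) if mutation_types is not None else [f"M{m + 1}" for m in range(M)],
    )
    return cm, alphas


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generator: signatures -> exposures -> expected counts -> noise.

    Fully determined by ``config.seed`` (single PCG64 stream).
    """
    rng = np.random.default_rng(config.seed)
    H = draw_signatures(config, rng)
    W = draw_exposures(config, rng)
    mu = W.values @ H.values
    counts, alphas = apply_noise(
        mu, config, rng, patient_ids=W.patient_ids, mutation_types=H.mutation_types
    )
    return SimulatedDataset(counts=counts, true_W=W, true_H=H, config=config, true_alphas=alphas)
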