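"""Tab-separated readers/writers for count matrices, catalogs and fits.

Dialects
--------
Count file: header row = mutation types, first column = patient id.
Catalog file: header row = signature ids, first column = mutation type in
"X[R>A]Y" notation, 96 data rows (COSMIC-style).  Exposure file: header =
signature ids, first column = patient id.  All files are UTF-8 TSV with '.'
decimal separator; writers emit 15 significant digits for reals.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    DispersionVector,
    ExposureMatrix,
    FactorizationFit,
    SignatureMatrix,
)
from .sbs96 import canonical_order

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.15g"
CATALOG_RENORM_TOL = 1e-6


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric values in column(s) {list(non_numeric)[:5]}")
    return df


def read_count_matrix(path, orientation: str = "patients_as_rows") -> CountMatrix:
    """Read a TSV count matrix; always returns patients-as-rows.

    ``orientation`` states how the file is laid out; no auto-detection is
    attempted (a 96x96 file would be ambiguous).
    """
    if orientation not in ("patients_as_rows", "patients_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "patients_as_columns":
        df = df.T
    return CountMatrix(
        values=df.to_numpy(),
        patient_ids=[str(i) for i in df.index],
        mutation_types=[str(c) for c in df.columns],
    )


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="patient")


def read_signature_catalog(path) -> SignatureMatrix:
    """Read a COSMIC-style catalog (rows = mutation types, columns = signatures).

    Columns are reordered to the canonical SBS96 order and each signature is
    renormalized to sum 1 (with a logged warning) when its probabilities
    deviate from 1 by more than 1e-6 — published catalogs carry rounding
    error.
    """
    df = _read_tsv(path)
    if len(df) != 96:
        raise ValueError(f"expected 96 mutation types, got {len(df)} rows")
    order = canonical_order([str(i) for i in df.index])
    df = df.iloc[order]
    values = df.to_numpy(dtype=float).T  # rows = signatures
    if (values < 0).any():
        raise ValueError("catalog contains negative entries")
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = [str(df.columns[k]) for k in np.flatnonzero(sums <= 0)]
        raise ValueError(f"signature(s) with nonpositive total probability: {bad}")
    off = np.abs(sums - 1.0) > CATALOG_RENORM_TOL
    if off.any():
        logger.warning(
            "renormalizing %d catalog signature(s) whose probabilities do not sum to 1",
            int(off.sum()),
        )
    values = values / sums[:, None]
    return SignatureMatrix(
        values=values,
        signature_ids=[str(c) for c in df.columns],
        mutation_types=[str(i) for i in df.index],
    )


def write_signature_catalog(H: SignatureMatrix, path) -> None:
    """Write a signature matrix in catalog orientation (types as rows)."""
    H.to_frame().T.to_csv(path, sep="\t", index_label="Type", float_format=FLOAT_FMT)


def write_signature_matrix(H: SignatureMatrix, path) -> None:
    H.to_frame().to_csv(path, sep="\t", index_label="signature", float_format=FLOAT_FMT)


def read_signature_matrix(path) -> SignatureMatrix:
    df = _read_tsv(path)
    values = df.to_numpy(dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    return SignatureMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_exposure_matrix(W: ExposureMatrix, path) -> None:
    W.to_frame().to_csv(path, sep="\t", index_label="patient", float_format=FLOAT_FMT)


def read_exposure_matrix(path) -> ExposureMatrix:
    df = _read_tsv(path)
    return ExposureMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_fit(fit: FactorizationFit, out_dir) -> None:
    """Write W.tsv, H.tsv, alpha.tsv (NB models only) and manifest.json."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_exposure_matrix(fit.W, out_dir / "W.tsv")
    write_signature_matrix(fit.H, out_dir / "H.tsv")
    manifest = {
        "model": fit.model,
        "rank": fit.rank,
        "seed": fit.seed,
        "n_inits": fit.n_inits,
        "n_iter": fit.n_iter,
        "final_divergence": fit.final_divergence,
        "loglik": fit.loglik,
    }
    if fit.dispersions is not None:
        pd.DataFrame(
            {"alpha": fit.dispersions.values}, index=fit.W.patient_ids
        ).to_csv(out_dir / "alpha.tsv", sep="\t", index_label="patient", float_format=FLOAT_FMT)
        manifest["shared_dispersion"] = bool(fit.dispersions.shared)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_fit(fit_dir, count_matrix: CountMatrix | None = None) -> FactorizationFit:
    """Reload a fit written by :func:`write_fit`."""
    fit_dir = Path(fit_dir)
    with open(fit_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    W = read_exposure_matrix(fit_dir / "W.tsv")
    H = read_signature_matrix(fit_dir / "H.tsv")
    dispersions = None
    alpha_path = fit_dir / "alpha.tsv"
    if alpha_path.exists():
        alpha = pd.read_csv(alpha_path, sep="\t", index_col=0)["alpha"].to_numpy()
        dispersions = DispersionVector(alpha, shared=bool(manifest.get("shared_dispersion")))
    return FactorizationFit(
        W=W,
        H=H,
        model=manifest["model"],
        rank=int(manifest["rank"]),
        divergence_trace=np.array([manifest["final_divergence"]]),
        n_inits=int(manifest["n_inits"]),
        seed=int(manifest["seed"]),
        loglik=float(manifest["loglik"]),
        dispersions=dispersions,
        n_iter=int(manifest.get("n_iter", 0)),
    )
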