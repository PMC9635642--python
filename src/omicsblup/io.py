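"""Delimited-text I/O for matrices, kernels, phenotypes and fit summaries.

Matrices travel as TSV/CSV with one header row of feature IDs and a first
column of individual IDs; kernels as TSV with individual IDs on both axes.
Values are written with 12 significant digits, so a write/read round trip
is lossless at that precision. Fit and evaluation summaries are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples, VariancePartition, predict
from .kernels import OmicsMatrix, RelationshipKernel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_kernel",
    "write_kernel",
    "read_plink_raw",
    "read_phenotype",
    "write_phenotype",
    "fit_to_json",
    "load_fit_json",
    "config_hash",
]

_FLOAT_FMT = "%.12g"


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    """Strict delimited read: unique IDs, rectangular rows, numeric cells.

    Errors name the offending identifier and the (1-based) line number.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:  # universal newlines: CRLF == LF
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(sep)
    col_ids = [c.strip() for c in header[1:]]
    if len(set(col_ids)) != len(col_ids):
        dup = next(c for i, c in enumerate(col_ids) if c in col_ids[:i])
        raise ValueError(f"{path}:1: duplicate column identifier {dup!r}")
    ncol = len(col_ids)
    row_ids, rows = [], []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != ncol + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol + 1} fields, got {len(parts)}"
            )
        rid = parts[0].strip()
        if rid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate row identifier {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        vals = np.empty(ncol)
        for j, cell in enumerate(parts[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                vals[j] = np.nan
                continue
            try:
                vals[j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cell!r} "
                    f"in column {col_ids[j]!r}"
                ) from None
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return pd.DataFrame(np.vstack(rows), index=row_ids, columns=col_ids)


def read_matrix(path, kind: str) -> OmicsMatrix:
    df = _read_table(path)
    return OmicsMatrix(df.to_numpy(), list(df.index), list(df.columns), kind)


def write_matrix(matrix, path) -> None:
    values = matrix.values
    df = pd.DataFrame(values, index=matrix.row_ids, columns=matrix.col_ids)
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index_label="id")


def read_kernel(path, component: str) -> RelationshipKernel:
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: kernel row and column identifiers differ")
    return RelationshipKernel(df.to_numpy(), component, list(df.index))


def write_kernel(kernel: RelationshipKernel, path) -> None:
    df = pd.DataFrame(kernel.values, index=kernel.row_ids, columns=kernel.row_ids)
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index_label="id")


def read_plink_raw(path) -> OmicsMatrix:
    """Read a PLINK .raw-style additive dosage export (FID/IID... columns)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
            if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError(f"{path}: missing IID column")
    ids = df["IID"].astype(str).tolist()
    data = df.drop(columns=meta)
    return OmicsMatrix(data.to_numpy(dtype=float), ids, list(data.columns),
                       "genotype")


def read_phenotype(path):
    """Phenotype table: columns id, y, and optionally generation."""
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "y" not in cols:
        raise ValueError(f"{path}: phenotype table needs 'id' and 'y' columns")
    ids = df[cols["id"]].astype(str).tolist()
    y = df[cols["y"]].to_numpy(dtype=float)
    gen = df[cols["generation"]].to_numpy() if "generation" in cols else None
    return ids, y, gen


def write_phenotype(ids, y, path, generations=None) -> None:
    data = {"id": ids, "y": y}
    if generations is not None:
        data["generation"] = generations
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False,
                              float_format=_FLOAT_FMT)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def fit_to_json(
    samples: PosteriorSamples,
    partition: VariancePartition,
    path,
    extra: dict | None = None,
) -> dict:
    """Serialize a fit summary: posterior means/SDs, partition, settings."""
    preds = predict(samples)
    summary = {
        "model": samples.model_name,
        "chain": {
            "n_iter": samples.chain.n_iter,
            "burn_in": samples.chain.burn_in,
            "thin": samples.chain.thin,
            "seed": samples.chain.seed,
            "retained": samples.n_draws,
        },
        "n_missing_phenotypes": samples.n_missing,
        "posterior_mean": {
            "mu": float(samples.mu.mean()),
            **{f"sigma2_{c}": float(v.mean()) for c, v in samples.sigma2.items()},
        },
        "posterior_sd": {
            "mu": float(samples.mu.std(ddof=1)),
            **{f"sigma2_{c}": float(v.std(ddof=1))
               for c, v in samples.sigma2.items()},
        },
        "variance_partition": {**partition.as_dict(), "sd": partition.sd},
        "ess": samples.diagnostics(),
        "row_ids": list(map(str, samples.row_ids)),
        "component_means": {
            c: [float(x) for x in v] for c, v in preds.components.items()
        },
        "y_hat": [float(x) for x in preds.y_hat],
    }
    if extra:
        summary.update(extra)
    Path(path).write_text(json.dumps(summary, indent=1))
    return summary


def load_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
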