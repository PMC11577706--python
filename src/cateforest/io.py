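"""CSV and serialization plumbing for the command-line workflows."""

from __future__ import annotations

import json
import numpy as np
import pandas as pd

from .dgp import Dataset
from .forest import forest_from_jsonl, forest_to_jsonl
from .cate_estimator import FittedCATE

__all__ = [
    "read_table",
    "write_dataset_csv",
    "write_manifest",
    "save_fitted",
    "load_fitted",
]

#: 17 significant digits round-trip IEEE doubles exactly.
FLOAT_FMT = "%.17g"


def read_table(path) -> Dataset:
    """Read a dataset CSV (columns Y, G, X1..Xp; tau_true optional).

    Raises a descriptive error naming the first offending column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    for col in ("Y", "G"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    xcols = sorted(
        (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not xcols:
        raise ValueError(f"{path}: no covariate columns X1..Xp found")
    expected = [f"X{i}" for i in range(1, len(xcols) + 1)]
    if xcols != expected:
        raise ValueError(f"{path}: covariate columns not contiguous, found {xcols}")
    for col in ["Y", "G", *xcols] + (["tau_true"] if "tau_true" in df.columns else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {row}")
    return Dataset(
        Y=df["Y"].to_numpy(float),
        G=df["G"].to_numpy(float),
        X=df[xcols].to_numpy(float),
        tau_true=df["tau_true"].to_numpy(float) if "tau_true" in df.columns else None,
    )


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Write a dataset as CSV with lossless float formatting."""
    cols = {"Y": dataset.Y, "G": dataset.G}
    for j in range(dataset.p):
        cols[f"X{j + 1}"] = dataset.X[:, j]
    if dataset.tau_true is not None:
        cols["tau_true"] = dataset.tau_true
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_manifest(path, params: dict) -> None:
    """Write a machine-readable run manifest (sorted keys, stable bytes)."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def save_fitted(fitted: FittedCATE, path) -> None:
    """Serialize a fitted estimator (training arrays + forest) to JSON lines."""
    with open(path, "w") as fh:
        header = {
            "type": "fitted_cate",
            "variant": fitted.variant_label,
            "X": fitted.X.tolist(),
            "Y_used": fitted.Y_used.tolist(),
            "G_used": fitted.G_used.tolist(),
        }
        fh.write(json.dumps(header) + "\n")
        forest_to_jsonl(fitted.forest, fh)


def load_fitted(path) -> FittedCATE:
    """Inverse of :func:`save_fitted`."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("type") != "fitted_cate":
            raise ValueError(f"{path}: not a fitted-estimator file")
        forest = forest_from_jsonl(fh)
    return FittedCATE(
        forest=forest,
        X=np.asarray(header["X"], dtype=float),
        Y_used=np.asarray(header["Y_used"], dtype=float),
        G_used=np.asarray(header["G_used"], dtype=float),
        variant_label=header["variant"],
    )
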