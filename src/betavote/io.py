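"""Readers and writers for the package's interchange formats.

* Vote matrix CSV — header ``id,label,g_1,...,g_K``; one row per compound.
* Dataset CSV — header ``id,label,x_1,...,x_D``.
* Count-profile TSV — ``k, pred_raw, err_raw, pred_corr, err_corr``.
* Uncertainty-profile TSV — ``k, phi_pmf, eps_pmf, u, confidence``.
* Model JSON — everything needed to score new data without refitting.

All files are UTF-8 with '.' decimals; floats round-trip at full double
precision (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import CountProfile, VoteMatrix
from .ensemble import Dataset

__all__ = [
    "read_vote_matrix",
    "write_vote_matrix",
    "read_dataset",
    "write_dataset",
    "write_count_profile",
    "read_count_profile",
    "write_model_json",
    "read_model_json",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # surface the offending row
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def read_vote_matrix(path) -> VoteMatrix:
    df = _read_csv(path)
    g_cols = sorted(
        (c for c in df.columns if c.startswith("g_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not g_cols or "label" not in df.columns:
        raise ValueError(
            f"{path}: expected columns id,label,g_1..g_K, got {list(df.columns)}"
        )
    bad = df[g_cols].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: missing outputs at row {int(bad.idxmax()) + 2}")
    return VoteMatrix(
        outputs=df[g_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        ids=df["id"].to_numpy() if "id" in df.columns else None,
    )


def write_vote_matrix(vm: VoteMatrix, path) -> None:
    df = pd.DataFrame(vm.outputs, columns=[f"g_{j + 1}" for j in range(vm.K)])
    df.insert(0, "label", vm.labels)
    df.insert(0, "id", vm.ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    df = _read_csv(path)
    x_cols = sorted(
        (c for c in df.columns if c.startswith("x_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not x_cols or "label" not in df.columns:
        raise ValueError(
            f"{path}: expected columns id,label,x_1..x_D, got {list(df.columns)}"
        )
    bad = df[x_cols].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: missing features at row {int(bad.idxmax()) + 2}")
    return Dataset(
        features=df[x_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
    )


def write_dataset(ds: Dataset, path) -> None:
    df = pd.DataFrame(ds.features, columns=[f"x_{j + 1}" for j in range(ds.d)])
    df.insert(0, "label", ds.labels)
    df.insert(0, "id", np.arange(ds.n))
    df.to_csv(path, index=False, float_format="%.17g")


def write_count_profile(raw: CountProfile, corrected: CountProfile, path) -> None:
    if raw.corrected or not corrected.corrected:
        raise ValueError("expected (raw, corrected) profile pair")
    pd.DataFrame(
        {
            "k": np.arange(raw.K + 1),
            "pred_raw": raw.pred_counts,
            "err_raw": raw.err_counts,
            "pred_corr": corrected.pred_counts,
            "err_corr": corrected.err_counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_count_profile(path) -> tuple[CountProfile, CountProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    K = len(df) - 1
    raw = CountProfile(
        K=K,
        pred_counts=df["pred_raw"].to_numpy(float),
        err_counts=df["err_raw"].to_numpy(float),
        corrected=False,
    )
    corr = CountProfile(
        K=K,
        pred_counts=df["pred_corr"].to_numpy(float),
        err_counts=df["err_corr"].to_numpy(float),
        corrected=True,
    )
    return raw, corr


def write_model_json(state: dict, path) -> None:
    Path(path).write_text(json.dumps(state, indent=2, sort_keys=True) + "\n")


def read_model_json(path) -> dict:
    return json.loads(Path(path).read_text())
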