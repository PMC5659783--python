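"""File I/O: behavioral datasets, parameter sets, fit results, manifests.

Datasets travel as comma-separated text with a header row; comment lines
prefixed ``#`` carry provenance (model fingerprint, seed) for simulated
data.  Parameter sets and manifests are JSON key-value files; floats are
serialized at full precision, so round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import ModelParams

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_params",
    "write_params",
    "read_json",
    "write_json",
]

DATASET_COLUMNS = ["subject", "trial", "v_left", "v_right", "choice", "rt_ms"]


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a behavioral dataset as commented CSV."""
    path = Path(path)
    lines = []
    for key in ("provenance", "model", "seed"):
        if key in dataset.attrs:
            lines.append(f"# {key}: {dataset.attrs[key]}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)
        dataset.to_csv(fh, index=False, columns=DATASET_COLUMNS,
                       lineterminator="\n")


def read_dataset(path) -> pd.DataFrame:
    """Read a behavioral dataset written by :func:`write_dataset`."""
    path = Path(path)
    attrs = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                attrs[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed dataset {path}: missing columns {missing}")
    bad = set(df["choice"].unique()) - {"L", "R", "NONE"}
    if bad:
        raise ValueError(f"malformed dataset {path}: bad choice codes {bad}")
    df.attrs.update(attrs)
    return df


def write_params(params: ModelParams, path) -> None:
    """Serialize one parameter set (with its active mask) as JSON."""
    write_json(params.to_dict(), path)


def read_params(path) -> ModelParams:
    return ModelParams.from_dict(read_json(path))


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
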