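"""Table loading/writing, config files, and model persistence.

All writers go through an atomic temp-file rename so a failing run never
leaves a partial artifact behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

from .manifold import Embedding, FeatureTable

FORMAT_VERSION = "1"

_CONFIG_KEYS = {
    "k", "epsilon", "alpha", "beta", "d",
    "n_trees", "learning_rate", "max_depth",
    "folds", "repeats", "seed", "threshold",
    "transductive", "standardize",
}


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def load_feature_table(
    path,
    id_col: Optional[str] = None,
    label_col: Optional[str] = None,
    require_label: bool = True,
) -> FeatureTable:
    """Load a delimited feature table.

    By default the first column is the sample id and the last the 0/1
    label; override with ``id_col`` / ``label_col``.  Pass
    ``require_label=False`` for unlabeled (prediction-time) tables, in
    which case every non-id column is a feature.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least an id column and one feature")

    id_col = id_col or df.columns[0]
    if id_col not in df.columns:
        raise ValueError(f"{path}: id column {id_col!r} not found")
    if require_label:
        label_col = label_col or df.columns[-1]
        if label_col not in df.columns:
            raise ValueError(f"{path}: label column {label_col!r} not found")
    elif label_col is not None and label_col not in df.columns:
        label_col = None
    elif label_col is None and df.columns[-1] == "label":
        label_col = "label"  # auto-detect on prediction-time tables

    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = df[id_col][df[id_col].duplicated()].unique()
        raise ValueError(f"{path}: duplicate sample ids {list(dupes)[:5]}")

    feature_cols = [c for c in df.columns if c not in {id_col, label_col}]
    raw = df[feature_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{ids[r]!r}, column {feature_cols[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {ids[r]!r}, column "
            f"{feature_cols[c]!r}"
        )

    y = None
    if label_col is not None:
        y_raw = pd.to_numeric(df[label_col], errors="coerce")
        if y_raw.isna().any() or not y_raw.isin((0, 1)).all():
            raise ValueError(f"{path}: label column must contain only 0/1")
        y = y_raw.to_numpy(dtype=int)
    return FeatureTable(ids=ids, X=numeric.to_numpy(dtype=float), y=y)


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    cols = {"id": table.ids}
    for j in range(table.n_features):
        cols[f"f{j + 1:03d}"] = table.X[:, j]
    if table.y is not None:
        cols["label"] = table.y
    df = pd.DataFrame(cols)
    _atomic_write(path, lambda p: df.to_csv(p, sep=_sep_for(path), index=False))


def write_embedding(ids, Y: np.ndarray, path, header_lines=()) -> None:
    """Embedding CSV: id, dim_1 ... dim_d, with optional '#' provenance
    comment lines up front."""
    path = Path(path)
    df = pd.DataFrame(Y, columns=[f"dim_{j + 1}" for j in range(Y.shape[1])])
    df.insert(0, "id", list(ids))

    def _write(p: Path) -> None:
        with open(p, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)

    _atomic_write(path, _write)


def write_json(obj: dict, path) -> None:
    _atomic_write(
        Path(path),
        lambda p: p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n"),
    )


def save_model(path, embedding: Embedding, classifier=None, extra=None) -> None:
    """Persist the fitted embedding (and optional classifier) as one
    archive."""
    payload = {
        "format_version": FORMAT_VERSION,
        "embedding": embedding,
        "classifier": classifier,
        "extra": extra or {},
    }
    _atomic_write(Path(path), lambda p: joblib.dump(payload, p))


def load_model(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = joblib.load(path)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model archive version")
    return payload


def read_config(path) -> dict:
    """Parse a ``key = value`` config file; unknown keys are rejected."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        out[key] = value
    return out


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
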