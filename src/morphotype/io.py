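"""Delimited-text dialects for every pipeline artefact.

All files are UTF-8 comma-delimited with a header row.  Measure tables and
similarity matrices carry participant ids as index; participant graphs use a
long format (participant_id, measure, region_a, region_b, weight).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd


def read_measure_table(path, expected_regions=None) -> pd.DataFrame:
    """Read and validate a participants x regions table.

    Rejects duplicate or missing participant ids, non-numeric cells and NaNs,
    naming the offending row/column.  ``expected_regions`` triggers a warning
    with the difference when the header deviates from an atlas list.
    """
    table = pd.read_csv(path, index_col="participant_id")
    if table.index.hasnans:
        raise ValueError(f"{path}: missing participant id")
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate participant id {dup[0]!r}")
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {bad!r}, column {col!r}")
        if table[col].isna().any():
            bad = table.index[table[col].isna()][0]
            raise ValueError(f"{path}: missing value at row {bad!r}, column {col!r}")
    if expected_regions is not None and list(table.columns) != list(expected_regions):
        extra = sorted(set(table.columns) - set(expected_regions))
        missing = sorted(set(expected_regions) - set(table.columns))
        warnings.warn(f"{path}: region header differs from atlas list (extra={extra}, missing={missing})",
                      stacklevel=2)
    return table.astype(float)


def write_measure_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index_label="participant_id")


def read_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path, index_col="participant_id")
    required = {"age", "sex", "batch"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"{path}: covariates missing columns {sorted(missing)}")
    return cov


def write_similarity_matrix(path, matrix: np.ndarray, participant_ids) -> None:
    ids = list(participant_ids)
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, index_label="participant_id")


def read_similarity_matrix(path):
    frame = pd.read_csv(path, index_col="participant_id")
    return frame.to_numpy(dtype=float), list(frame.index)


def write_graphs(path, long_frame: pd.DataFrame) -> None:
    long_frame.to_csv(path, index=False)


def read_graphs(path) -> pd.DataFrame:
    return pd.read_csv(path)


def long_to_stack(long_frame: pd.DataFrame):
    """Rebuild an (N, R, R) weight stack from long-format graph rows."""
    ids = list(dict.fromkeys(long_frame["participant_id"]))
    regions = sorted(set(long_frame["region_a"]) | set(long_frame["region_b"]))
    ridx = {r: i for i, r in enumerate(regions)}
    pidx = {p: i for i, p in enumerate(ids)}
    stack = np.zeros((len(ids), len(regions), len(regions)))
    pi = long_frame["participant_id"].map(pidx).to_numpy()
    ai = long_frame["region_a"].map(ridx).to_numpy()
    bi = long_frame["region_b"].map(ridx).to_numpy()
    w = long_frame["weight"].to_numpy(dtype=float)
    stack[pi, ai, bi] = w
    stack[pi, bi, ai] = w
    stack[:, np.arange(len(regions)), np.arange(len(regions))] = 1.0
    return stack, ids, regions


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
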