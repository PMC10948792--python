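"""CSV readers/writers and JSON reporting.

Dialects are fixed: UTF-8, comma-separated, mandatory header row, "."
decimal, lower-case canonical emotion labels.  Ratings travel long-format
(one row per participant x stimulus x emotion), probability tables wide
(first column ``stimulus_id``, then one column per emotion in configured
order), priors as two-column CSV.  Reports are schema-versioned JSON with a
provenance block (input hashes + config echo) so a run can be re-identified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .categories import CONDITIONS, EMOTIONS, QUALITIES
from .errors import SchemaError
from .tables import PriorVector, ProbabilityTable

REPORT_SCHEMA_VERSION = 1

RATING_COLUMNS = (
    "participant_id", "stimulus_id", "condition", "emotion", "presence", "intensity"
)
_OPTIONAL_RATING_COLUMNS = ("session", "quality")

_TRUE = {"yes", "true", "1"}
_FALSE = {"no", "false", "0"}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_ratings(path, emotions: Sequence[str] = EMOTIONS) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV.

    Presence may be encoded yes/no or true/false (case-insensitive).
    Malformed rows raise :class:`SchemaError` citing the first offending
    data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    _require_columns(df, RATING_COLUMNS, path)

    def _bad_rows(mask) -> str:
        rows = [int(i) + 1 for i in np.flatnonzero(np.asarray(mask))[:5]]
        return f"row(s) {rows}"

    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise SchemaError(f"{path}: unknown condition at {_bad_rows(bad)}")
    bad = ~df["emotion"].isin(list(emotions))
    if bad.any():
        labels = sorted(df.loc[bad, "emotion"].unique())
        raise SchemaError(f"{path}: unknown emotion label(s) {labels} at {_bad_rows(bad)}")
    presence_raw = df["presence"].astype(str).str.strip().str.lower()
    bad = ~presence_raw.isin(_TRUE | _FALSE) & df["presence"].notna()
    if bad.any():
        raise SchemaError(f"{path}: unparseable presence value at {_bad_rows(bad)}")
    df["presence"] = presence_raw.map(
        lambda v: True if v in _TRUE else (False if v in _FALSE else pd.NA)
    )
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.notna() & ~intensity.isin(range(0, 5))
    if bad.any():
        raise SchemaError(f"{path}: intensity outside 0..4 at {_bad_rows(bad)}")
    df["intensity"] = intensity.astype("Int64")
    if "session" in df.columns:
        df["session"] = pd.to_numeric(df["session"], errors="coerce").astype("Int64")
    if "quality" in df.columns:
        bad = df["quality"].notna() & ~df["quality"].isin(QUALITIES)
        if bad.any():
            raise SchemaError(f"{path}: unknown quality label at {_bad_rows(bad)}")
    return df


def write_ratings(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["presence"] = out["presence"].map({True: "yes", False: "no"})
    cols = [c for c in RATING_COLUMNS + _OPTIONAL_RATING_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def read_priors(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ("participant_id", "emotion", "likelihood"), path)
    return df


def write_priors(records: pd.DataFrame, path) -> None:
    records[["participant_id", "emotion", "likelihood"]].to_csv(path, index=False)


def read_probability_table(path, emotions: Sequence[str] | None = None) -> ProbabilityTable:
    """Read the wide probability-table dialect (stimulus_id + emotion columns)."""
    df = pd.read_csv(path, dtype={"stimulus_id": str})
    _require_columns(df, ("stimulus_id",), path)
    df = df.set_index("stimulus_id")
    if emotions is not None:
        missing = [e for e in emotions if e not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing emotion column(s) {missing}")
        df = df[list(emotions)]
    return ProbabilityTable.from_frame(df)


def write_probability_table(table: ProbabilityTable, path) -> None:
    table.to_frame().to_csv(path, float_format="%.17g")


def read_prior_vector(path) -> PriorVector:
    df = pd.read_csv(path)
    _require_columns(df, ("emotion", "probability"), path)
    return PriorVector(tuple(df["emotion"].astype(str)), df["probability"].to_numpy(float))


def write_prior_vector(prior: PriorVector, path) -> None:
    prior.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_covariates(path) -> pd.DataFrame:
    """Covariates CSV: participant_id plus one numeric column per covariate."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ("participant_id",), path)
    df = df.set_index("participant_id")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


# -- reporting ----------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_provenance(inputs: Mapping[str, str], config: Mapping) -> dict:
    """Provenance block: input hashes, config echo, software version."""
    return {
        "software": {"package": "emocue", "version": __version__},
        "inputs": {name: {"path": str(p), "sha256": file_sha256(p)}
                   for name, p in inputs.items()},
        "config": dict(config),
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
    return obj


def write_report(report: Mapping, path) -> None:
    """Serialize an analysis report to schema-versioned JSON at full precision."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **_jsonable(report)}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
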