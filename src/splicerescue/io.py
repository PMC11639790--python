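"""TSV readers/writers with strict schemas and reproducibility headers.

All interchange is UTF-8 tab-separated text. Output files carry ``#``-prefixed
header comment lines recording the tool version and any parameters or input
checksums the caller supplies; readers skip these. Numeric columns are parsed
strictly (a count of "12.5" is an error, not a truncation) and key-column
duplicates are reported with their line number.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diff import DiffTable

# schema: column -> kind ("int", "float", "str", "bool"); keys: uniqueness constraint
SCHEMAS = {
    "counts": {
        "columns": {"event_id": "str", "gene": "str", "event_type": "str",
                    "sample_id": "str", "inclusion": "int", "exclusion": "int"},
        "keys": ["event_id", "sample_id"],
    },
    "design": {
        "columns": {"sample_id": "str", "condition": "str"},
        "keys": ["sample_id"],
    },
    "ground_truth": {
        "columns": {"event_id": "str", "event_type": "str", "status": "str",
                    "true_psi_control": "float", "true_psi_dm1": "float",
                    "true_psi_treated": "float"},
        "keys": ["event_id"],
    },
    "psi": {
        "columns": {"event_id": "str", "gene": "str", "event_type": "str",
                    "condition": "str", "pooled_inclusion": "int",
                    "pooled_exclusion": "int", "coverage": "int", "psi": "float"},
        "keys": ["event_id", "condition"],
    },
    "diff": {
        "columns": {"event_id": "str", "event_type": "str", "psi_ref": "float",
                    "psi_test": "float", "dpsi": "float", "p_raw": "float",
                    "p_adj": "float", "significant": "bool"},
        "keys": ["event_id"],
    },
    "alteration": {
        "columns": {"feature_id": "str", "effect": "float", "significant": "bool"},
        "keys": ["feature_id"],
    },
    "labels": {
        "columns": {"feature_id": "str", "label": "str"},
        "keys": ["feature_id"],
    },
}


class TableFormatError(ValueError):
    """A TSV file does not match its schema; message carries the line number."""


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a TSV with a reproducibility header block.

    ``metadata`` key/value pairs are emitted as ``# key: value`` lines after
    the tool-version line.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# splicerescue {__version__}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def _count_header_comments(path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Raises :class:`TableFormatError` naming missing columns, the first
    malformed numeric cell, or the first duplicated key — with 1-based file
    line numbers.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    n_comments = _count_header_comments(path)
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False,
                      na_values=[""])
    missing = set(spec["columns"]) - set(raw.columns)
    if missing:
        raise TableFormatError(
            f"{path.name}: missing columns {sorted(missing)}; found {list(raw.columns)}"
        )
    first_data_line = n_comments + 2  # header row is line n_comments + 1

    out = pd.DataFrame(index=raw.index)
    for col, kind in spec["columns"].items():
        series = raw[col]
        if kind == "str":
            out[col] = series
        elif kind == "bool":
            lowered = series.str.lower()
            bad = ~lowered.isin(["true", "false"]) | series.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableFormatError(
                    f"{path.name} line {first_data_line + row}: column {col!r} must be "
                    f"True/False, got {series.iloc[row]!r}"
                )
            out[col] = lowered == "true"
        elif kind == "int":
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableFormatError(
                    f"{path.name} line {first_data_line + row}: column {col!r} must be an "
                    f"integer count, got {series.iloc[row]!r}"
                )
            out[col] = converted.astype(np.int64)
        elif kind == "float":
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna() & series.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableFormatError(
                    f"{path.name} line {first_data_line + row}: column {col!r} must be "
                    f"numeric, got {series.iloc[row]!r}"
                )
            out[col] = converted.astype(float)
        else:  # pragma: no cover - schema table is static
            raise AssertionError(kind)

    keys = spec["keys"]
    dup = out.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key_repr = tuple(out.iloc[row][k] for k in keys)
        raise TableFormatError(
            f"{path.name} line {first_data_line + row}: duplicated key "
            f"{dict(zip(keys, key_repr))}"
        )
    return out


def read_diff_table(path) -> DiffTable:
    """Read a differential-splicing TSV, recovering comparison metadata.

    The header comments written by :func:`write_diff_table` carry reference,
    test, threshold, alpha, and test name; missing metadata falls back to
    defaults with label "ref"/"test".
    """
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    table = read_table(path, "diff")
    return DiffTable(
        reference=meta.get("reference", "ref"),
        test=meta.get("test", "test"),
        dpsi_threshold=float(meta.get("dpsi_threshold", 15.0)),
        alpha=float(meta.get("alpha", 0.05)),
        table=table,
        test_name=meta.get("test_name", "fisher_exact_pooled"),
    )


def write_diff_table(diff: DiffTable, path, extra_metadata: dict | None = None) -> Path:
    meta = {
        "reference": diff.reference,
        "test": diff.test,
        "dpsi_threshold": diff.dpsi_threshold,
        "alpha": diff.alpha,
        "test_name": diff.test_name,
    }
    meta.update(extra_metadata or {})
    return write_table(diff.table, path, metadata=meta)
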