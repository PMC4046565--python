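"""Count-table readers/writers and provenance sidecars.

Counts travel as tidy TSV/CSV tables (one row per cell, columns ``cell_id``
and ``count``, optional ``condition`` and ``marker``); a ``--histogram``
style table of (count, n_cells) pairs is also accepted since published data
often come as histograms.  Every writer drops a JSON provenance sidecar
(``<output>.provenance.json``) recording inputs, parameters, seed and tool
version, so each output is reproducible from the sidecar alone.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import CountSample

__all__ = ["read_counts", "write_counts", "write_provenance", "tool_version"]


def tool_version() -> str:
    try:
        return version("organoise")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError("dialect must be 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def read_counts(
    path, dialect: str | None = None, *, histogram: bool = False
) -> CountSample:
    """Read a per-cell counts table (or a histogram table) into a CountSample.

    Validation is strict: counts must parse as non-negative integers and
    offending rows are named in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, dialect))
    if df.empty:
        raise ValueError(f"{path}: empty counts table")
    required = {"count", "n_cells"} if histogram else {"cell_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    def integer_column(col: str) -> np.ndarray:
        raw = df[col].to_numpy()
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values)) | (values < 0)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(
                f"{path}: column {col!r} must hold non-negative integers; "
                f"bad value(s) {[raw[i] for i in np.flatnonzero(bad.to_numpy())][:5]} "
                f"at file row(s) {rows[:5]}"
            )
        return values.to_numpy().astype(np.int64)

    if histogram:
        counts = np.repeat(integer_column("count"), integer_column("n_cells"))
        if counts.size == 0:
            raise ValueError(f"{path}: histogram expands to zero cells")
    else:
        counts = integer_column("count")
    condition = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
    marker = str(df["marker"].iloc[0]) if "marker" in df.columns else ""
    return CountSample(
        counts=counts, condition=condition, marker=marker,
        provenance={"source": str(path)},
    )


def write_provenance(path, record: dict) -> Path:
    sidecar = Path(str(path) + ".provenance.json")
    record = dict(record)
    record.setdefault("tool", "organoise")
    record.setdefault("tool_version", tool_version())
    sidecar.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return sidecar


def write_counts(
    sample: CountSample,
    path,
    dialect: str | None = None,
    *,
    force: bool = False,
) -> Path:
    """Write a CountSample as a tidy table plus a provenance JSON sidecar.

    Parent directories are created; an existing file is only overwritten
    with ``force=True``.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    sample.to_frame().to_csv(path, sep=_sep(path, dialect), index=False)
    write_provenance(path, {"provenance": dict(sample.provenance),
                            "condition": sample.condition,
                            "marker": sample.marker,
                            "n_cells": sample.n_cells})
    return path
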