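"""Readers and writers for the plain-text formats the pipeline exchanges.

The beta matrix travels as a tab-delimited loci x samples table (the
orientation of GEO series-matrix files); covariates and locus annotation as
samples-in-rows / loci-in-rows TSVs.  ``read_series_matrix`` is tolerant of
the series-matrix dialect: ``!``-prefixed metadata lines, optional
``!series_matrix_table_begin``/``_end`` sentinels, and quoted headers.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix

__all__ = [
    "read_series_matrix",
    "write_beta_tsv",
    "read_beta_tsv",
    "write_covariates_tsv",
    "read_covariates_tsv",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "write_key_value",
]

_FLOAT_FMT = "%.10g"


def read_series_matrix(path) -> tuple[BetaMatrix, pd.DataFrame | None]:
    """Parse a tab-delimited series-matrix-style beta table.

    Returns the beta matrix (samples x loci after transposition) and, when a
    second block or ``Detection Pval`` columns are present, a matching
    detection p-value frame (else None).
    """
    lines = Path(path).read_text().splitlines()
    table: list[str] = []
    in_table = True  # plain TSVs have no sentinels; treat whole file as table
    saw_sentinel = False
    for ln in lines:
        stripped = ln.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low.startswith("!series_matrix_table_begin"):
            in_table, saw_sentinel = True, True
            table = []
            continue
        if low.startswith("!series_matrix_table_end"):
            break
        if stripped.startswith("!"):
            if not saw_sentinel:
                continue
            continue
        if in_table:
            table.append(ln)
    if not table:
        raise ValueError(f"no data table found in {path}")
    frame = pd.read_csv(
        _io.StringIO("\n".join(table)), sep="\t", index_col=0, dtype=str
    )
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = [str(c).strip('"') for c in frame.columns]

    det_cols = [c for c in frame.columns if "detection" in c.lower()]
    beta_cols = [c for c in frame.columns if c not in det_cols]
    if not beta_cols:
        raise ValueError(f"no beta-value columns found in {path}")

    def _numeric(block: pd.DataFrame, what: str) -> pd.DataFrame:
        out = {}
        for col in block.columns:
            converted = pd.to_numeric(block[col], errors="coerce")
            raw = block[col]
            bad = converted.isna() & raw.notna() & (raw.str.strip().str.lower() != "null")
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-numeric {what} value {raw[row]!r} at row {row!r}, "
                    f"column {col!r}"
                )
            out[col] = converted
        return pd.DataFrame(out, index=block.index)

    beta = _numeric(frame[beta_cols], "beta")
    detection = None
    if det_cols:
        det = _numeric(frame[det_cols], "detection p")
        det.columns = [c.split(".")[0].strip() for c in det_cols]
        detection = det.T  # samples x loci
    # series matrices are loci x samples
    return BetaMatrix(beta.T), detection


def write_beta_tsv(beta: BetaMatrix, path) -> None:
    """Write loci x samples, matching series-matrix orientation."""
    out = beta.values.T
    out.index.name = "ID_REF"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_beta_tsv(path) -> BetaMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return BetaMatrix(frame.T)


def write_covariates_tsv(covariates: pd.DataFrame, path) -> None:
    out = covariates.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "locus_id"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann["chromosome"] = ann["chromosome"].astype(str)
    return ann


def write_key_value(mapping: dict, path) -> None:
    """Machine-readable sidecar: one flat JSON object, sorted keys."""

    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    Path(path).write_text(json.dumps(_clean(mapping), indent=2, sort_keys=True) + "\n")
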