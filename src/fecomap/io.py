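"""Readers and writers for the delimited-text tables.

All tables are comma-separated UTF-8 with a header row. Writers are
deterministic: fixed column order, ``\\n`` line endings and floats printed
with 17 significant digits (lossless for IEEE doubles), so identical inputs
yield byte-identical files. Schemas mirror typical connectome exports
(id-keyed flat tables); real CAVE/Codex exports can be adapted by renaming
columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import NEURON_CLASSES, SUBTYPES, TRANSMITTERS, ValidationError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

NEURON_COLUMNS = (
    "neuron_id",
    "neuron_class",
    "subtype",
    "hemilineage",
    "transmitter",
    "segment",
    "motor_module",
)

SYNAPSE_COLUMNS = ("pre_id", "post_id", "x", "y", "z")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing required column(s): {missing}")


def _bad_rows(mask: pd.Series) -> str:
    """File line numbers (header = line 1) of offending rows, for messages."""
    lines = (mask[mask].index + 2).tolist()
    shown = ", ".join(map(str, lines[:10]))
    return shown + ("..." if len(lines) > 10 else "")


def read_neuron_table(path) -> pd.DataFrame:
    """Read and validate a neuron annotation table.

    Enum columns are checked against the known vocabularies; violations are
    reported with file line numbers. ``motor_module`` must be set exactly for
    motor neurons, and a non-``none`` subtype is only allowed on sensory
    neurons. Extra columns are preserved.
    """
    df = pd.read_csv(
        path,
        dtype={
            "neuron_id": str,
            "neuron_class": str,
            "subtype": str,
            "hemilineage": str,
            "transmitter": str,
            "segment": str,
        },
    )
    _require_columns(df, NEURON_COLUMNS, "neuron table")
    dup = df["neuron_id"].duplicated(keep=False)
    if dup.any():
        names = sorted(df.loc[dup, "neuron_id"].unique())
        raise ValidationError(f"duplicate neuron_id(s): {names[:10]}")
    for col, allowed in (
        ("neuron_class", NEURON_CLASSES),
        ("subtype", SUBTYPES),
        ("transmitter", TRANSMITTERS),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            values = sorted(df.loc[bad, col].unique())
            raise ValidationError(
                f"unrecognized {col} value(s) {values} at line(s) {_bad_rows(bad)}"
            )
    df["motor_module"] = pd.array(
        pd.to_numeric(df["motor_module"], errors="coerce"), dtype="Int64"
    )
    is_motor = df["neuron_class"] == "motor"
    bad = is_motor ^ df["motor_module"].notna()
    if bad.any():
        raise ValidationError(
            "motor_module must be set exactly for motor neurons; "
            f"violations at line(s) {_bad_rows(bad)}"
        )
    bad = (df["subtype"] != "none") & (df["neuron_class"] != "sensory")
    if bad.any():
        raise ValidationError(
            f"non-sensory neuron with a sensory subtype at line(s) {_bad_rows(bad)}"
        )
    return df


def write_neuron_table(df: pd.DataFrame, path) -> None:
    extras = [c for c in df.columns if c not in NEURON_COLUMNS]
    out = df[list(NEURON_COLUMNS) + sorted(extras)]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_synapse_table(path) -> pd.DataFrame:
    """Read and validate a synapse table (one row per contact, coords in nm)."""
    df = pd.read_csv(
        path, dtype={"pre_id": str, "post_id": str}, float_precision="round_trip"
    )
    _require_columns(df, SYNAPSE_COLUMNS, "synapse table")
    for col in ("x", "y", "z"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            raise ValidationError(
                f"non-numeric or non-finite {col} coordinate at line(s) {_bad_rows(bad)}"
            )
        df[col] = values.astype(float)
    return df


def write_synapse_table(df: pd.DataFrame, path) -> None:
    extras = [c for c in df.columns if c not in SYNAPSE_COLUMNS]
    out = df[list(SYNAPSE_COLUMNS) + sorted(extras)]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_matrix(matrix, row_labels, col_labels, path, index_name: str = "id") -> None:
    """Write a labelled matrix as CSV; re-reading reproduces values exactly."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape != (len(row_labels), len(col_labels)):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match labels "
            f"({len(row_labels)}, {len(col_labels)})"
        )
    df = pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels))
    df.index.name = index_name
    df.to_csv(path, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def write_frame(df: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic CSV dump of an arbitrary result table."""
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT, lineterminator="\n")
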