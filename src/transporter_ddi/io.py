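"""Readers and writers for assay tables and configuration files.

Assay CSVs follow the schema produced by the synthetic-data generators
(comma or tab delimited, auto-detected):

* cell assays: ``experiment_id, cell_line, well_id, inhibitor_conc_uM,
  substrate_conc_uM, signal`` with ``cell_line`` in {transporter, control};
* vesicle assays: ``experiment_id, energy_source, well_id,
  inhibitor_conc_uM, signal`` with ``energy_source`` in {ATP, AMP}.

Concentrations are μM end-to-end; a unit suffix other than ``uM`` in a
concentration column name is rejected rather than converted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synth import ASSAY_COLUMNS, VESICLE_COLUMNS

__all__ = ["read_assay_csv", "write_assay_csv", "load_yaml", "dump_yaml"]


def _validate_cell_assay(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = set(df["cell_line"].unique()) - {"transporter", "control"}
    if bad:
        raise ValueError(f"{path}: unknown cell_line values {sorted(bad)}")
    if "transporter" not in set(df["cell_line"]):
        raise ValueError(f"{path}: no transporter-cell records")
    dup = df.duplicated(subset=["experiment_id", "cell_line", "well_id"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicated well ids at lines {lines}")
    # every nonzero inhibitor concentration must appear in both cell lines
    if set(df["cell_line"]) == {"transporter", "control"}:
        per_line = df.groupby("cell_line")["inhibitor_conc_uM"].agg(set)
        only_one = per_line["transporter"] ^ per_line["control"]
        only_one.discard(0.0)
        if only_one:
            raise ValueError(
                f"{path}: concentrations present in only one cell line: "
                f"{sorted(only_one)}"
            )
    return df


def _validate_vesicle(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = set(df["energy_source"].unique()) - {"ATP", "AMP"}
    if bad:
        raise ValueError(f"{path}: unknown energy_source values {sorted(bad)}")
    counts = df.groupby("inhibitor_conc_uM")["energy_source"].agg(set)
    incomplete = counts[counts != {"ATP", "AMP"}]
    if len(incomplete):
        raise ValueError(
            f"{path}: concentrations lacking ATP or AMP wells: "
            f"{incomplete.index.tolist()}"
        )
    return df


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    """Read a cell-assay or vesicle-assay CSV/TSV, validating its schema.

    The table kind is inferred from the header: an ``energy_source`` column
    marks a vesicle dataset. Malformed numeric rows are reported with their
    line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in df.columns:
        if col.startswith("inhibitor_conc") or col.startswith("substrate_conc"):
            if not col.endswith("_uM"):
                raise ValueError(f"{path}: concentration column {col!r} must be in uM")

    is_vesicle = "energy_source" in df.columns
    expected = VESICLE_COLUMNS if is_vesicle else ASSAY_COLUMNS
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    numeric = ["inhibitor_conc_uM", "signal"] + (
        [] if is_vesicle else ["substrate_conc_uM"]
    )
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(f"{path}: non-numeric {col!r} at lines {lines}")
        df[col] = coerced
    if df[numeric].isna().any().any():
        raise ValueError(f"{path}: missing values in numeric columns")
    if (df[[c for c in numeric if "conc" in c]] < 0).any().any():
        raise ValueError(f"{path}: negative concentrations")

    return _validate_vesicle(df, path) if is_vesicle else _validate_cell_assay(df, path)


def write_assay_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an assay table as plain CSV (lossless round-trip with the reader)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
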