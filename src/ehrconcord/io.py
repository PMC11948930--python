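"""Delimited-text readers for the five input tables and the code-set map.

All files are UTF-8 CSV with a header row and ISO-8601 dates.  Readers
validate the schema up front and report offending rows with their file
line numbers (header = line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .ehr import CODE_SYSTEMS, INPATIENT, MDR, OUTPATIENT, VHA, ConditionCodeSet


class SchemaError(ValueError):
    """An input file does not conform to its expected schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _check_enum(df: pd.DataFrame, column: str, allowed, path) -> None:
    bad = ~df[column].isin(list(allowed))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]
        raise SchemaError(
            f"{path}: column {column!r} has values outside {sorted(allowed)} "
            f"at lines {lines}")


def _parse_dates(df: pd.DataFrame, column: str, path) -> None:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]
        raise SchemaError(f"{path}: column {column!r} has unparseable dates "
                          f"at lines {lines}")
    df[column] = parsed


def read_encounters(path) -> pd.DataFrame:
    """Encounter table: one row per coded diagnosis.

    Columns: participant_id, source (VHA|MDR; purchased care belongs
    under VHA), setting (inpatient|outpatient), event_date, code,
    code_system (ICD9|ICD10|CPT), position (>=1), personal_history (0/1).
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "code": str})
    _require_columns(df, ["participant_id", "source", "setting", "event_date",
                          "code", "code_system", "position",
                          "personal_history"], path)
    _check_enum(df, "source", {VHA, MDR}, path)
    _check_enum(df, "setting", {INPATIENT, OUTPATIENT}, path)
    _check_enum(df, "code_system", set(CODE_SYSTEMS), path)
    _parse_dates(df, "event_date", path)
    if (df["position"] < 1).any():
        raise SchemaError(f"{path}: diagnostic positions must be >= 1")
    return df


def read_survey(path) -> pd.DataFrame:
    """Survey table: one row per completed participant-wave."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "wave", "survey_date"], path)
    _parse_dates(df, "survey_date", path)
    dup = df.duplicated(["participant_id", "wave"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise SchemaError(f"{path}: duplicate participant-wave rows at lines {lines}")
    return df


def read_vitals(path) -> pd.DataFrame:
    """Vital-sign table: participant_id, date, kind (height|weight), value."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "date", "kind", "value"], path)
    _check_enum(df, "kind", {"height", "weight"}, path)
    _parse_dates(df, "date", path)
    return df


def read_behaviors(path) -> pd.DataFrame:
    """Behavior table: participant_id, date, kind (audit_c|smoking), value."""
    df = pd.read_csv(path, dtype={"participant_id": str, "value": str})
    _require_columns(df, ["participant_id", "date", "kind", "value"], path)
    _check_enum(df, "kind", {"audit_c", "smoking"}, path)
    _parse_dates(df, "date", path)
    return df


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "sex"], path)
    return df


def read_codesets(path) -> list[ConditionCodeSet]:
    """Code-set map: condition_id, code_system, code, match_mode."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["condition_id", "code_system", "code", "match_mode"],
                     path)
    _check_enum(df, "code_system", set(CODE_SYSTEMS), path)
    _check_enum(df, "match_mode", {"exact", "prefix"}, path)
    out = []
    for cond, grp in df.groupby("condition_id", sort=False):
        modes = grp["match_mode"].unique()
        if len(modes) > 1:
            raise SchemaError(f"{path}: condition {cond!r} mixes match modes")
        entries = tuple(zip(grp["code_system"], grp["code"]))
        out.append(ConditionCodeSet(cond, entries, modes[0]))
    return out
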