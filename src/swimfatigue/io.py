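"""Trials-table serialization and machine-readable reports.

The interchange format is plain CSV (UTF-8, '.' decimal, mandatory header):
one row per trial, missing time-to-fatigue encoded as an empty field.
Write-then-read round-trips all records and flags exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import PipelineResult
from .population import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "report", "write_report"]

logger = logging.getLogger(__name__)

#: Columns a trials file must provide; the remainder of TRIAL_COLUMNS is
#: optional and any extra columns are carried through untouched.
REQUIRED_COLUMNS = ["species", "fish_id", "fork_length", "U_f", "T_f", "success"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "t": True, "f": False, "yes": True, "no": False}


class TrialsSchemaError(ValueError):
    """The file does not conform to the trials-table schema."""


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col
    mapped = col.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if mapped.isna().any():
        bad = col[mapped.isna()].unique()[:5]
        raise TrialsSchemaError(f"column {name!r} has non-boolean values: {bad}")
    return mapped.astype(bool)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trials CSV.

    Rows violating record invariants (negative or missing-on-success T_f,
    non-positive U_f or fork length) are dropped with row-numbered
    diagnostics; a missing required column or an empty file is a hard
    error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrialsSchemaError(f"{path}: no trials (empty file)") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialsSchemaError(f"{path}: header is missing required columns {missing}")
    if df.empty:
        raise TrialsSchemaError(f"{path}: no trials (header only)")

    df["success"] = _parse_bool(df["success"], "success")
    if "is_outlier" in df.columns:
        df["is_outlier"] = _parse_bool(df["is_outlier"], "is_outlier")
    else:
        df["is_outlier"] = False

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    def _flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad.loc[mask] = True

    _flag(~(df["U_f"] > 0), "non-positive U_f")
    _flag(~(df["fork_length"] > 0), "non-positive fork_length")
    _flag(df["success"] & ~(df["T_f"] > 0), "successful trial without positive T_f")
    _flag(~df["success"] & df["T_f"].notna(), "unsuccessful trial with recorded T_f")

    for i, reason in reasons.items():
        logger.warning("%s: row %d rejected: %s", path, i + 2, reason)  # 1-based + header
    df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise TrialsSchemaError(f"{path}: no valid trials after validation")
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trials table as CSV (missing T_f as empty field)."""
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, index=False)
    return path


def _round_half_up_pct(successes: int, total: int) -> int:
    return int(100.0 * successes / total + 0.5) if total else 0


def report(result: PipelineResult) -> dict:
    """Machine-readable summary of a pipeline run.

    Contains one entry per fitted group (regression fields, exponent
    estimate, reliability index, screening outcome), the groups where no
    fit was possible, and a per-species success summary with percentages
    rounded half-up to the nearest integer.
    """
    fits = result.fits_frame()
    species_summary = {}
    if result.success_summary is not None:
        for name, row in result.success_summary.iterrows():
            species_summary[str(name)] = {
                "total_fish": int(row["total_fish"]),
                "successful_trials": int(row["successful_trials"]),
                "success_rate_pct": _round_half_up_pct(
                    int(row["successful_trials"]), int(row["total_fish"])),
            }
    return {
        "n_groups": len(result.groups),
        "n_fits": len(result.fits),
        "n_accepted": int(fits["accepted"].sum()) if len(fits) else 0,
        "fits": json.loads(fits.to_json(orient="records")),
        "refused": result.refused,
        "species_summary": species_summary,
    }


def write_report(result: PipelineResult, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
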