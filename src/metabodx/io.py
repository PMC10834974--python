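"""Reading/writing concentration tables and run artifacts (delimited text)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .panel import resolve_alias
from .simulate import CASE, CONTROL, META_COLUMNS, GroundTruth, metabolite_columns

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "group", "age")
GROUP_ALIASES = {
    "control": CONTROL, "non-cvd": CONTROL, "non_cvd": CONTROL, "noncvd": CONTROL,
    "ctrl": CONTROL, "0": CONTROL,
    "case": CASE, "ihd": CASE, "1": CASE,
}


class TableFormatError(ValueError):
    """Raised when a concentration table fails validation."""


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if header.count("\t") > header.count(",") else ","


def read_table(path: str | Path, resolve_aliases: bool = True) -> pd.DataFrame:
    """Read and validate a wide concentration table (CSV or TSV).

    Requires ``subject_id, group, age`` columns (``sex`` optional); all other
    columns are metabolites and must be numeric.  Group labels are normalized
    to control/case; duplicate subject ids and missing group/age values are
    rejected with context.  Metabolite column names are normalized through
    the short-code alias map (C16-OH -> Hydroxyhexadecanoylcarnitine) unless
    ``resolve_aliases`` is off.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TableFormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if "sex" not in df.columns:
        df["sex"] = ""
    df["subject_id"] = df["subject_id"].astype(str)
    dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
    if dups:
        raise TableFormatError(f"{path}: duplicated subject_id(s): {sorted(set(dups))}")

    df["group"] = df["group"].astype(str).str.strip().str.lower().map(GROUP_ALIASES)
    if df["group"].isna().any():
        bad = df.loc[df["group"].isna(), "subject_id"].tolist()
        raise TableFormatError(f"{path}: unrecognized/missing group for {bad}")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if df["age"].isna().any():
        bad = df.loc[df["age"].isna(), "subject_id"].tolist()
        raise TableFormatError(f"{path}: missing/non-numeric age for {bad}")

    if resolve_aliases:
        df = df.rename(columns={c: resolve_alias(c) for c in metabolite_columns(df)})
    for c in metabolite_columns(df):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = df.index[bad][0]
            raise TableFormatError(
                f"{path}: non-numeric concentration in column {c!r}, "
                f"row {row} (subject {df.loc[row, 'subject_id']})"
            )
        df[c] = vals
    neg = [c for c in metabolite_columns(df) if (df[c] < 0).any()]
    if neg:
        logger.warning("negative concentrations in %d column(s) (adjusted table?)", len(neg))
    return df[META_COLUMNS + metabolite_columns(df)]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a concentration table as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(gt.to_dict(), sort_keys=False))


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(yaml.safe_load(Path(path).read_text()))


__all__ = [
    "read_table",
    "write_table",
    "write_ground_truth",
    "read_ground_truth",
    "TableFormatError",
]
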