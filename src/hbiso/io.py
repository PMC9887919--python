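"""Strict CSV I/O for cohort tables.

Cohorts are plain UTF-8 CSV with one header row and '.' as the decimal
separator.  Reading validates required columns and numeric cells:
a localized decimal comma (``"1,23"``) in a numeric column is rejected
with the offending row number rather than silently parsed or coerced.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_cohort", "write_table", "NUMERIC_COLUMNS"]

NUMERIC_COLUMNS = (
    "age", "height", "weight", "bmi", "wc", "hc", "smm", "fm", "bf_pct",
    "energy", "pa", "economic_score", "sbp", "dbp",
    "water", "unsweetened_coffee_tea", "low_fat_milk", "full_fat_milk",
    "fruit_juice_100", "ssb", "diet_drinks", "alcohol",
    "total_bev_energy", "total_fluid", "hbi_total",
    "id", "so", "smm_low2", "fm_high2", "bmi_ge30",
)


def _is_numeric_column(name: str) -> bool:
    return name in NUMERIC_COLUMNS or name.startswith("hbi_") and name != "hbi_quartile"


def read_cohort(path: str | Path, required: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read a cohort CSV, checking required columns and numeric cells."""
    df = pd.read_csv(path, dtype=object)
    for col in required or ():
        if col not in df.columns:
            raise KeyError(f"cohort file {path} is missing required column {col!r}")
    for col in df.columns:
        if not _is_numeric_column(col):
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValueError(
                f"non-numeric value {raw[bad.idxmax()]!r} in numeric column {col!r} "
                f"at line {row} of {path}"
            )
        df[col] = parsed
    return df


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV, round-trippable float precision, '.' decimals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False)
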