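"""Tabular ingest and report output.

Tree tables are delimited text (CSV/TSV; the delimiter is sniffed unless
given).  A column map adapts arbitrary headers to the canonical schema used
throughout the package; derived quantities (V, WD, BEF, BCEF, G) are
computed from raw measurements whenever absent, and each derived column is
noted in ``DataFrame.attrs['derived']``.  Rows violating basic invariants
(non-positive D, H <= 1.3 with no volume, non-numeric cells) are quarantined
with a warning rather than aborting the read.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .metrics import taper_volume

__all__ = ["read_trees", "write_report", "fit_results_table", "SchemaError"]

CANONICAL_COLUMNS = (
    "D", "H", "age", "stem_mass", "bark_mass", "branch_mass", "foliage_mass",
    "stump_mass", "coarse_root_mass", "middle_root_mass", "small_root_mass",
    "trunk_mass", "aboveground_mass", "TB", "V", "WD", "BEF", "BCEF", "G", "SI",
)


class SchemaError(ValueError):
    pass


def read_trees(path, column_map: Optional[Mapping[str, str]] = None,
               delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read and validate a tree table.

    ``column_map`` maps file headers to canonical names, e.g.
    ``{"DBH": "D", "height": "H"}``.  Unknown columns are kept untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if column_map:
        missing = [src for src in column_map if src not in df.columns]
        if missing:
            raise SchemaError(
                f"mapped column(s) {missing} not in file; available: {list(df.columns)}")
        df = df.rename(columns=dict(column_map))
    if "D" not in df.columns:
        raise SchemaError(f"no 'D' column after mapping; available: {list(df.columns)}")

    # coerce canonical columns to numeric; non-numeric cells become NaN
    bad_rows = pd.Series(False, index=df.index)
    for col in df.columns:
        if col in CANONICAL_COLUMNS:
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            for idx in df.index[newly_bad]:
                warnings.warn(f"row {idx}: non-numeric value {df.at[idx, col]!r} "
                              f"in column {col!r}; row quarantined")
            bad_rows |= newly_bad
            df[col] = coerced

    bad = bad_rows | (df["D"] <= 0) | df["D"].isna()
    if "H" in df.columns:
        bad |= (df["H"] <= 1.3) & (df["V"].isna() if "V" in df.columns else True)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"quarantined {n_bad} row(s) violating tree invariants")
    quarantined = df[bad]
    df = df[~bad].reset_index(drop=True)
    df = _derive_columns(df)
    df.attrs["quarantined"] = quarantined
    return df


def _derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    derived = {}

    def have(c):
        return c in df.columns and df[c].notna().all()

    if not have("trunk_mass") and have("stem_mass"):
        bark = df["bark_mass"] if have("bark_mass") else 0.0
        df["trunk_mass"] = df["stem_mass"] + bark
        derived["trunk_mass"] = "stem_mass + bark_mass"
    if not have("aboveground_mass") and have("trunk_mass"):
        extra = sum((df[c] for c in ("branch_mass", "foliage_mass") if have(c)),
                    start=pd.Series(0.0, index=df.index))
        df["aboveground_mass"] = df["trunk_mass"] + extra
        derived["aboveground_mass"] = "trunk_mass + branch_mass + foliage_mass"
    if not have("TB") and have("aboveground_mass"):
        roots = sum((df[c] for c in ("stump_mass", "coarse_root_mass",
                                     "middle_root_mass", "small_root_mass")
                     if have(c)), start=pd.Series(0.0, index=df.index))
        df["TB"] = df["aboveground_mass"] + roots
        derived["TB"] = "aboveground_mass + root components"
    if not have("V") and have("H"):
        df["V"] = [taper_volume(d, h) for d, h in zip(df["D"], df["H"])]
        derived["V"] = "taper model integral of (D, H)"
    if not have("WD") and have("trunk_mass") and have("V"):
        df["WD"] = df["trunk_mass"] / df["V"]
        derived["WD"] = "trunk_mass / V"
    if not have("BEF") and have("aboveground_mass") and have("trunk_mass"):
        df["BEF"] = df["aboveground_mass"] / df["trunk_mass"]
        derived["BEF"] = "aboveground_mass / trunk_mass"
    if not have("BCEF") and have("BEF") and have("WD"):
        df["BCEF"] = df["BEF"] * df["WD"]
        derived["BCEF"] = "BEF * WD"
    if not have("G"):
        df["G"] = np.pi * (df["D"] / 200.0) ** 2
        derived["G"] = "pi * (D/200)^2"
    df.attrs["derived"] = derived
    return df


def fit_results_table(results: Sequence[FitResult]) -> pd.DataFrame:
    """One row per model in the published reference-table layout."""
    from .catalogue import get_model
    rows = []
    for r in results:
        row = {"id": r.model_id, "formula": "", "n": r.n, "converged": r.converged}
        try:
            row["formula"] = get_model(r.model_id).formula
        except Exception:
            pass
        for i, name in enumerate("abcde"):
            if r.converged and r.params is not None and i < len(r.params):
                row[name] = float(r.params[i])
            else:
                row[name] = np.nan
        for crit in ("MAB", "RMSE", "ARE", "R2", "AIC", "BIC"):
            row[crit] = r.criteria.get(crit, np.nan) if r.converged else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(results, path, format: str = "csv") -> None:
    """Serialize fit results (or any DataFrame) deterministically.

    CSV keeps 12 significant digits so a read round-trips losslessly at that
    precision; JSON uses pandas' table-free records orientation.
    """
    if isinstance(results, pd.DataFrame):
        table = results
    else:
        results = list(results)
        if not results:
            raise ValueError("no results to write")
        table = fit_results_table(results)
    if len(table) == 0:
        raise ValueError("no results to write")
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        path.write_text(json.dumps(
            json.loads(table.to_json(orient="records", double_precision=12)),
            indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
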