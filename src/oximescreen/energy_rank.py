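"""Two-layer subtractive energy arithmetic, delta-vs-reference energetics,
threshold counting, ranking, and quartile-based candidate selection.

Energy tables are pandas frames with columns
``(code, e_oniom2, d_b3lyp, d_mp2, d_op)``; the packaged ``table1.csv``
fixture transcribes the campaign's printed 18-analog table plus its
reference row.  All energies are kcal/mol, distances Angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NumericError, ReferenceLookupError, SchemaError, SizeError

__all__ = [
    "OniomComponents",
    "GapSummary",
    "oniom2_energy",
    "load_energy_table",
    "load_table1",
    "REFERENCE_CODE",
    "delta_vs_reference",
    "count_below",
    "quartile_select",
    "QuartileSelection",
    "rank_and_extremes",
    "RankSummary",
    "gap_difference",
]

REFERENCE_CODE = "2-PAM"

ENERGY_COLUMNS = ("e_oniom2", "d_b3lyp", "d_mp2")


@dataclass(frozen=True)
class OniomComponents:
    """The three terms of the two-layer subtractive extrapolation."""

    e_high_model: float
    e_low_real: float
    e_low_model: float


def oniom2_energy(c: OniomComponents) -> float:
    """E_high_model + E_low_real - E_low_model (the target-energy estimate)."""
    terms = (c.e_high_model, c.e_low_real, c.e_low_model)
    if not all(math.isfinite(t) for t in terms):
        raise NumericError(f"non-finite component in {terms}")
    return c.e_high_model + c.e_low_real - c.e_low_model


def load_energy_table(path) -> pd.DataFrame:
    """Read an energy CSV, normalizing Unicode minus signs to ASCII."""
    df = pd.read_csv(path, dtype=str)
    if "code" not in df.columns:
        raise SchemaError("energy table needs a 'code' column")
    for col in df.columns:
        if col == "code":
            continue
        df[col] = pd.to_numeric(df[col].str.replace("−", "-", regex=False))
    if df["code"].duplicated().any():
        dupes = df.loc[df["code"].duplicated(), "code"].tolist()
        raise ValueError(f"duplicate analog codes in table: {dupes}")
    return df


def load_table1() -> pd.DataFrame:
    """The packaged transcription of the printed 18-analog energy table."""
    ref = resources.files("oximescreen.data") / "table1.csv"
    with resources.as_file(ref) as path:
        return load_energy_table(path)


def _require_columns(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}")


def delta_vs_reference(
    table: pd.DataFrame,
    ref_code: str = REFERENCE_CODE,
    columns: Sequence[str] = ENERGY_COLUMNS,
) -> pd.DataFrame:
    """Add ``delta_<col>`` columns: value minus the reference row's value.

    The reference row's deltas are exactly zero.
    """
    _require_columns(table, ("code", *columns))
    ref_rows = table.loc[table["code"] == ref_code]
    if ref_rows.empty:
        raise ReferenceLookupError(f"reference code {ref_code!r} not in table")
    out = table.copy()
    for col in columns:
        ref_val = float(ref_rows.iloc[0][col])
        out[f"delta_{col}"] = out[col] - ref_val
        out.loc[out["code"] == ref_code, f"delta_{col}"] = 0.0
    return out


def count_below(
    table: pd.DataFrame,
    column: str,
    threshold: float,
    strict: bool = True,
    ref_code: str | None = REFERENCE_CODE,
) -> int:
    """Rows (reference excluded) with value < threshold (or <= if non-strict)."""
    _require_columns(table, (column,))
    values = table[column]
    if ref_code is not None and "code" in table.columns:
        values = values[table["code"] != ref_code]
    if strict:
        return int((values < threshold).sum())
    return int((values <= threshold).sum())


@dataclass(frozen=True)
class QuartileSelection:
    kept: frozenset[str]
    dropped: frozenset[str]
    labels: dict[str, str]
    boundary_affinity: float


def quartile_select(scores: pd.DataFrame) -> QuartileSelection:
    """Partition docking scores into quartiles and drop the worst one.

    ``scores`` has columns (code, affinity); more negative affinity is
    more favorable.  Ranks are assigned after sorting ascending by
    (affinity, code); rank r belongs to Q4 iff r > 3n/4.  A score tied
    with the Q3/Q4 boundary value is kept — only entries strictly worse
    than the boundary are dropped.
    """
    _require_columns(scores, ("code", "affinity"))
    n = len(scores)
    if n < 4:
        raise SizeError(f"need at least 4 scores for quartiles, got {n}")
    ordered = scores.sort_values(["affinity", "code"]).reset_index(drop=True)
    ranks = np.arange(1, n + 1)
    labels_by_rank = np.select(
        [ranks <= n / 4, ranks <= n / 2, ranks <= 3 * n / 4],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    boundary_rank = int(math.floor(3 * n / 4))  # last rank at or below 3n/4
    boundary_affinity = float(ordered.loc[boundary_rank - 1, "affinity"])
    labels: dict[str, str] = {}
    dropped = []
    for i, row in ordered.iterrows():
        labels[row["code"]] = labels_by_rank[i]
        if labels_by_rank[i] == "Q4" and row["affinity"] > boundary_affinity:
            dropped.append(row["code"])
    kept = frozenset(ordered["code"]) - frozenset(dropped)
    return QuartileSelection(
        kept=kept,
        dropped=frozenset(dropped),
        labels=labels,
        boundary_affinity=boundary_affinity,
    )


@dataclass(frozen=True)
class RankSummary:
    ranking: pd.DataFrame
    e_oniom2_min: float
    e_oniom2_max: float
    d_op_min: float
    d_op_max: float


def rank_and_extremes(
    table: pd.DataFrame,
    ref_code: str | None = REFERENCE_CODE,
    rank_column: str = "d_mp2",
) -> RankSummary:
    """Rank analogs by ascending ``rank_column`` (ties broken by code) and
    summarize analog-row extremes of ``e_oniom2`` and ``d_op``."""
    _require_columns(table, ("code", rank_column, "e_oniom2", "d_op"))
    analogs = table if ref_code is None else table.loc[table["code"] != ref_code]
    if analogs.empty:
        raise SizeError("no analog rows to rank")
    ranking = analogs.sort_values([rank_column, "code"]).reset_index(drop=True)
    return RankSummary(
        ranking=ranking,
        e_oniom2_min=float(ranking["e_oniom2"].min()),
        e_oniom2_max=float(ranking["e_oniom2"].max()),
        d_op_min=float(ranking["d_op"].min()),
        d_op_max=float(ranking["d_op"].max()),
    )


@dataclass(frozen=True)
class GapSummary:
    """A labelled HOMO-LUMO gap in kcal/mol (ingested, never computed)."""

    label: str
    e_gap: float

    def __post_init__(self):
        if not self.e_gap > 0:
            raise ValueError(f"e_gap must be positive, got {self.e_gap}")


def gap_difference(ref: GapSummary, analog: GapSummary) -> float:
    """Reference gap minus analog gap (sign preserved)."""
    return ref.e_gap - analog.e_gap
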