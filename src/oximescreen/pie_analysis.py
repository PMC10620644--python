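"""Pair interaction energies, per-residue delta fingerprints, and
interaction-residue consensus sets.

Component tables carry the five decomposition terms per (ligand,
residue): electrostatic, charge-transfer+mix, dispersion, exchange, and
solvation.  Interaction matrices are boolean frames with analog rows and
residue columns; the structural detection that produces them is outside
this module's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import NumericError, SchemaError

__all__ = [
    "PiedaComponents",
    "PieFingerprint",
    "DeltaFingerprint",
    "pie_total",
    "load_pieda_table",
    "fingerprint_from_table",
    "delta_fingerprint",
    "consensus_residues",
]

COMPONENT_COLUMNS = ("e_es", "e_ct_mix", "e_di", "e_ex", "g_sol")


@dataclass(frozen=True)
class PiedaComponents:
    """Decomposed interaction terms between one ligand and one residue."""

    residue: str
    e_es: float
    e_ct_mix: float
    e_di: float
    e_ex: float
    g_sol: float


def pie_total(c: PiedaComponents) -> float:
    """Total pair interaction energy: the sum of the five components."""
    terms = (c.e_es, c.e_ct_mix, c.e_di, c.e_ex, c.g_sol)
    if not all(math.isfinite(t) for t in terms):
        raise NumericError(f"non-finite component for residue {c.residue!r}: {terms}")
    return float(sum(terms))


@dataclass(frozen=True)
class PieFingerprint:
    """Per-residue total interaction energies for one ligand."""

    code: str
    values: Mapping[str, float]


@dataclass(frozen=True)
class DeltaFingerprint:
    """Per-residue PIE differences (analog minus reference).

    Residues present in only one of the two fingerprints are compared
    against zero and flagged in ``one_sided`` ("analog_only" or
    "ref_only") instead of erroring out, since fragmentation lists
    differ per ligand.
    """

    deltas: Mapping[str, float]
    one_sided: Mapping[str, str] = field(default_factory=dict)


def load_pieda_table(path) -> pd.DataFrame:
    """Read a component CSV (ligand, residue, e_es, e_ct_mix, e_di, e_ex, g_sol)."""
    df = pd.read_csv(path)
    missing = [c for c in ("ligand", "residue", *COMPONENT_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}")
    for col in COMPONENT_COLUMNS:
        if df[col].dtype == object:
            df[col] = pd.to_numeric(df[col].str.replace("−", "-", regex=False))
    return df


def fingerprint_from_table(table: pd.DataFrame, ligand: str) -> PieFingerprint:
    """Sum the components of one ligand's rows into a PIE fingerprint."""
    rows = table.loc[table["ligand"] == ligand]
    if rows["residue"].duplicated().any():
        dupes = rows.loc[rows["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residue labels for ligand {ligand!r}: {dupes}")
    values = {
        str(row["residue"]): pie_total(
            PiedaComponents(
                residue=str(row["residue"]),
                **{col: float(row[col]) for col in COMPONENT_COLUMNS},
            )
        )
        for _, row in rows.iterrows()
    }
    return PieFingerprint(code=ligand, values=values)


def delta_fingerprint(fp_analog: PieFingerprint, fp_ref: PieFingerprint) -> DeltaFingerprint:
    """Residue-wise PIE(analog) - PIE(ref), missing entries treated as 0."""
    residues = set(fp_analog.values) | set(fp_ref.values)
    deltas: dict[str, float] = {}
    one_sided: dict[str, str] = {}
    for res in sorted(residues):
        a = fp_analog.values.get(res)
        r = fp_ref.values.get(res)
        if a is None:
            one_sided[res] = "ref_only"
        elif r is None:
            one_sided[res] = "analog_only"
        deltas[res] = (a or 0.0) - (r or 0.0)
    return DeltaFingerprint(deltas=deltas, one_sided=one_sided)


def consensus_residues(matrix: pd.DataFrame, fraction: float = 0.5) -> frozenset[str]:
    """Residues interacting in at least ``fraction`` of the analog rows.

    ``matrix`` has analog rows and residue columns of truthy/falsy cells.
    An empty matrix yields the empty set.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if matrix.empty:
        return frozenset()
    if matrix.columns.duplicated().any() or matrix.index.duplicated().any():
        raise ValueError("interaction matrix has duplicate rows or columns")
    presence = matrix.astype(bool).mean(axis=0)
    return frozenset(presence.index[presence >= fraction].astype(str))
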