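"""Near-attack geometry from 3D coordinates and apical classification.

A pose is reduced to the triplet (oxime oxygen, adduct phosphorus, serine
hydroxyl oxygen).  ``d_op`` is the oxygen-phosphorus distance; ``theta_opo``
is the angle at the phosphorus vertex between the rays to the two oxygens.
A pose is *apical* (near-attack) when ``d_op < d_max`` and
``theta_min < theta_opo <= theta_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .errors import DegenerateGeometryError, SelectionError

__all__ = [
    "AttackTriplet",
    "PoseGeometry",
    "ApicalCriteria",
    "DEFAULT_SELECTOR",
    "compute_geometry",
    "classify_apical",
    "extract_triplets",
    "screen_poses",
]

_EPS = 1e-9

# role -> (residue name, atom name); covalent-adduct naming varies by
# preparation pipeline, so this is configuration, not convention.
DEFAULT_SELECTOR: dict[str, tuple[str, str]] = {
    "o_oxime": ("LIG", "O1"),
    "p_paraoxon": ("POX", "P"),
    "o_serine": ("SER", "OG"),
}


@dataclass(frozen=True)
class AttackTriplet:
    """The three attack-geometry atoms of one pose, in Angstroms."""

    o_oxime: np.ndarray
    p_paraoxon: np.ndarray
    o_serine: np.ndarray
    pose_id: str = ""

    def __post_init__(self):
        for name in ("o_oxime", "p_paraoxon", "o_serine"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class PoseGeometry:
    d_op: float
    theta_opo: float
    apical: bool = False
    pose_id: str = ""

    def __post_init__(self):
        if not self.d_op > 0:
            raise ValueError(f"d_op must be positive, got {self.d_op}")
        if not 0.0 <= self.theta_opo <= 180.0:
            raise ValueError(f"theta_opo out of [0, 180]: {self.theta_opo}")


@dataclass(frozen=True)
class ApicalCriteria:
    """d_op < d_max (strict) and theta_min < theta <= theta_max.

    180 deg is included although it is the in-line ideal attainable only
    as a boundary; both bounds are configurable.
    """

    d_max: float = 8.0
    theta_min: float = 120.0
    theta_max: float = 180.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not self.theta_min < self.theta_max:
            raise ValueError("theta_min must be below theta_max")


def compute_geometry(triplet: AttackTriplet, criteria: ApicalCriteria | None = None) -> PoseGeometry:
    """Distance and vertex angle for one triplet.

    The angle is taken at ``p_paraoxon`` between rays to ``o_oxime`` and
    ``o_serine``.  Coincident points raise
    :class:`~oximescreen.errors.DegenerateGeometryError`.
    """
    u = triplet.o_oxime - triplet.p_paraoxon
    v = triplet.o_serine - triplet.p_paraoxon
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError(
            f"pose {triplet.pose_id!r}: coincident points (|u|={nu:g}, |v|={nv:g})"
        )
    cos_theta = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    geom = PoseGeometry(d_op=float(nu), theta_opo=theta, pose_id=triplet.pose_id)
    if criteria is not None:
        geom = PoseGeometry(
            d_op=geom.d_op,
            theta_opo=geom.theta_opo,
            apical=classify_apical(geom, criteria),
            pose_id=geom.pose_id,
        )
    return geom


def classify_apical(geom: PoseGeometry, criteria: ApicalCriteria | None = None) -> bool:
    criteria = criteria or ApicalCriteria()
    return (
        geom.d_op < criteria.d_max
        and criteria.theta_min < geom.theta_opo <= criteria.theta_max
    )


def _select_atom(model, role: str, resname: str, atom_name: str) -> np.ndarray:
    matches = []
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip() != resname:
                continue
            for atom in residue:
                if atom.get_name().strip() == atom_name:
                    # first alt-loc only, by policy
                    if atom.is_disordered():
                        atom = atom.disordered_get_list()[0]
                    matches.append(atom)
    if len(matches) != 1:
        raise SelectionError(
            role,
            f"role {role!r} (residue {resname!r}, atom {atom_name!r}) matched "
            f"{len(matches)} atoms, need exactly 1",
        )
    return np.asarray(matches[0].get_coord(), dtype=float)


def extract_triplets(
    pdb_path,
    selector: Mapping[str, tuple[str, str]] | None = None,
) -> list[AttackTriplet]:
    """Read one PDB file into one triplet per MODEL record."""
    selector = dict(selector or DEFAULT_SELECTOR)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(pdb_path).stem, str(pdb_path))
    models = list(structure)
    triplets = []
    for model in models:
        pose_id = Path(pdb_path).stem
        if len(models) > 1:
            pose_id = f"{pose_id}#m{model.id}"
        coords = {
            role: _select_atom(model, role, resname, atom_name)
            for role, (resname, atom_name) in selector.items()
        }
        triplets.append(AttackTriplet(pose_id=pose_id, **coords))
    return triplets


def screen_poses(
    pdb_paths: Sequence,
    selector: Mapping[str, tuple[str, str]] | None = None,
    criteria: ApicalCriteria | None = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Geometry + apical classification for a set of pose files.

    Returns a frame with columns (pose_id, d_op, theta_opo, apical).
    With ``on_error="report"`` a pose whose atom selection fails is kept
    as a row with NaN geometry and the failing role in ``error`` instead
    of aborting the screen.
    """
    if on_error not in ("raise", "report"):
        raise ValueError("on_error must be 'raise' or 'report'")
    criteria = criteria or ApicalCriteria()
    rows = []
    for path in pdb_paths:
        try:
            triplets = extract_triplets(path, selector)
        except SelectionError as exc:
            if on_error == "raise":
                raise
            rows.append(
                {
                    "pose_id": Path(path).stem,
                    "d_op": np.nan,
                    "theta_opo": np.nan,
                    "apical": False,
                    "error": exc.role,
                }
            )
            continue
        for triplet in triplets:
            geom = compute_geometry(triplet, criteria)
            rows.append(
                {
                    "pose_id": geom.pose_id,
                    "d_op": geom.d_op,
                    "theta_opo": geom.theta_opo,
                    "apical": geom.apical,
                    "error": "",
                }
            )
    columns = ["pose_id", "d_op", "theta_opo", "apical", "error"]
    return pd.DataFrame(rows, columns=columns)
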