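"""Analog enumeration and CNS drug-likeness filtering.

The parent scaffold is 1-methylpyridinium-2-aldoxime.  Electron-donating
groups from a configurable registry are grafted at the ring carbon *para*
to the aldoxime-bearing carbon (R1) and/or *ortho* to it (R2).  Analogs
are identified by ``"R1-R2"`` codes with ``0`` meaning unsubstituted, so
``"0-0"`` is the parent itself.

Descriptor computation delegates to RDKit; the blood-brain-barrier flag
is a documented surrogate rule (see :func:`bbb_surrogate`), overridable
by an ingested column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .errors import RegistryError, SmilesParseError, StructureError

__all__ = [
    "Substituent",
    "SubstituentRegistry",
    "AnalogSpec",
    "DescriptorProfile",
    "CnsCriteria",
    "FilterVerdict",
    "enumerate_analogs",
    "build_smiles",
    "compute_descriptors",
    "bbb_surrogate",
    "apply_cns_filter",
    "load_profiles_csv",
    "verdicts_to_frame",
]

PARENT_SMILES = "C[n+]1ccccc1C=NO"

STRENGTH_CLASSES = ("weak", "moderate", "strong")


@dataclass(frozen=True)
class Substituent:
    """One registry entry: an EDG fragment graftable onto the scaffold."""

    id: int
    label: str
    strength: str
    fragment: str
    authoritative: bool = False

    def __post_init__(self):
        if self.strength not in STRENGTH_CLASSES:
            raise RegistryError(
                f"substituent {self.id}: strength {self.strength!r} not in "
                f"{STRENGTH_CLASSES}"
            )
        if self.id < 1:
            raise RegistryError(f"substituent ids are positive, got {self.id}")


class SubstituentRegistry:
    """Mapping of integer ids to :class:`Substituent` entries."""

    def __init__(self, substituents: Iterable[Substituent]):
        self._entries: dict[int, Substituent] = {}
        for sub in substituents:
            if sub.id in self._entries:
                raise RegistryError(f"duplicate substituent id {sub.id}")
            self._entries[sub.id] = sub

    @classmethod
    def from_yaml(cls, path) -> "SubstituentRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(Substituent(**entry) for entry in doc["substituents"])

    @classmethod
    def default(cls) -> "SubstituentRegistry":
        ref = resources.files("oximescreen.data") / "registry.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    @property
    def ids(self) -> frozenset[int]:
        return frozenset(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries.values(), key=lambda s: s.id))

    def __contains__(self, sid: int) -> bool:
        return sid in self._entries

    def __getitem__(self, sid: int) -> Substituent:
        try:
            return self._entries[sid]
        except KeyError:
            raise RegistryError(f"unknown substituent id {sid!r}") from None

    def strength_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in STRENGTH_CLASSES}
        for sub in self._entries.values():
            counts[sub.strength] += 1
        return counts


@dataclass(frozen=True, order=True)
class AnalogSpec:
    """Identity of one analog: substituent ids at R1 (para) and R2 (ortho)."""

    r1: int | None = None
    r2: int | None = None

    @property
    def code(self) -> str:
        return f"{self.r1 or 0}-{self.r2 or 0}"

    @classmethod
    def from_code(cls, code: str) -> "AnalogSpec":
        try:
            a, b = code.split("-")
            r1, r2 = int(a), int(b)
        except ValueError:
            raise ValueError(f"malformed analog code {code!r}") from None
        return cls(r1 or None, r2 or None)

    @property
    def is_parent(self) -> bool:
        return self.r1 is None and self.r2 is None


def enumerate_analogs(
    r1_ids: Iterable[int] | None,
    r2_ids: Iterable[int] | None,
    mode: str = "combined",
    registry: SubstituentRegistry | None = None,
) -> list[AnalogSpec]:
    """Enumerate single-position or combined (Cartesian product) analogs.

    ``single`` yields one analog per (position, id); ``combined`` yields
    the full ``r1 x r2`` product.  Output is sorted by code and free of
    duplicates.
    """
    if mode not in ("single", "combined"):
        raise ValueError(f"mode must be 'single' or 'combined', got {mode!r}")
    registry = registry or SubstituentRegistry.default()
    r1_ids = sorted(set(r1_ids or ()))
    r2_ids = sorted(set(r2_ids or ()))
    for sid in (*r1_ids, *r2_ids):
        if sid not in registry:
            raise RegistryError(f"unknown substituent id {sid!r}")
    if mode == "single":
        specs = {AnalogSpec(r1=i) for i in r1_ids} | {AnalogSpec(r2=j) for j in r2_ids}
    else:
        specs = {AnalogSpec(r1=i, r2=j) for i, j in product(r1_ids, r2_ids)}
    return sorted(specs, key=lambda a: a.code)


def build_smiles(analog: AnalogSpec, registry: SubstituentRegistry | None = None) -> str:
    """Canonical SMILES of the scaffold with the analog's grafts applied.

    The aldoxime carbon is ring position 2; R2 grafts ortho to it (C3)
    and R1 para to it (C5).  Deterministic for a fixed registry.
    """
    registry = registry or SubstituentRegistry.default()
    r2_branch = f"({registry[analog.r2].fragment})" if analog.r2 else ""
    r1_branch = f"({registry[analog.r1].fragment})" if analog.r1 else ""
    raw = f"C[n+]1c(C=NO)c{r2_branch}cc{r1_branch}c1"
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureError(f"graft for analog {analog.code} produced invalid SMILES {raw!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class DescriptorProfile:
    """Drug-likeness descriptors for one molecule.

    ``code`` is optional plumbing so verdicts can name their analog.
    """

    mw: float
    hbd: int
    hba: int
    rotatable_bonds: int
    clogp: float
    psa: float
    heavy_atoms: int
    bbb_permeant: bool
    code: str = ""

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        for name in ("hbd", "hba", "rotatable_bonds", "heavy_atoms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def bbb_surrogate(psa: float, clogp: float) -> bool:
    """Deterministic stand-in for an external BBB classifier.

    Permeant iff ``psa <= 79`` and ``0.4 <= clogp <= 6`` (an egg-style
    physicochemical box).  Ingested BBB columns override this rule.
    """
    return psa <= 79.0 and 0.4 <= clogp <= 6.0


def compute_descriptors(smiles: str, code: str = "") -> DescriptorProfile:
    """Compute a :class:`DescriptorProfile` with RDKit."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES {smiles!r}")
    psa = Descriptors.TPSA(mol)
    clogp = Crippen.MolLogP(mol)
    return DescriptorProfile(
        mw=Descriptors.MolWt(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        clogp=clogp,
        psa=psa,
        heavy_atoms=mol.GetNumHeavyAtoms(),
        bbb_permeant=bbb_surrogate(psa, clogp),
        code=code,
    )


@dataclass(frozen=True)
class CnsCriteria:
    """Inclusive-threshold CNS drug-likeness criteria.

    Defaults follow the screening thresholds as printed: MW <= 450 Da,
    HBD <= 7, HBA <= 3, cLogP <= 5, PSA <= 70 A^2 (permissive end of the
    printed 60-70 range), 12 <= heavy atoms <= 30, BBB permeant.
    """

    mw_max: float = 450.0
    hbd_max: int = 7
    hba_max: int = 3
    clogp_max: float = 5.0
    psa_max: float = 70.0
    heavy_min: int = 12
    heavy_max: int = 30
    require_bbb: bool = True

    def __post_init__(self):
        if self.heavy_min > self.heavy_max:
            raise ValueError("heavy_min must not exceed heavy_max")


# (criterion name, predicate) in fixed reporting order
_CRITERIA = (
    ("mw_max", lambda p, c: p.mw <= c.mw_max),
    ("hbd_max", lambda p, c: p.hbd <= c.hbd_max),
    ("hba_max", lambda p, c: p.hba <= c.hba_max),
    ("clogp_max", lambda p, c: p.clogp <= c.clogp_max),
    ("psa_max", lambda p, c: p.psa <= c.psa_max),
    ("heavy_min", lambda p, c: p.heavy_atoms >= c.heavy_min),
    ("heavy_max", lambda p, c: p.heavy_atoms <= c.heavy_max),
    ("bbb", lambda p, c: (not c.require_bbb) or p.bbb_permeant),
)

CRITERION_NAMES = tuple(name for name, _ in _CRITERIA)


@dataclass(frozen=True)
class FilterVerdict:
    code: str
    passed: bool
    violations: tuple[str, ...] = ()

    def __post_init__(self):
        if self.passed != (len(self.violations) == 0):
            raise ValueError("passed must equal 'violations empty'")


def apply_cns_filter(
    profiles: Sequence[DescriptorProfile],
    criteria: CnsCriteria | None = None,
) -> list[FilterVerdict]:
    """Evaluate each profile against every criterion (inclusive bounds)."""
    criteria = criteria or CnsCriteria()
    verdicts = []
    for prof in profiles:
        violations = tuple(
            name for name, pred in _CRITERIA if not pred(prof, criteria)
        )
        verdicts.append(
            FilterVerdict(code=prof.code, passed=not violations, violations=violations)
        )
    return verdicts


def load_profiles_csv(path) -> list[DescriptorProfile]:
    """Ingest a descriptor table (code, mw, hbd, hba, rotatable_bonds,
    clogp, psa, heavy_atoms[, bbb_permeant]).

    A missing ``bbb_permeant`` column falls back to :func:`bbb_surrogate`.
    """
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        if "bbb_permeant" in df.columns:
            bbb = bool(row["bbb_permeant"])
        else:
            bbb = bbb_surrogate(float(row["psa"]), float(row["clogp"]))
        profiles.append(
            DescriptorProfile(
                mw=float(row["mw"]),
                hbd=int(row["hbd"]),
                hba=int(row["hba"]),
                rotatable_bonds=int(row.get("rotatable_bonds", 0)),
                clogp=float(row["clogp"]),
                psa=float(row["psa"]),
                heavy_atoms=int(row["heavy_atoms"]),
                bbb_permeant=bbb,
                code=str(row.get("code", "")),
            )
        )
    return profiles


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "code": [v.code for v in verdicts],
            "passed": [v.passed for v in verdicts],
            "violations": [";".join(v.violations) for v in verdicts],
        }
    )
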