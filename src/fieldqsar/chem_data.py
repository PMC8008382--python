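"""Molecular structures, activities and dataset containers.

This module reads and writes small-molecule 3D structures (Tripos MOL2 and
SDF V2000), attaches measured potencies to them, applies the negative
log10 transform (pIC50 convention) and splits training/test sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "ActivityRecord",
    "QsarDataset",
    "read_molecules",
    "write_molecules",
    "read_activity_table",
    "attach_activities",
    "check_activity_range",
    "split_train_test",
    "UNIT_FACTORS",
]

#: Conversion factors from the supported concentration units to mol/L.
UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

MIN_TRAINING_RECOMMENDED = 15


class ParseError(ValueError):
    """Raised when a structure file record cannot be parsed."""


@dataclass
class Atom:
    """A single atom: element, Sybyl atom type, 3D position and charge.

    ``partial_charge`` is ``None`` when the source file carried no charge
    information; such molecules are flagged and refused by the
    electrostatic field computation.
    """

    element: str
    sybyl_type: str
    coords: np.ndarray
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.sybyl_type:
            raise ValueError("sybyl_type must be non-empty")


@dataclass
class Molecule:
    """An ordered collection of atoms plus bonds.

    Bonds are ``(i, j, order)`` triples with 0-based atom indices; aromatic
    bonds are stored with order 4 (Tripos 'ar' convention).
    """

    mol_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.mol_id!r} has no atoms")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"molecule {self.mol_id!r}: bond index ({i},{j}) out of range"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges_missing(self) -> bool:
        return any(a.partial_charge is None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def charges_array(self) -> np.ndarray:
        if self.charges_missing:
            raise ValueError(f"molecule {self.mol_id!r} lacks partial charges")
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of this molecule with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.element, a.sybyl_type, coords[k].copy(), a.partial_charge)
            for k, a in enumerate(self.atoms)
        ]
        return Molecule(self.mol_id, atoms, list(self.bonds), self.name)


@dataclass
class ActivityRecord:
    """A measured potency with its negative-log10 transform.

    ``raw_value`` is a concentration in mol/L; ``p_value`` is
    -log10(raw_value), so larger means more potent.
    """

    mol_id: str
    raw_value: float
    measure: str = "other"
    p_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw_value <= 0:
            raise ValueError(
                f"activity for {self.mol_id!r} must be positive, got {self.raw_value}"
            )
        p = -math.log10(self.raw_value)
        if self.p_value is None:
            self.p_value = p
        elif abs(self.p_value - p) > 1e-12:
            raise ValueError(
                f"p_value for {self.mol_id!r} inconsistent with raw_value"
            )


@dataclass
class QsarDataset:
    """Molecules with activities and training/test roles."""

    molecules: list[Molecule]
    activities: dict[str, ActivityRecord] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.mol_id for m in self.molecules]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate mol_id(s): {sorted(dup)}")

    @property
    def N(self) -> int:
        return len(self.molecules)

    @property
    def mol_ids(self) -> list[str]:
        return [m.mol_id for m in self.molecules]

    def molecule(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.mol_id == mol_id:
                return m
        raise KeyError(mol_id)

    def subset(self, role: str) -> "QsarDataset":
        """Training or test subset (roles must be assigned)."""
        mols = [m for m in self.molecules if self.roles.get(m.mol_id) == role]
        acts = {m.mol_id: self.activities[m.mol_id] for m in mols
                if m.mol_id in self.activities}
        return QsarDataset(mols, acts, {m.mol_id: role for m in mols})

    def p_values(self, mol_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.mol_ids if mol_ids is None else list(mol_ids)
        missing = [i for i in ids if i not in self.activities]
        if missing:
            raise KeyError(f"no activity for: {missing}")
        return np.array([self.activities[i].p_value for i in ids], dtype=float)


# ---------------------------------------------------------------------------
# MOL2 reading / writing
#
# The Tripos MOL2 format is plain text with @<TRIPOS> record headers; the
# ATOM section carries the Sybyl atom type in column 6 and the partial
# charge in column 9.  The writer emits the same three sections it reads
# so that round trips preserve coordinates, types and charges.

def _parse_mol2_blocks(text: str) -> list[list[str]]:
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>MOLECULE"):
            current = [line]
            blocks.append(current)
        elif current is not None:
            current.append(line)
    return blocks


def _parse_mol2_molecule(block: list[str], index: int) -> Molecule:
    sections: dict[str, list[str]] = {}
    name = None
    current = "MOLECULE"
    sections[current] = []
    for line in block[1:]:
        if line.startswith("@<TRIPOS>"):
            current = line.strip()[len("@<TRIPOS>"):]
            sections[current] = []
        else:
            sections[current].append(line)
    mol_lines = [l for l in sections.get("MOLECULE", [])]
    if not mol_lines or not mol_lines[0].strip():
        raise ParseError(f"MOL2 record {index}: missing molecule name line")
    name = mol_lines[0].strip()
    try:
        counts = mol_lines[1].split()
        n_atoms = int(counts[0])
        n_bonds = int(counts[1]) if len(counts) > 1 else 0
    except (IndexError, ValueError) as exc:
        raise ParseError(f"MOL2 record {index}: bad counts line") from exc

    atoms: list[Atom] = []
    charge_type = mol_lines[3].strip() if len(mol_lines) > 3 else ""
    no_charges = charge_type.upper() == "NO_CHARGES"
    atom_lines = [l for l in sections.get("ATOM", []) if l.strip()]
    if len(atom_lines) < n_atoms:
        raise ParseError(
            f"MOL2 record {index}: expected {n_atoms} atoms, found {len(atom_lines)}"
        )
    for l in atom_lines[:n_atoms]:
        parts = l.split()
        try:
            x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            sybyl = parts[5]
            charge = None
            if not no_charges and len(parts) >= 9:
                charge = float(parts[8])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"MOL2 record {index}: bad atom line {l!r}") from exc
        element = sybyl.split(".")[0]
        atoms.append(Atom(element, sybyl, np.array([x, y, z]), charge))

    bonds: list[tuple[int, int, int]] = []
    bond_lines = [l for l in sections.get("BOND", []) if l.strip()]
    for l in bond_lines[:n_bonds]:
        parts = l.split()
        try:
            i, j = int(parts[1]) - 1, int(parts[2]) - 1
            order_s = parts[3]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"MOL2 record {index}: bad bond line {l!r}") from exc
        order = {"ar": 4, "am": 1, "du": 1, "un": 1, "nc": 0}.get(
            order_s, None
        )
        if order is None:
            try:
                order = int(order_s)
            except ValueError as exc:
                raise ParseError(
                    f"MOL2 record {index}: unknown bond type {order_s!r}"
                ) from exc
        bonds.append((i, j, order))

    return Molecule(mol_id=name, atoms=atoms, bonds=bonds, name=name)


def _read_mol2(path: Path) -> list[Molecule]:
    blocks = _parse_mol2_blocks(path.read_text())
    return [_parse_mol2_molecule(b, k) for k, b in enumerate(blocks)]


_BOND_TYPE_STR = {4: "ar", 0: "nc"}


def write_molecules(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as a multi-record Tripos MOL2 file."""
    lines: list[str] = []
    for mol in molecules:
        charges = "NO_CHARGES" if mol.charges_missing else "USER_CHARGES"
        lines.append("@<TRIPOS>MOLECULE")
        lines.append(mol.mol_id)
        lines.append(f"{mol.n_atoms} {len(mol.bonds)} 0 0 0")
        lines.append("SMALL")
        lines.append(charges)
        lines.append("@<TRIPOS>ATOM")
        for k, a in enumerate(mol.atoms, start=1):
            q = 0.0 if a.partial_charge is None else a.partial_charge
            lines.append(
                f"{k:>7d} {a.element}{k:<4} "
                f"{a.coords[0]:>12.6f} {a.coords[1]:>12.6f} {a.coords[2]:>12.6f} "
                f"{a.sybyl_type:<8} 1 UNL {q:>10.6f}"
            )
        lines.append("@<TRIPOS>BOND")
        for k, (i, j, order) in enumerate(mol.bonds, start=1):
            ts = _BOND_TYPE_STR.get(order, str(order))
            lines.append(f"{k:>6d} {i + 1:>5d} {j + 1:>5d} {ts:>4}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SDF V2000 (via RDKit)

_SDF_CHARGE_PROPS = ("PARTIAL_CHARGES", "atom.dprop.PartialCharge")


def _read_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    molecules: list[Molecule] = []
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"SDF record {k}: unreadable")
        try:
            Chem.SanitizeMol(rdmol)
        except Exception:
            pass  # keep unsanitizable records; types fall back to element
        if rdmol.GetNumConformers() == 0:
            raise ParseError(f"SDF record {k}: no 3D coordinates")
        conf = rdmol.GetConformer()
        charges = _sdf_charges(rdmol)
        atoms = []
        for a in rdmol.GetAtoms():
            pos = conf.GetAtomPosition(a.GetIdx())
            atoms.append(
                Atom(
                    element=a.GetSymbol(),
                    sybyl_type=_sybyl_type(a),
                    coords=np.array([pos.x, pos.y, pos.z]),
                    partial_charge=None if charges is None else charges[a.GetIdx()],
                )
            )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             4 if b.GetIsAromatic() else int(b.GetBondTypeAsDouble()))
            for b in rdmol.GetBonds()
        ]
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"sdf_{k}"
        molecules.append(Molecule(mol_id, atoms, bonds, name=mol_id))
    return molecules


def _sdf_charges(rdmol) -> list[float] | None:
    """Per-atom partial charges from an SDF property block, if present."""
    for prop in _SDF_CHARGE_PROPS:
        if rdmol.HasProp(prop):
            vals = [float(v) for v in rdmol.GetProp(prop).split()]
            if len(vals) == rdmol.GetNumAtoms():
                return vals
    return None


def _sybyl_type(rdatom) -> str:
    """Minimal element+hybridization mapping to a Sybyl type string."""
    from rdkit.Chem import HybridizationType

    sym = rdatom.GetSymbol()
    if sym in ("H", "F", "Cl", "Br", "I"):
        return sym
    hyb = rdatom.GetHybridization()
    if rdatom.GetIsAromatic():
        return f"{sym}.ar"
    suffix = {
        HybridizationType.SP3: "3",
        HybridizationType.SP2: "2",
        HybridizationType.SP: "1",
    }.get(hyb, "3")
    return f"{sym}.{suffix}"


def read_molecules(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read a multi-molecule structure file.

    Parameters
    ----------
    path
        MOL2 or SDF file.
    format
        ``"mol2"`` or ``"sdf"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "mol2":
        mols = _read_mol2(path)
    elif format in ("sdf", "sd", "mol"):
        mols = _read_sdf(path)
    else:
        raise ValueError(f"unsupported format: {format!r}")
    if not mols:
        raise ValueError(f"no molecules found in {path}")
    flagged = [m.mol_id for m in mols if m.charges_missing]
    if flagged:
        warnings.warn(
            f"molecules lacking partial charges (electrostatic fields will be "
            f"refused): {flagged}",
            stacklevel=2,
        )
    return mols


# ---------------------------------------------------------------------------
# Activities

def read_activity_table(path: str | Path) -> list[tuple[str, float, str]]:
    """Read a CSV/TSV activity table with header ``mol_id,value,unit``."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"mol_id", "value", "unit"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    return [
        (str(r.mol_id), float(r.value), str(r.unit)) for r in df.itertuples()
    ]


def attach_activities(
    ds: QsarDataset, table: Iterable[tuple[str, float, str]],
    measure: str = "other",
) -> QsarDataset:
    """Attach potencies to a dataset, converting to mol/L and p-transforming.

    Each row is ``(mol_id, value, unit)`` with unit one of M, mM, µM (uM),
    nM, pM.  The stored ``p_value`` is -log10 of the molar concentration,
    so positive model coefficients associate with improved activity.
    """
    known = set(ds.mol_ids)
    for mol_id, value, unit in table:
        if mol_id not in known:
            raise KeyError(f"activity for unknown mol_id {mol_id!r}")
        if unit not in UNIT_FACTORS:
            raise ValueError(
                f"unknown unit {unit!r}; supported: {sorted(set(UNIT_FACTORS))}"
            )
        if value <= 0:
            raise ValueError(f"non-positive activity for {mol_id!r}: {value}")
        molar = value * UNIT_FACTORS[unit]
        ds.activities[mol_id] = ActivityRecord(mol_id, molar, measure)
    return ds


def check_activity_range(ds: QsarDataset) -> tuple[float, bool]:
    """Span of p-values and whether it is below the 2-log recommendation.

    Returns ``(span, warn)``; a span under 2 log units risks a model that
    cannot distinguish signal from experimental variability.
    """
    if len(ds.activities) < 2:
        raise ValueError("need at least 2 activities to compute a range")
    p = np.array([a.p_value for a in ds.activities.values()])
    span = float(p.max() - p.min())
    warn = span < 2.0
    if warn:
        warnings.warn(
            f"activity span {span:.2f} log units is below the recommended 2.0",
            stacklevel=2,
        )
    return span, warn


def split_train_test(
    ds: QsarDataset, test_fraction: float, seed: int
) -> QsarDataset:
    """Assign training/test roles by seeded sampling without replacement."""
    if not (0 <= test_fraction < 1):
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = ds.mol_ids
    n_test = int(round(test_fraction * len(ids)))
    n_train = len(ids) - n_test
    if n_train < 2:
        raise ValueError("training set would have fewer than 2 molecules")
    test_ids = set(rng.choice(ids, size=n_test, replace=False)) if n_test else set()
    ds.roles = {i: ("test" if i in test_ids else "training") for i in ids}
    if n_train < MIN_TRAINING_RECOMMENDED:
        warnings.warn(
            f"training set has {n_train} molecules; at least "
            f"{MIN_TRAINING_RECOMMENDED} are recommended",
            stacklevel=2,
        )
    return ds
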