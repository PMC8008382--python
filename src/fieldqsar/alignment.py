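"""Template selection and rigid-body molecular superposition.

Alignment proceeds by picking a template molecule from the training set
(most active, least active, or most flexible) and superposing every other
molecule onto it with a least-squares (Kabsch) fit over a supplied or
substructure-derived atom mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_data import Molecule, QsarDataset

__all__ = [
    "AtomMapping",
    "RigidTransform",
    "select_template",
    "rotatable_bond_count",
    "kabsch_superpose",
    "align_training_set",
    "mcs_mapping",
    "read_mappings",
]

log = logging.getLogger(__name__)

TEMPLATE_STRATEGIES = ("most_active", "least_active", "most_flexible")


@dataclass
class AtomMapping:
    """Pairs of (mobile atom index, template atom index) for one molecule."""

    mol_id: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError(
                f"mapping for {self.mol_id!r} needs >= 3 pairs, got {len(self.pairs)}"
            )
        mobile = [p[0] for p in self.pairs]
        template = [p[1] for p in self.pairs]
        if len(set(mobile)) != len(mobile) or len(set(template)) != len(template):
            raise ValueError(f"mapping for {self.mol_id!r} repeats an atom index")


@dataclass
class RigidTransform:
    """Proper rotation + translation; `apply` maps mobile coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rotatable_bond_count(mol: Molecule) -> int:
    """Single, acyclic, non-terminal bonds between heavy atoms.

    A bond is terminal when either end has fewer than two heavy-atom
    neighbours; ring membership is decided on the heavy-atom bond graph.
    """
    heavy = [k for k, a in enumerate(mol.atoms) if a.element != "H"]
    heavy_set = set(heavy)
    adj: dict[int, set[int]] = {k: set() for k in heavy}
    for i, j, _ in mol.bonds:
        if i in heavy_set and j in heavy_set:
            adj[i].add(j)
            adj[j].add(i)

    def in_ring(i: int, j: int) -> bool:
        # bond (i, j) is in a ring iff j stays reachable from i without it
        seen = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if (u, v) in ((i, j), (j, i)):
                    continue
                if v == j:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    count = 0
    for i, j, order in mol.bonds:
        if order != 1 or i not in heavy_set or j not in heavy_set:
            continue
        if len(adj[i]) < 2 or len(adj[j]) < 2:
            continue
        if not in_ring(i, j):
            count += 1
    return count


def select_template(ds: QsarDataset, strategy: str) -> str:
    """Pick the alignment template; ties break to the lexicographically
    first mol_id."""
    if ds.N == 0:
        raise ValueError("empty dataset")
    if strategy not in TEMPLATE_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {TEMPLATE_STRATEGIES}"
        )
    ids = sorted(ds.mol_ids)
    if strategy == "most_flexible":
        scores = {i: rotatable_bond_count(ds.molecule(i)) for i in ids}
        return max(ids, key=lambda i: (scores[i], ))  # max, first id on ties
    p = {i: ds.activities[i].p_value for i in ids}
    if strategy == "most_active":
        return max(ids, key=lambda i: p[i])
    return min(ids, key=lambda i: p[i])


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray,
    mapping: AtomMapping | None = None,
) -> RigidTransform:
    """Least-squares rigid superposition of mapped points (SVD, reflection
    corrected).

    ``mobile`` and ``reference`` are full coordinate sets; when ``mapping``
    is given, only the mapped pairs drive the fit.  The returned transform
    maps mobile coordinates onto the reference frame; its ``rmsd`` is the
    post-fit value over the mapped pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mapping is None:
        if mobile.shape != reference.shape:
            raise ValueError("coordinate shapes differ and no mapping given")
        A, B = mobile, reference
    else:
        mi = [p[0] for p in mapping.pairs]
        ti = [p[1] for p in mapping.pairs]
        A, B = mobile[mi], reference[ti]
    if len(A) < 3:
        raise ValueError("need >= 3 mapped pairs")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinear mapped points leave rotation about the line undetermined
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise ValueError("mapped points are collinear; superposition is degenerate")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    fitted = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - B) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def align_training_set(
    ds: QsarDataset, template: str, mappings: list[AtomMapping]
) -> QsarDataset:
    """Rigidly superpose every molecule onto the template.

    Every non-template molecule needs a mapping; the full coordinate set of
    each molecule is transformed by its fitted transform, the template is
    left untouched, and the per-molecule rmsd is logged.
    """
    by_id = {m.mol_id: m for m in mappings}
    ref = ds.molecule(template)
    missing = [m.mol_id for m in ds.molecules
               if m.mol_id != template and m.mol_id not in by_id]
    if missing:
        raise ValueError(f"no atom mapping for molecule(s): {missing}")

    aligned: list[Molecule] = []
    for mol in ds.molecules:
        if mol.mol_id == template:
            aligned.append(mol)
            continue
        tr = kabsch_superpose(
            mol.coords_array(), ref.coords_array(), by_id[mol.mol_id]
        )
        log.info("aligned %s onto %s: rmsd %.4f A", mol.mol_id, template, tr.rmsd)
        aligned.append(mol.with_coords(tr.apply(mol.coords_array())))
    return QsarDataset(aligned, dict(ds.activities), dict(ds.roles))


def mcs_mapping(mobile: Molecule, template: Molecule,
                timeout: int = 10) -> AtomMapping:
    """Derive an atom mapping from the maximum common substructure (RDKit).

    Falls back on element-only matching when typed matching finds fewer
    than 3 atoms.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFMCS

    rd_mobile = _to_rdkit(mobile)
    rd_template = _to_rdkit(template)
    mcs = rdFMCS.FindMCS(
        [rd_mobile, rd_template],
        timeout=timeout,
        bondCompare=rdFMCS.BondCompare.CompareAny,
    )
    patt = Chem.MolFromSmarts(mcs.smartsString)
    if patt is None:
        raise ValueError(
            f"no common substructure between {mobile.mol_id!r} and "
            f"{template.mol_id!r}"
        )
    mi = rd_mobile.GetSubstructMatch(patt)
    ti = rd_template.GetSubstructMatch(patt)
    if len(mi) < 3:
        raise ValueError(
            f"common substructure of {mobile.mol_id!r} and {template.mol_id!r} "
            f"has fewer than 3 atoms"
        )
    return AtomMapping(mobile.mol_id, list(zip(mi, ti)))


def _to_rdkit(mol: Molecule):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j, order in mol.bonds:
        bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}.get(
                  order, Chem.BondType.SINGLE)
        rw.AddBond(i, j, bt)
    conf = Chem.Conformer(mol.n_atoms)
    for k, a in enumerate(mol.atoms):
        conf.SetAtomPosition(k, Point3D(*a.coords))
    m = rw.GetMol()
    m.AddConformer(conf)
    try:
        Chem.SanitizeMol(m)
    except Exception:
        pass
    return m


def read_mappings(path) -> list[AtomMapping]:
    """Read mappings from CSV ``mol_id,mobile_idx,template_idx`` (0-based)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for mol_id, grp in df.groupby("mol_id", sort=False):
        pairs = list(zip(grp.mobile_idx.astype(int), grp.template_idx.astype(int)))
        out.append(AtomMapping(str(mol_id), pairs))
    return out
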