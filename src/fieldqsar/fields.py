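"""Grid construction and molecular interaction fields (MIF).

The aligned training set is embedded in a rectilinear lattice; at every
lattice point a probe atom (charge +1 e) accumulates a 12-6 Lennard-Jones
steric energy and a Coulomb electrostatic energy against all atoms of each
molecule.  Energies are truncated at a cutoff, low-variance columns are
masked by a minimum-sigma filter, and the retained columns of one or both
fields are assembled into the descriptor matrix for PLS.

Units: distances in Å, energies in kcal/mol, charges in elementary
charge units.  The Coulomb constant is 332.0716 kcal·Å·mol⁻¹·e⁻².
Grid points are ordered x-fastest: point index = i + nx*(j + ny*l).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from .chem_data import Molecule, QsarDataset

__all__ = [
    "GridSpec",
    "Probe",
    "FieldBlock",
    "DescriptorMatrix",
    "COULOMB_CONSTANT",
    "MIN_DISTANCE",
    "PROBE_NAMES",
    "load_vdw_table",
    "get_probe",
    "build_grid",
    "lj_energy",
    "coulomb_energy",
    "compute_mif",
    "apply_min_sigma",
    "assemble_descriptor_matrix",
]

COULOMB_CONSTANT = 332.0716  # kcal*A/(mol*e^2)
MIN_DISTANCE = 1e-6  # A; guards the r->0 singularity at coincident points

PROBE_NAMES = ("C.3", "C.2", "C.cat", "O.3", "N.3", "H")

# soft ranges: settings outside these draw a warning, not an error
SPACING_RANGE = (1.0, 3.0)
EXTENSION_RANGE = (5.0, 10.0)
CUTOFF_RANGE = (20.0, 40.0)
MIN_SIGMA_RANGE = (0.05, 2.0)

_vdw_cache: dict[str, tuple[float, float]] | None = None


def load_vdw_table() -> dict[str, tuple[float, float]]:
    """Bundled Tripos-style table: sybyl_type -> (vdw radius Å, well depth
    kcal/mol)."""
    global _vdw_cache
    if _vdw_cache is None:
        import pandas as pd

        with resources.files("fieldqsar.data").joinpath("tripos_vdw.csv").open() as fh:
            df = pd.read_csv(fh)
        _vdw_cache = {
            str(r.sybyl_type): (float(r.vdw_radius), float(r.well_depth))
            for r in df.itertuples()
        }
    return _vdw_cache


@dataclass(frozen=True)
class Probe:
    """Probe atom placed at each lattice point; charge fixed at +1 e."""

    name: str
    vdw_radius: float
    well_depth: float
    charge: float = 1.0

    def __post_init__(self) -> None:
        if self.well_depth <= 0:
            raise ValueError("probe well depth must be positive")


def get_probe(name: str, charge: float = 1.0) -> Probe:
    if name not in PROBE_NAMES:
        raise ValueError(f"unknown probe {name!r}; supported: {PROBE_NAMES}")
    table = load_vdw_table()
    radius, depth = table[name]
    return Probe(name=name, vdw_radius=radius, well_depth=depth, charge=charge)


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear lattice geometry.

    ``origin`` is the position of point (0,0,0); points are spaced
    ``spacing`` Å apart along each axis with ``npoints = (nx, ny, nz)``.
    ``extension`` records the margin the box was grown by.
    """

    origin: tuple[float, float, float]
    spacing: float
    npoints: tuple[int, int, int]
    extension: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.npoints):
            raise ValueError("npoints must be positive")

    @property
    def n_total(self) -> int:
        nx, ny, nz = self.npoints
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_total, 3), x-fastest order."""
        nx, ny, nz = self.npoints
        l, j, i = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        idx = np.stack([i.ravel(), j.ravel(), l.ravel()], axis=1)
        return np.asarray(self.origin) + self.spacing * idx

    def point(self, index: int) -> np.ndarray:
        nx, ny, nz = self.npoints
        i = index % nx
        j = (index // nx) % ny
        l = index // (nx * ny)
        return np.asarray(self.origin) + self.spacing * np.array([i, j, l])

    def max_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (
            np.asarray(self.npoints) - 1
        )

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean per row: does the point lie inside the lattice box?"""
        lo = np.asarray(self.origin)
        hi = self.max_corner()
        return np.all((coords >= lo) & (coords <= hi), axis=1)


def build_grid(
    aligned: QsarDataset | Sequence[Molecule],
    spacing: float,
    extension: float,
    force: bool = False,
) -> GridSpec:
    """Lattice covering all atoms of all molecules plus a margin.

    The bounding box over every atom is expanded by ``extension`` on each
    side; the number of points per axis is floor(span/spacing) + 1 and the
    lattice is centered on the expanded box.
    """
    molecules = aligned.molecules if isinstance(aligned, QsarDataset) else list(aligned)
    if not molecules:
        raise ValueError("empty dataset")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not force:
        _warn_range("grid spacing", spacing, SPACING_RANGE)
        _warn_range("grid extension", extension, EXTENSION_RANGE)

    coords = np.vstack([m.coords_array() for m in molecules])
    lo = coords.min(axis=0) - extension
    hi = coords.max(axis=0) + extension
    span = hi - lo
    npoints = np.floor(span / spacing + 1e-9).astype(int) + 1
    # center the lattice (whose extent is (n-1)*spacing) on the expanded box
    origin = (lo + hi) / 2 - (npoints - 1) * spacing / 2
    return GridSpec(
        origin=tuple(float(v) for v in origin),
        spacing=float(spacing),
        npoints=tuple(int(n) for n in npoints),
        extension=float(extension),
    )


def _warn_range(name: str, value: float, rng: tuple[float, float]) -> None:
    if not (rng[0] <= value <= rng[1]):
        warnings.warn(
            f"{name} {value} is outside the usual scan range {rng}",
            stacklevel=3,
        )


def lj_energy(probe: Probe, atom, r: float) -> float:
    """12-6 Lennard-Jones probe-atom energy.

    E = eps_ij * [(R_ij/r)^12 - 2*(R_ij/r)^6] with R_ij the sum of vdW
    radii and eps_ij the geometric mean of well depths; the minimum is
    exactly -eps_ij at r = R_ij.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    radius, depth = _atom_params(atom.sybyl_type)
    rij = probe.vdw_radius + radius
    eps = np.sqrt(probe.well_depth * depth)
    q = (rij / max(r, MIN_DISTANCE)) ** 6
    return float(eps * (q * q - 2.0 * q))


def coulomb_energy(
    q_probe: float,
    q_atom: float,
    r: float,
    dielectric: Literal["distance_dependent"] | float = "distance_dependent",
) -> float:
    """Coulomb probe-atom energy, kcal/mol.

    With the distance-dependent dielectric (the default) eps(r) = r, so the
    energy falls off as 1/r².
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    r = max(r, MIN_DISTANCE)
    eps = r if dielectric == "distance_dependent" else float(dielectric)
    return COULOMB_CONSTANT * q_probe * q_atom / (eps * r)


def _atom_params(sybyl_type: str) -> tuple[float, float]:
    table = load_vdw_table()
    if sybyl_type not in table:
        raise KeyError(
            f"no Lennard-Jones parameters for atom type {sybyl_type!r}"
        )
    return table[sybyl_type]


@dataclass
class FieldBlock:
    """One field matrix: molecules × lattice points, kcal/mol.

    ``column_mask`` marks columns retained for modeling (all true until
    the minimum-sigma filter runs); the matrix itself keeps every column
    so reports and maps can still see the full lattice.
    """

    field_type: Literal["steric", "electrostatic"]
    matrix: np.ndarray
    grid: GridSpec
    probe: Probe
    cutoff: float
    mol_ids: list[str]
    column_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    min_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.column_mask is None:
            self.column_mask = np.ones(self.matrix.shape[1], dtype=bool)
        if self.matrix.shape != (len(self.mol_ids), self.grid.n_total):
            raise ValueError("field matrix shape inconsistent with grid/molecules")

    @property
    def retained(self) -> np.ndarray:
        """Masked matrix: retained columns only."""
        return self.matrix[:, self.column_mask]

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.column_mask)


def _pairwise_energies(
    coords: np.ndarray,
    charges: np.ndarray | None,
    sybyl_types: Sequence[str],
    points: np.ndarray,
    probe: Probe,
    dielectric,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Raw (untruncated) steric and electrostatic sums for one molecule."""
    # distances: points x atoms
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    d = np.maximum(d, MIN_DISTANCE)

    radii = np.empty(len(sybyl_types))
    depths = np.empty(len(sybyl_types))
    for k, t in enumerate(sybyl_types):
        radii[k], depths[k] = _atom_params(t)
    rij = probe.vdw_radius + radii
    eps = np.sqrt(probe.well_depth * depths)
    q6 = (rij[None, :] / d) ** 6
    steric = (eps[None, :] * (q6 * q6 - 2.0 * q6)).sum(axis=1)

    ele = None
    if charges is not None:
        if dielectric == "distance_dependent":
            denom = d * d
        else:
            denom = float(dielectric) * d
        ele = (COULOMB_CONSTANT * probe.charge * charges[None, :] / denom).sum(axis=1)
    return steric, ele


def compute_mif(
    aligned: QsarDataset | Sequence[Molecule],
    grid: GridSpec,
    probe: Probe,
    cutoff: float,
    dielectric: Literal["distance_dependent"] | float = "distance_dependent",
    buried_electrostatic: Literal["column_mean", "clamp"] = "column_mean",
) -> tuple[FieldBlock, FieldBlock]:
    """Steric and electrostatic interaction fields for every molecule.

    Per molecule and lattice point the probe's Lennard-Jones and Coulomb
    energies against all atoms are summed.  Steric energies are truncated
    at +cutoff; electrostatic energies are clamped to [-cutoff, +cutoff].
    At points buried inside a molecule (pre-truncation steric >= cutoff)
    the electrostatic value is, by default, replaced by the column mean
    over the molecules not buried there, the classic CoMFA convention.

    Raises if any molecule lacks partial charges (the electrostatic field
    would be undefined).
    """
    molecules = aligned.molecules if isinstance(aligned, QsarDataset) else list(aligned)
    if not molecules:
        raise ValueError("empty dataset")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    uncharged = [m.mol_id for m in molecules if m.charges_missing]
    if uncharged:
        raise ValueError(
            f"electrostatic field refused; molecules lack charges: {uncharged}"
        )

    points = grid.points()
    n_mol, n_pts = len(molecules), grid.n_total
    steric = np.empty((n_mol, n_pts))
    ele = np.empty((n_mol, n_pts))
    buried = np.zeros((n_mol, n_pts), dtype=bool)

    for m, mol in enumerate(molecules):
        s_raw, e_raw = _pairwise_energies(
            mol.coords_array(),
            mol.charges_array(),
            [a.sybyl_type for a in mol.atoms],
            points,
            probe,
            dielectric,
        )
        buried[m] = s_raw >= cutoff
        steric[m] = np.clip(s_raw, -cutoff, cutoff)
        ele[m] = np.clip(e_raw, -cutoff, cutoff)

    if buried_electrostatic == "column_mean":
        any_buried = buried.any(axis=0)
        for c in np.flatnonzero(any_buried):
            free = ~buried[:, c]
            fill = ele[free, c].mean() if free.any() else 0.0
            ele[buried[:, c], c] = fill

    mol_ids = [m.mol_id for m in molecules]
    return (
        FieldBlock("steric", steric, grid, probe, cutoff, mol_ids),
        FieldBlock("electrostatic", ele, grid, probe, cutoff, mol_ids),
    )


def apply_min_sigma(block: FieldBlock, min_sigma: float) -> FieldBlock:
    """Mask columns whose sample standard deviation falls below min_sigma.

    The comparison is strict (< min_sigma masks; a column exactly at the
    threshold is kept).  The matrix is retained in full; only the mask
    changes.
    """
    if min_sigma < 0:
        raise ValueError("min_sigma must be >= 0")
    if min_sigma == 0:
        mask = np.ones(block.matrix.shape[1], dtype=bool)
    else:
        sd = block.matrix.std(axis=0, ddof=1)
        mask = sd >= min_sigma
    return replace(block, column_mask=mask, min_sigma=min_sigma)


@dataclass
class DescriptorMatrix:
    """Assembled PLS descriptor matrix with per-column provenance.

    ``X`` holds the raw (unscaled) retained columns; ``scales`` is the
    per-column divisor from block scaling (ones when scaling is off);
    ``provenance[k]`` is ``(field_type, grid_index)`` for column k.
    """

    X: np.ndarray
    provenance: list[tuple[str, int]]
    scales: np.ndarray

    @property
    def X_scaled(self) -> np.ndarray:
        return self.X / self.scales


COMBINATIONS = ("Ste", "Ele", "Both")


def assemble_descriptor_matrix(
    blocks: Sequence[FieldBlock],
    combination: Literal["Ste", "Ele", "Both"] = "Both",
    scaling: Literal["none", "block"] | None = None,
) -> DescriptorMatrix:
    """Concatenate masked field columns into the modeling matrix.

    Block scaling (the default for "Both") divides each block's columns by
    the square root of the block's total column variance, so that both
    fields contribute equal total variance regardless of their natural
    energy scales.
    """
    if combination not in COMBINATIONS:
        raise ValueError(f"combination must be one of {COMBINATIONS}")
    wanted = {
        "Ste": ["steric"],
        "Ele": ["electrostatic"],
        "Both": ["steric", "electrostatic"],
    }[combination]
    if scaling is None:
        scaling = "block" if combination == "Both" else "none"

    selected = []
    for ft in wanted:
        matches = [b for b in blocks if b.field_type == ft]
        if not matches:
            raise ValueError(f"no {ft} block supplied")
        selected.append(matches[0])

    g0 = selected[0].grid
    ids0 = selected[0].mol_ids
    for b in selected[1:]:
        if b.grid != g0:
            raise ValueError("field blocks computed on different grids")
        if b.mol_ids != ids0:
            raise ValueError("field blocks have different molecule order")

    parts, provenance, scales = [], [], []
    for b in selected:
        sub = b.retained
        parts.append(sub)
        provenance.extend((b.field_type, int(i)) for i in b.retained_indices)
        if scaling == "block" and sub.shape[1] > 0:
            total_var = float(sub.var(axis=0, ddof=1).sum())
            s = np.sqrt(total_var) if total_var > 0 else 1.0
        else:
            s = 1.0
        scales.append(np.full(sub.shape[1], s))

    X = np.hstack(parts) if parts else np.empty((len(ids0), 0))
    return DescriptorMatrix(
        X=X, provenance=provenance, scales=np.concatenate(scales) if scales else np.ones(0)
    )
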