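"""Contour maps: back-projection of PLS coefficients into 3D space.

Each retained lattice point gets the product of its PLS coefficient and a
column statistic (standard deviation by default — the classic
"StDev*Coeff" display — or the column mean).  With activities on the
negative-log scale, positive steric values mark regions where added bulk
increases predicted potency and negative ones where it hurts; for the
electrostatic field (probe charge +1) positive values favor positive
potential around the ligand.

Maps can be exported as Gaussian cube or OpenDX volumetric files for any
standard viewer; masked lattice points are written as exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .fields import FieldBlock, GridSpec
from .pls import PlsModel

__all__ = [
    "ContourMap",
    "compute_contour",
    "contribution_levels",
    "export_volumetric",
    "read_cube",
    "read_dx",
]

BOHR_PER_ANGSTROM = 1.8897259886


@dataclass
class ContourMap:
    """Per-lattice-point contribution values for one field."""

    field_type: Literal["steric", "electrostatic"]
    point_indices: np.ndarray   # grid indices of retained columns
    values: np.ndarray          # coefficient x column statistic
    statistic: Literal["stdev", "mean"]
    grid: GridSpec
    favored_level: float | None = None
    disfavored_level: float | None = None

    def full_lattice(self) -> np.ndarray:
        """Values on the complete lattice, zeros at masked points."""
        out = np.zeros(self.grid.n_total)
        out[self.point_indices] = self.values
        return out


def compute_contour(
    model: PlsModel,
    blocks: Sequence[FieldBlock],
    statistic: Literal["stdev", "mean"] = "stdev",
) -> dict[str, ContourMap]:
    """StDev*Coeff (or Mean*Coeff) maps for every field in the model.

    The statistic is computed over the training molecules of the raw field
    column; the coefficient is taken on the same raw scale (the model's
    block scaling is divided back out), so the two conventions agree.
    """
    if statistic not in ("stdev", "mean"):
        raise ValueError("statistic must be 'stdev' or 'mean'")
    if not model.column_provenance:
        raise ValueError("model carries no column provenance")
    by_type = {b.field_type: b for b in blocks}
    for ft, _ in model.column_provenance:
        if ft not in by_type:
            raise ValueError(f"model references a {ft} block that was not supplied")

    raw_coef = model.coefficients / model.x_scale
    maps: dict[str, ContourMap] = {}
    for ft in dict.fromkeys(t for t, _ in model.column_provenance):
        block = by_type[ft]
        sel = [k for k, (t, _) in enumerate(model.column_provenance) if t == ft]
        idx = np.array([model.column_provenance[k][1] for k in sel], dtype=int)
        cols = block.matrix[:, idx]
        stat = cols.std(axis=0, ddof=1) if statistic == "stdev" else cols.mean(axis=0)
        maps[ft] = ContourMap(
            field_type=ft,  # type: ignore[arg-type]
            point_indices=idx,
            values=raw_coef[sel] * stat,
            statistic=statistic,
            grid=block.grid,
        )
    return maps


def contribution_levels(
    cmap: ContourMap, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float | None, float | None]:
    """Display isolevels from percentiles of the signed contribution values.

    The favored level is the ``favored_pct`` percentile of the positive
    values; the disfavored level is the ``100 - disfavored_pct`` percentile
    of the negative values.  A side with no values yields ``None``.
    """
    for pct in (favored_pct, disfavored_pct):
        if not (0 < pct < 100):
            raise ValueError("percentiles must lie strictly between 0 and 100")
    pos = cmap.values[cmap.values > 0]
    neg = cmap.values[cmap.values < 0]
    favored = float(np.percentile(pos, favored_pct)) if pos.size else None
    disfavored = (
        float(np.percentile(neg, 100.0 - disfavored_pct)) if neg.size else None
    )
    cmap.favored_level = favored
    cmap.disfavored_level = disfavored
    return favored, disfavored


# ---------------------------------------------------------------------------
# Volumetric export.  Both formats store values with z varying fastest;
# the in-memory lattice is x-fastest, so arrays are transposed on the way
# out and back.

def _lattice_zyx_to_file_order(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    nx, ny, nz = grid.npoints
    return values.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()


def _file_order_to_lattice(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    nx, ny, nz = grid.npoints
    return values.reshape(nx, ny, nz).transpose(2, 1, 0).ravel()


def export_volumetric(
    cmap: ContourMap, format: Literal["cube", "dx"], path: str | Path
) -> Path:
    """Write the map on its full lattice as a Gaussian cube or OpenDX file."""
    path = Path(path)
    values = cmap.full_lattice()
    if format == "cube":
        _write_cube(values, cmap.grid, path,
                    title=f"{cmap.field_type} {cmap.statistic}*coeff")
    elif format == "dx":
        _write_dx(values, cmap.grid, path)
    else:
        raise ValueError("format must be 'cube' or 'dx'")
    return path


def _write_cube(values: np.ndarray, grid: GridSpec, path: Path, title: str) -> None:
    nx, ny, nz = grid.npoints
    b = BOHR_PER_ANGSTROM
    o = np.asarray(grid.origin) * b
    step = grid.spacing * b
    lines = [title, "field contribution map (values follow, z fastest)"]
    # one placeholder atom keeps strict readers happy
    lines.append(f"{1:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    lines.append(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
    lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
    lines.append(f"{6:5d}{0.0:12.6f}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    ordered = _lattice_zyx_to_file_order(values, grid)
    for start in range(0, len(ordered), 6):
        chunk = ordered[start:start + 6]
        lines.append("".join(f"{v:16.8E}" for v in chunk))
    path.write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read a Gaussian cube written by :func:`export_volumetric`.

    Returns the grid (Å) and values in x-fastest lattice order.
    """
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    axes = []
    for k in range(3):
        parts = lines[3 + k].split()
        axes.append((int(parts[0]), np.array([float(v) for v in parts[1:4]])))
    (nx, vx), (ny, vy), (nz, vz) = axes
    spacing = float(vx[0]) / BOHR_PER_ANGSTROM
    data_start = 6 + abs(natoms)
    flat = np.array(
        [float(v) for line in lines[data_start:] for v in line.split()]
    )
    grid = GridSpec(
        origin=tuple(float(v) for v in origin),
        spacing=spacing,
        npoints=(nx, ny, nz),
        extension=0.0,
    )
    return grid, _file_order_to_lattice(flat, grid)


def _write_dx(values: np.ndarray, grid: GridSpec, path: Path) -> None:
    nx, ny, nz = grid.npoints
    o = grid.origin
    d = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    ordered = _lattice_zyx_to_file_order(values, grid)
    for start in range(0, len(ordered), 3):
        chunk = ordered[start:start + 3]
        lines.append(" ".join(f"{v:.8E}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    path.write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an OpenDX scalar grid written by :func:`export_volumetric`."""
    lines = Path(path).read_text().splitlines()
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    for line in lines:
        s = line.strip()
        if s.startswith("object 1"):
            counts = tuple(int(v) for v in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(v) for v in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append(np.array([float(v) for v in s.split()[1:4]]))
        elif "data follows" in s:
            in_data = True
        elif s.startswith("attribute"):
            in_data = False
        elif in_data and s:
            data.extend(float(v) for v in s.split())
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"not a parseable OpenDX grid: {path}")
    grid = GridSpec(
        origin=tuple(float(v) for v in origin),
        spacing=float(deltas[0][0]),
        npoints=counts,
        extension=0.0,
    )
    return grid, _file_order_to_lattice(np.array(data), grid)
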