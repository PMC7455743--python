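"""Gaussian cube volumetric format for nuclear densities.

Header layout follows the cube convention exactly: two comment lines;
atom count + grid origin (Bohr); three axis records (voxel counts and
axis vectors, Bohr); one record per atom (Z, charge, position); then the
volumetric data with the last (z) index running fastest.  Values are
written with 17 significant digits so a write→read→write round trip is
bit-identical, and negative values are legal (difference cubes).
"""

from __future__ import annotations

import numpy as np

from .constants import ATOMIC_NUMBERS
from .densities import NuclearDensityGrid
from .model_systems import MolecularSystem

__all__ = ["write_cube", "read_cube"]


def write_cube(
    path,
    grid: NuclearDensityGrid,
    system: MolecularSystem,
    field: np.ndarray | None = None,
    comment: str = "semivib nuclear density",
) -> None:
    """Write one scalar field (default: the summed molecular density) on the
    grid to a cube file."""
    data = grid.total if field is None else np.asarray(field)
    if data.shape != tuple(grid.shape):
        raise ValueError("field shape does not match the grid")
    if system.n_atoms != grid.per_nucleus.shape[0]:
        raise ValueError("system and grid disagree on the atom count")
    nx, ny, nz = grid.shape
    ox, oy, oz = grid.origin
    h = grid.spacing
    lines = [comment.replace("\n", " "), "OUTER LOOP: X, MIDDLE: Y, INNER: Z"]
    lines.append(f"{system.n_atoms:5d} {ox:23.17e} {oy:23.17e} {oz:23.17e}")
    lines.append(f"{nx:5d} {h:23.17e} {0.0:23.17e} {0.0:23.17e}")
    lines.append(f"{ny:5d} {0.0:23.17e} {h:23.17e} {0.0:23.17e}")
    lines.append(f"{nz:5d} {0.0:23.17e} {0.0:23.17e} {h:23.17e}")
    for el, r in zip(system.atom_labels, system.q_eq):
        z = ATOMIC_NUMBERS[el]
        lines.append(
            f"{z:5d} {float(z):23.17e} {r[0]:23.17e} {r[1]:23.17e} {r[2]:23.17e}")
    flat = data.reshape(nx * ny, nz)
    for row in flat:
        for s in range(0, nz, 6):
            chunk = row[s:s + 6]
            lines.append(" ".join(f"{v:23.17e}" for v in chunk))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path) -> tuple[np.ndarray, dict]:
    """Read a cube file back into (data, header) where header carries the
    origin, spacing, shape and atom records.  Malformed headers raise with
    the offending line number."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    def fail(lineno, msg):
        raise ValueError(f"{path}: line {lineno}: {msg}")

    if len(lines) < 6:
        fail(1, "truncated cube header")
    try:
        parts = lines[2].split()
        n_atoms = int(parts[0])
        origin = np.array([float(v) for v in parts[1:4]])
    except (ValueError, IndexError):
        fail(3, "expected 'natoms ox oy oz'")
    axes = []
    shape = []
    for a in range(3):
        try:
            parts = lines[3 + a].split()
            shape.append(int(parts[0]))
            axes.append(np.array([float(v) for v in parts[1:4]]))
        except (ValueError, IndexError):
            fail(4 + a, "expected 'n vx vy vz' axis record")
    axes = np.array(axes)
    off = np.abs(axes - np.diag(np.diag(axes)))
    if off.max() > 1e-15:
        fail(4, "only axis-aligned cubic grids are supported")
    spacings = np.diag(axes)
    if np.ptp(spacings) > 1e-12:
        fail(4, "anisotropic voxels not supported")
    atoms = []
    for i in range(n_atoms):
        try:
            parts = lines[6 + i].split()
            atoms.append((int(parts[0]),
                          np.array([float(v) for v in parts[2:5]])))
        except (ValueError, IndexError):
            fail(7 + i, "expected 'Z charge x y z' atom record")
    vals = []
    for raw in lines[6 + n_atoms:]:
        vals.extend(float(v) for v in raw.split())
    nx, ny, nz = shape
    if len(vals) != nx * ny * nz:
        fail(7 + n_atoms, f"expected {nx*ny*nz} voxels, found {len(vals)}")
    data = np.array(vals).reshape(nx, ny, nz)
    return data, {
        "origin": origin, "spacing": float(spacings[0]),
        "shape": (nx, ny, nz), "atoms": atoms,
        "comments": lines[:2],
    }
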