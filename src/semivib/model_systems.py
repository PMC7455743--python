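"""Analytic model potentials, molecular system definitions and fixtures.

The downstream stages (trajectory propagation, semiclassical spectra,
eigenfunction expansion, density sampling) only require a potential that
can return energy, gradient and Hessian at arbitrary points.  This module
provides such surfaces in closed form — Morse oscillators, harmonic and
cubically coupled few-mode models, and a harmonic diatomic fixture — so
the whole pipeline is testable without any electronic-structure code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import (
    AMU_TO_ME,
    ANGSTROM_TO_BOHR,
    ATOMIC_MASSES,
    HARTREE_TO_CM,
)

__all__ = [
    "MolecularSystem",
    "PESModel",
    "make_morse",
    "make_coupled_model",
    "make_fixture_diatomic",
    "to_mass_weighted",
    "check_pes_consistency",
    "read_xyz",
    "write_xyz",
    "read_hessian",
]


@dataclass(frozen=True)
class MolecularSystem:
    """A molecule: atoms, masses and an equilibrium geometry.

    Parameters
    ----------
    atom_labels : element symbols, one per atom.
    masses : atomic masses in amu, one per atom.
    q_eq : equilibrium Cartesian coordinates in Bohr, shape ``(N, 3)``.
    charge : total charge.
    is_linear : whether the equilibrium geometry is linear, which changes
        the vibrational dimension from 3N−6 to 3N−5.
    """

    atom_labels: tuple[str, ...]
    masses: np.ndarray
    q_eq: np.ndarray
    charge: int = 0
    is_linear: bool = False

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        q_eq = np.asarray(self.q_eq, dtype=float).reshape(-1, 3)
        if np.any(masses <= 0):
            raise ValueError("all masses must be strictly positive")
        if len(self.atom_labels) != masses.size or q_eq.shape[0] != masses.size:
            raise ValueError("atom_labels, masses and q_eq must agree in length")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "q_eq", q_eq)

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def n_vib(self) -> int:
        """Vibrational dimension: 3N−6 for nonlinear, 3N−5 for linear."""
        return 3 * self.n_atoms - (5 if self.is_linear else 6)

    @property
    def masses_au(self) -> np.ndarray:
        """Masses in electron-mass atomic units."""
        return self.masses * AMU_TO_ME


@dataclass
class PESModel:
    """Potential-energy surface with analytic gradient and Hessian.

    ``coords`` records whether the surface is parameterized by plain
    Cartesian coordinates or by mass-weighted (normal-mode style)
    coordinates; dynamics requires the latter.
    """

    dim: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    hessian: Callable[[np.ndarray], np.ndarray]
    coords: str = "cartesian"  # "cartesian" | "mass-weighted"
    meta: dict = field(default_factory=dict)

    def __call__(self, x) -> float:
        return self.energy(np.atleast_1d(np.asarray(x, dtype=float)))


def make_morse(D: float, a: float, m: float, x0: float = 0.0) -> PESModel:
    """Morse oscillator ``V(x) = D (1 − e^{−a(x−x0)})²``.

    Parameters
    ----------
    D : dissociation energy (Hartree).
    a : range parameter (1/Bohr).
    m : mass (electron masses).
    x0 : equilibrium position (Bohr).

    The harmonic frequency at the bottom of the well,
    ``ω0 = a √(2D/m)``, and the exact bound spectrum
    ``E_n = ω0(n+½) − [ω0(n+½)]²/(4D)`` are exposed through ``meta``.
    """
    if D <= 0 or a <= 0 or m <= 0:
        raise ValueError("Morse parameters D, a, m must all be positive")

    def energy(x):
        y = np.exp(-a * (x[0] - x0))
        return float(D * (1.0 - y) ** 2)

    def gradient(x):
        y = np.exp(-a * (x[0] - x0))
        return np.array([2.0 * D * a * y * (1.0 - y)])

    def hessian(x):
        y = np.exp(-a * (x[0] - x0))
        return np.array([[2.0 * D * a ** 2 * y * (2.0 * y - 1.0)]])

    omega0 = a * math.sqrt(2.0 * D / m)

    def level(n: int) -> float:
        e = omega0 * (n + 0.5)
        return e - e * e / (4.0 * D)

    return PESModel(
        dim=1,
        energy=energy,
        gradient=gradient,
        hessian=hessian,
        coords="cartesian",
        meta={"kind": "morse", "D": D, "a": a, "m": m, "x0": x0,
              "omega0": omega0, "level": level,
              "n_bound": int(math.floor(2.0 * D / omega0 - 0.5))},
    )


def make_coupled_model(
    frequencies_cm: Sequence[float],
    couplings: Mapping[tuple[int, int, int], float] | None = None,
    box_halfwidth: float | None = None,
) -> PESModel:
    """Cubically coupled few-mode model in mass-weighted coordinates.

    ``V(q) = ½ Σ ωk² qk² + Σ λ_ijk qi qj qk`` with frequencies given in
    cm⁻¹ and couplings in Hartree per (mass-weighted Bohr)³.  Cubic (not
    bilinear) couplings leave the Hessian at the origin diagonal, so the
    harmonic analysis is untouched and all anharmonicity lives in the
    couplings.  A coarse scan over the declared sampling box rejects
    parameter sets for which the potential dips below the minimum, since
    an unbounded surface would invalidate both trajectory propagation
    and Monte Carlo sampling.
    """
    omega = np.asarray(frequencies_cm, dtype=float) / HARTREE_TO_CM
    if omega.size < 2:
        raise ValueError("coupled model needs at least two modes")
    if np.any(omega <= 0):
        raise ValueError("frequencies must be positive")
    dim = omega.size
    couplings = dict(couplings or {})
    for key in couplings:
        if len(key) != 3 or not all(0 <= i < dim for i in key):
            raise ValueError(f"bad coupling index {key!r}")

    w2 = omega ** 2

    def energy(q):
        v = 0.5 * float(np.dot(w2, q * q))
        for (i, j, k), lam in couplings.items():
            v += lam * q[i] * q[j] * q[k]
        return v

    def gradient(q):
        g = w2 * q
        for (i, j, k), lam in couplings.items():
            g[i] += lam * q[j] * q[k]
            g[j] += lam * q[i] * q[k]
            g[k] += lam * q[i] * q[j]
        return g

    def hessian(q):
        h = np.diag(w2).astype(float)
        for (i, j, k), lam in couplings.items():
            h[i, j] += lam * q[k]
            h[j, i] += lam * q[k]
            h[i, k] += lam * q[j]
            h[k, i] += lam * q[j]
            h[j, k] += lam * q[i]
            h[k, j] += lam * q[i]
        return h

    # boundedness scan on the sampling box (default: 4 ground-state widths
    # σk = 1/√(2ωk) per mode, the region quantum sampling actually visits)
    if box_halfwidth is None:
        half = 4.0 / np.sqrt(2.0 * omega)
    else:
        half = np.full(dim, float(box_halfwidth))
    if couplings:
        if dim <= 3:
            axes = [np.linspace(-h, h, 9) for h in half]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, dim)
        else:
            rng = np.random.default_rng(0)
            grid = rng.uniform(-1.0, 1.0, size=(4096, dim)) * half
        vals = np.array([energy(q) for q in grid])
        if vals.min() < -1e-10:
            raise ValueError(
                "couplings make the potential dip below the minimum inside "
                "the sampling box; reduce them or shrink the box"
            )

    return PESModel(
        dim=dim, energy=energy, gradient=gradient, hessian=hessian,
        coords="mass-weighted",
        meta={"kind": "coupled", "omega": omega, "couplings": couplings},
    )


def make_fixture_diatomic(
    element_pair: tuple[str, str],
    force_constant: float,
    r_eq: float = 1.832,
) -> tuple[MolecularSystem, PESModel]:
    """Harmonic diatomic fixture: two atoms on the z axis, bond potential
    ``V = ½ k (r − r_eq)²`` expressed over the full 6 Cartesian coordinates.

    ``force_constant`` is in Hartree/Bohr², ``r_eq`` in Bohr.  The single
    vibrational frequency is ``ω = √(k/μ)`` with the reduced mass
    ``μ = m1 m2/(m1+m2)``; it is stored in ``meta`` for convenience.
    """
    e1, e2 = element_pair
    if e1 not in ATOMIC_MASSES or e2 not in ATOMIC_MASSES:
        raise ValueError(f"unknown element in {element_pair!r}")
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    m1 = ATOMIC_MASSES[e1] * AMU_TO_ME
    m2 = ATOMIC_MASSES[e2] * AMU_TO_ME
    mu = m1 * m2 / (m1 + m2)
    k = float(force_constant)

    system = MolecularSystem(
        atom_labels=(e1, e2),
        masses=np.array([ATOMIC_MASSES[e1], ATOMIC_MASSES[e2]]),
        q_eq=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_eq]]),
        is_linear=True,
    )

    def _split(x):
        return x[:3], x[3:]

    def energy(x):
        r1, r2 = _split(x)
        r = float(np.linalg.norm(r1 - r2))
        return 0.5 * k * (r - r_eq) ** 2

    def gradient(x):
        r1, r2 = _split(x)
        d = r1 - r2
        r = float(np.linalg.norm(d))
        u = d / r
        g = k * (r - r_eq) * u
        return np.concatenate([g, -g])

    def hessian(x):
        r1, r2 = _split(x)
        d = r1 - r2
        r = float(np.linalg.norm(d))
        u = d / r
        uu = np.outer(u, u)
        hb = k * uu + k * (r - r_eq) / r * (np.eye(3) - uu)
        h = np.empty((6, 6))
        h[:3, :3] = hb
        h[3:, 3:] = hb
        h[:3, 3:] = -hb
        h[3:, :3] = -hb
        return h

    pes = PESModel(
        dim=6, energy=energy, gradient=gradient, hessian=hessian,
        coords="cartesian",
        meta={"kind": "harmonic-diatomic", "k": k, "mu": mu,
              "omega": math.sqrt(k / mu), "r_eq": r_eq},
    )
    return system, pes


def to_mass_weighted(pes: PESModel, masses: np.ndarray, center: np.ndarray) -> PESModel:
    """Re-express a Cartesian-coordinate PES in mass-weighted displacement
    coordinates ``Q = √m ⊙ (x − center)`` so the minimum sits at ``Q = 0``.

    ``masses`` carries one mass (a.u.) per coordinate (for molecules,
    each atom's mass repeated three times).
    """
    if pes.coords != "cartesian":
        raise ValueError("PES is already mass-weighted")
    sq = np.sqrt(np.asarray(masses, dtype=float))
    c = np.atleast_1d(np.asarray(center, dtype=float)).ravel()
    if sq.size != pes.dim or c.size != pes.dim:
        raise ValueError("masses/center dimension mismatch")

    def energy(Q):
        return pes.energy(c + Q / sq)

    def gradient(Q):
        return pes.gradient(c + Q / sq) / sq

    def hessian(Q):
        return pes.hessian(c + Q / sq) / np.outer(sq, sq)

    return PESModel(dim=pes.dim, energy=energy, gradient=gradient,
                    hessian=hessian, coords="mass-weighted",
                    meta=dict(pes.meta, mass_weighted_from=pes.meta.get("kind")))


def check_pes_consistency(pes: PESModel, x: np.ndarray, rtol: float = 1e-6,
                          h: float = 1e-4) -> None:
    """Verify gradient and Hessian against central finite differences of the
    energy; raises AssertionError when the relative error exceeds ``rtol``.
    """
    x = np.asarray(x, dtype=float)
    g = pes.gradient(x)
    H = pes.hessian(x)
    if not np.allclose(H, H.T, atol=1e-12):
        raise AssertionError("hessian is not symmetric")
    scale_g = max(np.max(np.abs(g)), 1e-8)
    scale_h = max(np.max(np.abs(H)), 1e-8)
    for i in range(pes.dim):
        e = np.zeros(pes.dim)
        e[i] = h
        gfd = (pes.energy(x + e) - pes.energy(x - e)) / (2 * h)
        if abs(gfd - g[i]) > rtol * scale_g + 1e-10:
            raise AssertionError(f"gradient component {i}: {g[i]} vs FD {gfd}")
        hfd = (pes.gradient(x + e) - pes.gradient(x - e)) / (2 * h)
        if np.max(np.abs(hfd - H[:, i])) > rtol * scale_h + 1e-8:
            raise AssertionError(f"hessian column {i} inconsistent with gradient FD")


# ---------------------------------------------------------------------------
# plain-text geometry / Hessian I/O


def read_xyz(path) -> MolecularSystem:
    """Read a standard XYZ file (count, comment, ``El x y z`` in Å) into a
    MolecularSystem with coordinates converted to Bohr.  Masses come from
    the standard atomic weights table.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line 1 must hold the atom count") from exc
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom lines, file truncated")
    labels, coords = [], []
    for ln, raw in enumerate(lines[2:2 + n], start=3):
        parts = raw.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln} malformed")
        el = parts[0].capitalize()
        if el not in ATOMIC_MASSES:
            raise ValueError(f"{path}: line {ln}: unknown element {el!r}")
        labels.append(el)
        coords.append([float(v) for v in parts[1:4]])
    q = np.asarray(coords) * ANGSTROM_TO_BOHR
    masses = np.array([ATOMIC_MASSES[el] for el in labels])
    # linear geometries (incl. diatomics) have 3N−5 vibrations
    centered = q - q.mean(axis=0)
    is_linear = (len(labels) == 2 or
                 np.linalg.matrix_rank(centered, tol=1e-6) <= 1)
    return MolecularSystem(atom_labels=tuple(labels), masses=masses, q_eq=q,
                           is_linear=is_linear)


def write_xyz(path, system: MolecularSystem, comment: str = "") -> None:
    from .constants import BOHR_TO_ANGSTROM

    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for el, r in zip(system.atom_labels, system.q_eq):
            x, y, z = r * BOHR_TO_ANGSTROM
            fh.write(f"{el:2s} {x:20.12f} {y:20.12f} {z:20.12f}\n")


def read_hessian(path, n_atoms: int) -> np.ndarray:
    """Read a row-major plain-text Cartesian Hessian (Hartree/Bohr²) of
    dimension 3N×3N; whitespace layout is free-form."""
    vals = np.loadtxt(path).ravel()
    dim = 3 * n_atoms
    if vals.size != dim * dim:
        raise ValueError(
            f"{path}: expected {dim * dim} Hessian entries, got {vals.size}")
    H = vals.reshape(dim, dim)
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError(f"{path}: Hessian is not symmetric")
    return 0.5 * (H + H.T)
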