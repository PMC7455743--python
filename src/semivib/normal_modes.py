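"""Harmonic normal-mode analysis at an equilibrium geometry.

The mass-weighted Hessian is diagonalized after projecting out rigid
translations and infinitesimal rotations about the center of mass.
Modes are sorted by ascending frequency, so in an N-atom nonlinear
molecule "mode N_v" is always the highest-frequency one (for protonated
glycine that is the hydroxyl O–H stretch).  The resulting basis carries
the bidirectional linear map between Cartesian displacements and
normal-mode coordinates used by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HARTREE_TO_CM
from .model_systems import MolecularSystem

__all__ = [
    "NormalModeBasis",
    "normal_mode_analysis",
    "cart_to_normal",
    "normal_to_cart",
    "harmonic_stick_spectrum",
    "assign_mirror_parities",
]


class ImaginaryFrequencyError(ValueError):
    """Raised when the projected Hessian has a genuinely negative eigenvalue:
    the geometry is not a minimum and the method's assumptions fail."""


@dataclass(frozen=True)
class NormalModeBasis:
    """Result of a harmonic analysis.

    Attributes
    ----------
    omega : vibrational frequencies in a.u., ascending.
    L : mass-weighted Cartesian eigenvectors, shape ``(3N, N_v)`` with
        orthonormal columns; column k spans mode k.
    masses_au : per-atom masses (a.u.).
    q_eq : equilibrium geometry, shape ``(N, 3)`` in Bohr.
    irrep_labels : optional point-group labels, one per mode.
    """

    omega: np.ndarray
    L: np.ndarray
    masses_au: np.ndarray
    q_eq: np.ndarray
    irrep_labels: tuple[str, ...] | None = None

    @property
    def n_modes(self) -> int:
        return self.omega.size

    @property
    def n_atoms(self) -> int:
        return self.masses_au.size

    @property
    def zpe_harmonic(self) -> float:
        """Harmonic zero-point energy ½ Σ ωk (Hartree)."""
        return 0.5 * float(np.sum(self.omega))

    @property
    def omega_cm(self) -> np.ndarray:
        return self.omega * HARTREE_TO_CM

    @property
    def mass_vector(self) -> np.ndarray:
        """Per-coordinate masses (a.u.), length 3N."""
        return np.repeat(self.masses_au, 3)


def _rigid_body_vectors(masses_au: np.ndarray, q_eq: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N, 5 or 6)."""
    n = masses_au.size
    sq = np.sqrt(masses_au)
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    com = (masses_au[:, None] * q_eq).sum(axis=0) / masses_au.sum()
    rel = q_eq - com
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = sq[:, None] * np.cross(rel, e)
        vecs.append(v.ravel())
    V = np.array(vecs).T  # (3N, 6)
    # drop null rotations (linear molecules) and orthonormalize
    keep = np.linalg.norm(V, axis=0) > 1e-10
    V = V[:, keep]
    Q, R = np.linalg.qr(V)
    keep = np.abs(np.diag(R)) > 1e-10
    return Q[:, keep]


def normal_mode_analysis(
    system: MolecularSystem,
    hessian: np.ndarray,
    gradient: np.ndarray | None = None,
    neg_tol: float = 1e-8,
) -> NormalModeBasis:
    """Diagonalize the mass-weighted Hessian with translations and rotations
    projected out.

    Parameters
    ----------
    system : molecule (supplies masses and equilibrium geometry).
    hessian : Cartesian Hessian at ``q_eq``, Hartree/Bohr², shape (3N, 3N).
    gradient : optional Cartesian gradient; a loud warning is emitted if it
        is not numerically zero, since the harmonic picture assumes a
        stationary point.
    neg_tol : eigenvalues above ``−neg_tol`` are treated as numerical zeros;
        anything below raises :class:`ImaginaryFrequencyError`.
    """
    n = system.n_atoms
    H = np.asarray(hessian, dtype=float)
    if H.shape != (3 * n, 3 * n):
        raise ValueError(f"hessian must be {3*n}x{3*n}")
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    if gradient is not None and np.max(np.abs(gradient)) > 1e-5:
        import warnings

        warnings.warn(
            "gradient at q_eq is not zero; harmonic analysis assumes a minimum",
            stacklevel=2,
        )
    m = system.masses_au
    invsq = 1.0 / np.sqrt(np.repeat(m, 3))
    Hmw = H * np.outer(invsq, invsq)

    B = _rigid_body_vectors(m, system.q_eq)
    P = np.eye(3 * n) - B @ B.T
    Hp = P @ Hmw @ P
    Hp = 0.5 * (Hp + Hp.T)

    evals, evecs = np.linalg.eigh(Hp)
    # the projected-out directions land at (numerically) zero eigenvalue
    n_rigid = B.shape[1]
    order = np.argsort(np.abs(evals))
    vib_idx = np.sort(order[n_rigid:])
    lam = evals[vib_idx]
    L = evecs[:, vib_idx]
    if np.any(lam < -neg_tol):
        k = int(np.argmin(lam))
        freq_i = np.sqrt(-lam[k]) * HARTREE_TO_CM
        raise ImaginaryFrequencyError(
            f"imaginary frequency {freq_i:.1f}i cm⁻¹ (mode index {k}): "
            "the input geometry is not a minimum"
        )
    lam = np.clip(lam, 0.0, None)
    omega = np.sqrt(lam)
    order = np.argsort(omega)
    omega = omega[order]
    L = L[:, order]
    # deterministic sign: largest-magnitude component positive
    for k in range(L.shape[1]):
        j = int(np.argmax(np.abs(L[:, k])))
        if L[j, k] < 0:
            L[:, k] = -L[:, k]
    if omega.size != system.n_vib:
        raise ValueError(
            f"expected {system.n_vib} vibrations, got {omega.size}; "
            "check the is_linear flag"
        )
    return NormalModeBasis(omega=omega, L=L, masses_au=m, q_eq=system.q_eq)


def cart_to_normal(x: np.ndarray, basis: NormalModeBasis) -> np.ndarray:
    """Normal-mode coordinates ``Q = Lᵀ M^{1/2} (x − q_eq)``.

    ``x`` may be a single geometry ``(N, 3)``/``(3N,)`` or a batch
    ``(n, N, 3)``; the mode axis is last.
    """
    x = np.asarray(x, dtype=float)
    flat_eq = basis.q_eq.ravel()
    sq = np.sqrt(basis.mass_vector)
    disp = x.reshape(*x.shape[: max(x.ndim - 2, 0)], -1) if x.ndim > 1 else x
    disp = np.atleast_2d(disp) - flat_eq
    Q = (disp * sq) @ basis.L
    return Q[0] if x.ndim <= 2 else Q


def normal_to_cart(Q: np.ndarray, basis: NormalModeBasis) -> np.ndarray:
    """Cartesian geometry ``x = q_eq + M^{−1/2} L Q`` (inverse of
    :func:`cart_to_normal` on the vibrational subspace).  Batched input of
    shape ``(n, N_v)`` returns ``(n, N, 3)``."""
    Q = np.asarray(Q, dtype=float)
    sq = np.sqrt(basis.mass_vector)
    single = Q.ndim == 1
    Q2 = np.atleast_2d(Q)
    x = basis.q_eq.ravel() + (Q2 @ basis.L.T) / sq
    x = x.reshape(Q2.shape[0], basis.n_atoms, 3)
    return x[0] if single else x


def harmonic_stick_spectrum(
    basis: NormalModeBasis, states: list[tuple[int, ...]]
) -> list[tuple[float, str]]:
    """Harmonic energies ``E(n) = Σ (nk+½) ωk`` from the potential minimum,
    one per quantum-number tuple, with a compact ``mode+1:quanta`` label."""
    out = []
    for n in states:
        n = tuple(int(v) for v in n)
        if len(n) != basis.n_modes or any(v < 0 for v in n):
            raise ValueError(f"bad quantum-number tuple {n!r}")
        E = float(np.dot(np.asarray(n) + 0.5, basis.omega))
        lab = " ".join(f"{k + 1}:{v}" for k, v in enumerate(n) if v) or "ground"
        out.append((E, lab))
    return out


def assign_mirror_parities(basis: NormalModeBasis, plane_normal=(1.0, 0.0, 0.0),
                           tol: float = 1e-6) -> tuple[str, ...]:
    """Label each mode A′ (symmetric) or A″ (antisymmetric) under reflection
    through the mirror plane containing the molecule.

    Works for Cs-symmetric planar-heavy systems where reflection maps the
    geometry onto itself atom-by-atom.  Modes that transform into neither
    ±themselves raise, since then the declared plane is not a symmetry
    element.
    """
    nrm = np.asarray(plane_normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    R = np.eye(3) - 2.0 * np.outer(nrm, nrm)
    # reflection must permute atoms onto equivalent positions
    ref_geom = basis.q_eq @ R.T
    n = basis.n_atoms
    perm = np.full(n, -1, dtype=int)
    for i in range(n):
        d = np.linalg.norm(ref_geom[i] - basis.q_eq, axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-6 or abs(basis.masses_au[i] - basis.masses_au[j]) > 1e-6:
            raise ValueError("geometry is not symmetric under the declared plane")
        perm[i] = j
    labels = []
    for k in range(basis.n_modes):
        v = basis.L[:, k].reshape(n, 3)
        rv = (v @ R.T)[np.argsort(perm)]
        if np.linalg.norm(rv - v) < tol * max(1.0, np.linalg.norm(v)):
            labels.append("A'")
        elif np.linalg.norm(rv + v) < tol * max(1.0, np.linalg.norm(v)):
            labels.append("A''")
        else:
            raise ValueError(f"mode {k} has mixed mirror parity")
    return tuple(labels)
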