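"""Sinc-function discrete variable representation (DVR) on a uniform grid.

Numerically exact bound states for 1D and small 2D potentials, used
throughout the test suite as the independent quantum oracle against
which the semiclassical eigenvalues, eigenfunctions and distributions
are judged.  The kinetic matrix is the standard uniform-grid sinc form:
diagonal π²/3, off-diagonal 2(−1)^{i−j}/(i−j)², both over 2mΔx².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .eigenfunctions import HarmonicBasisState, hermite_functions
from .model_systems import PESModel

__all__ = ["DVRSolution", "solve_1d", "solve_2d", "project_onto_harmonic_basis"]


@dataclass
class DVRSolution:
    """Grid, ascending eigenvalues, and grid-normalized eigenvectors.

    For 1D, ``eigvecs[:, k]`` sampled on ``grid`` satisfies
    Σ ψ² Δx = 1.  For 2D, the leading axis is the flattened tensor grid
    (first coordinate slowest) and ``grids`` holds the two axes.
    """

    grid: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dx: float | tuple[float, float]
    meta: dict = field(default_factory=dict)


def _kinetic(n: int, dx: float, m: float) -> np.ndarray:
    i = np.arange(n)
    dij = i[:, None] - i[None, :]
    with np.errstate(divide="ignore"):
        T = 2.0 / dij.astype(float) ** 2
    T[dij == 0] = np.pi ** 2 / 3.0
    T *= (-1.0) ** dij / (2.0 * m * dx * dx)
    return T


def solve_1d(
    pes: PESModel,
    m: float,
    x_min: float,
    x_max: float,
    n_grid: int = 512,
    n_states: int = 8,
    boundary_tol: float = 1e-6,
) -> DVRSolution:
    """Diagonalize the 1D Hamiltonian on [x_min, x_max].

    The grid must span the classically allowed region plus tunneling
    tails; eigenvectors with boundary amplitude above ``boundary_tol``
    signal an under-sized box and raise.
    """
    if pes.dim != 1:
        raise ValueError("solve_1d needs a 1D PES")
    x = np.linspace(x_min, x_max, n_grid)
    dx = x[1] - x[0]
    V = np.array([pes.energy(np.array([xi])) for xi in x])
    H = _kinetic(n_grid, dx, m) + np.diag(V)
    evals, evecs = eigh(H, subset_by_index=[0, n_states - 1])
    psi = evecs / np.sqrt(dx)
    edge = np.max(np.abs(psi[[0, -1], :]), axis=0)
    if np.any(edge > boundary_tol):
        k = int(np.argmax(edge))
        raise ValueError(
            f"state {k} has boundary amplitude {edge[k]:.2e} > {boundary_tol}; "
            "widen the grid")
    return DVRSolution(grid=x, eigenvalues=evals, eigenvectors=psi, dx=float(dx),
                       meta={"m": m, "n_grid": n_grid})


def solve_2d(
    pes: PESModel,
    masses: tuple[float, float] = (1.0, 1.0),
    ranges: tuple[tuple[float, float], tuple[float, float]] = ((-10, 10), (-10, 10)),
    n_grid: tuple[int, int] = (96, 96),
    n_states: int = 10,
) -> DVRSolution:
    """Tensor-product sinc-DVR for a 2D surface (mass-weighted models use
    masses (1, 1)).  Grids above 128² are refused to bound memory."""
    if pes.dim != 2:
        raise ValueError("solve_2d needs a 2D PES")
    n1, n2 = n_grid
    if n1 > 128 or n2 > 128:
        raise ValueError("2D DVR grid capped at 128 points per axis")
    x1 = np.linspace(*ranges[0], n1)
    x2 = np.linspace(*ranges[1], n2)
    d1, d2 = x1[1] - x1[0], x2[1] - x2[0]
    X1, X2 = np.meshgrid(x1, x2, indexing="ij")
    pts = np.stack([X1.ravel(), X2.ravel()], axis=1)
    V = np.array([pes.energy(p) for p in pts])
    T1 = _kinetic(n1, d1, masses[0])
    T2 = _kinetic(n2, d2, masses[1])
    H = (np.kron(T1, np.eye(n2)) + np.kron(np.eye(n1), T2) + np.diag(V))
    evals, evecs = eigh(H, subset_by_index=[0, n_states - 1])
    psi = evecs / np.sqrt(d1 * d2)
    return DVRSolution(grid=pts, eigenvalues=evals, eigenvectors=psi,
                       dx=(float(d1), float(d2)),
                       meta={"axes": (x1, x2), "shape": (n1, n2)})


def project_onto_harmonic_basis(
    sol: DVRSolution,
    state_index: int,
    basis_states: list[HarmonicBasisState],
    omega: np.ndarray,
    center: np.ndarray | float = 0.0,
    mass: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Quadrature projection of a DVR eigenvector onto harmonic product
    states defined in mass-weighted displacement coordinates
    ``Q = √m (x − center)``.

    Returns the normalized coefficient vector; a completeness warning is
    emitted when the truncated basis captures less than 99% of the state.
    """
    import warnings

    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    center = np.broadcast_to(np.atleast_1d(np.asarray(center, float)), omega.shape)
    mass = np.broadcast_to(np.atleast_1d(np.asarray(mass, float)), omega.shape)
    psi = sol.eigenvectors[:, state_index]
    pts = np.atleast_2d(sol.grid.reshape(len(psi), -1))
    if pts.shape[1] != omega.size:
        raise ValueError("grid dimension does not match omega")
    Qpts = np.sqrt(mass) * (pts - center)
    n_max = max(max(s.n) for s in basis_states)
    y = Qpts * np.sqrt(omega)
    tab = hermite_functions(y, n_max) * (mass * omega) ** 0.25  # ψ in x-units
    vol = sol.dx if np.isscalar(sol.dx) else float(np.prod(sol.dx))
    modes = np.arange(omega.size)
    c = np.empty(len(basis_states))
    for i, st in enumerate(basis_states):
        phi = np.prod(tab[np.asarray(st.n), :, modes].T, axis=1)
        c[i] = np.sum(psi * phi) * vol
    captured = float(np.sum(c * c))
    if captured < 0.99:
        warnings.warn(
            f"truncated basis captures only {captured:.3f} of the DVR state",
            stacklevel=2)
    return c / np.linalg.norm(c)
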