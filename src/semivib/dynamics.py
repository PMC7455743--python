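"""Classical trajectory propagation in mass-weighted normal-mode coordinates.

A single velocity-Verlet trajectory carries all the classical input the
semiclassical power spectrum needs: the phase-space path, the classical
action ∫(T−V)dt, and the monodromy (stability) matrix propagated with the
Hessian of the potential at every step.  Propagating the monodromy with
the same discretization as the trajectory keeps it exactly symplectic,
so det M = 1 holds to machine precision at every time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .model_systems import PESModel
from .normal_modes import NormalModeBasis

__all__ = [
    "Trajectory",
    "propagate",
    "initial_conditions_for_state",
    "save_trajectory",
    "load_trajectory",
    "save_trajectory_text",
    "load_trajectory_text",
]


@dataclass
class Trajectory:
    """Phase-space path with action and stability information.

    ``M`` stores the 2N_v×2N_v monodromy matrix at every step in the block
    order ``[[∂Q/∂Q0, ∂Q/∂P0], [∂P/∂Q0, ∂P/∂P0]]``.
    """

    t: np.ndarray          # (nt,)
    Q: np.ndarray          # (nt, d)
    P: np.ndarray          # (nt, d)
    S: np.ndarray          # (nt,) classical action
    M: np.ndarray          # (nt, 2d, 2d)
    energy: np.ndarray     # (nt,) total energy per step
    hessians: np.ndarray | None = None  # (nt, d, d)
    meta: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.Q.shape[1]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def E0(self) -> float:
        return float(self.energy[0])

    @property
    def energy_drift(self) -> float:
        """Max relative deviation of the total energy from its initial value."""
        scale = max(abs(self.E0), 1e-30)
        return float(np.max(np.abs(self.energy - self.E0)) / scale)

    def symplectic_defect(self) -> float:
        """‖MᵀJM − J‖_max over a subsample of steps."""
        d = self.dim
        J = np.zeros((2 * d, 2 * d))
        J[:d, d:] = np.eye(d)
        J[d:, :d] = -np.eye(d)
        idx = np.linspace(0, len(self.t) - 1, min(64, len(self.t))).astype(int)
        return max(
            float(np.max(np.abs(self.M[i].T @ J @ self.M[i] - J))) for i in idx
        )


def propagate(
    pes: PESModel,
    Q0: np.ndarray,
    P0: np.ndarray,
    dt: float,
    nsteps: int,
    box: float | None = None,
    store_hessians: bool = True,
) -> Trajectory:
    """Velocity-Verlet propagation on a mass-weighted PES.

    The action is accumulated by the trapezoid rule on the Lagrangian and
    the monodromy matrix is pushed forward with the exact Jacobian of the
    discrete Verlet map (a composition of shears, hence symplectic).

    Parameters
    ----------
    box : optional coordinate bound; if any |Q_k| exceeds it the run is
        truncated with a warning (e.g. dissociation on a Morse surface).
    """
    if pes.coords != "mass-weighted":
        raise ValueError("propagate requires a mass-weighted PES; "
                         "use to_mass_weighted() first")
    if dt <= 0:
        raise ValueError("dt must be positive")
    Q0 = np.atleast_1d(np.asarray(Q0, dtype=float))
    P0 = np.atleast_1d(np.asarray(P0, dtype=float))
    d = pes.dim
    if Q0.size != d or P0.size != d:
        raise ValueError("initial conditions do not match pes.dim")

    nt = nsteps + 1
    Q = np.empty((nt, d))
    P = np.empty((nt, d))
    S = np.empty(nt)
    E = np.empty(nt)
    M = np.empty((nt, 2 * d, 2 * d))
    hess = np.empty((nt, d, d)) if store_hessians else None

    Q[0], P[0], S[0] = Q0, P0, 0.0
    M[0] = np.eye(2 * d)
    g0 = pes.gradient(Q0)
    h0 = pes.hessian(Q0)
    if store_hessians:
        hess[0] = h0
    V0 = pes.energy(Q0)
    T0 = 0.5 * float(P0 @ P0)
    E[0] = T0 + V0
    L0 = T0 - V0

    eye = np.eye(d)
    n_done = nsteps
    for k in range(nsteps):
        q = Q[k] + dt * P[k] - 0.5 * dt * dt * g0
        g1 = pes.gradient(q)
        p = P[k] - 0.5 * dt * (g0 + g1)
        h1 = pes.hessian(q)

        Jqq = eye - 0.5 * dt * dt * h0
        Jpq = -0.5 * dt * (h0 + h1 @ Jqq)
        Jpp = eye - 0.5 * dt * dt * h1
        J = np.empty((2 * d, 2 * d))
        J[:d, :d] = Jqq
        J[:d, d:] = dt * eye
        J[d:, :d] = Jpq
        J[d:, d:] = Jpp
        M[k + 1] = J @ M[k]

        V1 = pes.energy(q)
        T1 = 0.5 * float(p @ p)
        L1 = T1 - V1
        S[k + 1] = S[k] + 0.5 * dt * (L0 + L1)
        E[k + 1] = T1 + V1
        Q[k + 1], P[k + 1] = q, p
        if store_hessians:
            hess[k + 1] = h1
        g0, h0, L0 = g1, h1, L1

        if box is not None and np.max(np.abs(q)) > box:
            warnings.warn(
                f"trajectory left the coordinate box at step {k + 1}; "
                "truncating (dissociation?)", stacklevel=2)
            n_done = k + 1
            break

    sl = slice(0, n_done + 1)
    return Trajectory(
        t=np.arange(n_done + 1) * dt,
        Q=Q[sl], P=P[sl], S=S[sl], M=M[sl], energy=E[sl],
        hessians=hess[sl] if store_hessians else None,
        meta={"dt": dt, "nsteps": n_done},
    )


def initial_conditions_for_state(
    omega: np.ndarray | NormalModeBasis, excitation: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-classical initial conditions for a target harmonic state.

    The trajectory starts at the minimum (``Q0 = 0``) with each mode given
    its full harmonic energy ``(nk+½)ωk`` as kinetic energy, i.e.
    ``Pk = √((2nk+1) ωk)``, positive sign by convention.  The trajectory
    energy then sits close to the vibrational eigenvalue of interest,
    which is what makes a single trajectory sufficient for the
    time-averaged semiclassical spectrum.
    """
    w = omega.omega if isinstance(omega, NormalModeBasis) else np.asarray(omega, float)
    n = np.asarray(excitation, dtype=int)
    if n.size != w.size or np.any(n < 0):
        raise ValueError("excitation tuple must have one non-negative entry per mode")
    Q0 = np.zeros(w.size)
    P0 = np.sqrt((2.0 * n + 1.0) * w)
    return Q0, P0


# ---------------------------------------------------------------------------
# persistence


def save_trajectory(path, traj: Trajectory) -> None:
    """Write the trajectory to an HDF5 file with named datasets."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("t", "Q", "P", "S", "M", "energy"):
            fh.create_dataset(name, data=getattr(traj, name))
        if traj.hessians is not None:
            fh.create_dataset("hessians", data=traj.hessians)


def load_trajectory(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        kw = {name: fh[name][...] for name in ("t", "Q", "P", "S", "M", "energy")}
        hess = fh["hessians"][...] if "hessians" in fh else None
    return Trajectory(hessians=hess, **kw)


def save_trajectory_text(path, traj: Trajectory) -> None:
    """Columnar plain-text export: t, Q(d), P(d), S, E, Hessian (row-major d²).

    This is also the import layout for externally computed (e.g. ab
    initio) trajectories; the monodromy is reconstructed from the stored
    Hessians on import.
    """
    d = traj.dim
    if traj.hessians is None:
        raise ValueError("text export needs stored Hessians")
    cols = np.column_stack([
        traj.t, traj.Q, traj.P, traj.S, traj.energy,
        traj.hessians.reshape(len(traj.t), d * d),
    ])
    header = f"semivib trajectory dim={d} columns=t,Q*{d},P*{d},S,E,H*{d*d}"
    np.savetxt(path, cols, header=header, fmt="%.17e")


def load_trajectory_text(path) -> Trajectory:
    """Read a columnar trajectory and rebuild the monodromy matrix from the
    per-step Hessians using the same symplectic update as :func:`propagate`."""
    with open(path) as fh:
        first = fh.readline()
    if "dim=" not in first:
        raise ValueError(f"{path}: missing trajectory header")
    d = int(first.split("dim=")[1].split()[0])
    data = np.atleast_2d(np.loadtxt(path))
    nt = data.shape[0]
    t = data[:, 0]
    Q = data[:, 1:1 + d]
    P = data[:, 1 + d:1 + 2 * d]
    S = data[:, 1 + 2 * d]
    E = data[:, 2 + 2 * d]
    hess = data[:, 3 + 2 * d:].reshape(nt, d, d)
    dt = t[1] - t[0] if nt > 1 else 1.0
    if nt > 2 and not np.allclose(np.diff(t), dt, rtol=1e-8):
        raise ValueError(f"{path}: time grid is not uniform")
    M = np.empty((nt, 2 * d, 2 * d))
    M[0] = np.eye(2 * d)
    eye = np.eye(d)
    for k in range(nt - 1):
        h0, h1 = hess[k], hess[k + 1]
        Jqq = eye - 0.5 * dt * dt * h0
        J = np.empty((2 * d, 2 * d))
        J[:d, :d] = Jqq
        J[:d, d:] = dt * eye
        J[d:, :d] = -0.5 * dt * (h0 + h1 @ Jqq)
        J[d:, d:] = eye - 0.5 * dt * dt * h1
        M[k + 1] = J @ M[k]
    return Trajectory(t=t, Q=Q, P=P, S=S, M=M, energy=E, hessians=hess,
                      meta={"dt": float(dt), "nsteps": nt - 1, "source": str(path)})
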