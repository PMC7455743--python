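"""Shared fixtures: model systems and (expensive) reference trajectories."""

from __future__ import annotations

import numpy as np
import pytest

import semivib as sv
from semivib.constants import AMU_TO_ME, ATOMIC_MASSES
from semivib.model_systems import PESModel


OH_MU = (ATOMIC_MASSES["O"] * ATOMIC_MASSES["H"]
         / (ATOMIC_MASSES["O"] + ATOMIC_MASSES["H"])) * AMU_TO_ME
MORSE_D = 0.1994     # Hartree — O–H-like well depth
MORSE_A = 1.11       # 1/Bohr — gives ω0 ≈ 3700 cm⁻¹
OH_REQ = 1.832       # Bohr


def make_harmonic_1d(omega: float) -> PESModel:
    """1D harmonic PES in mass-weighted coordinates."""
    w2 = omega * omega
    return PESModel(
        dim=1,
        energy=lambda q: 0.5 * w2 * float(q[0] * q[0]),
        gradient=lambda q: w2 * np.asarray(q, dtype=float),
        hessian=lambda q: np.array([[w2]]),
        coords="mass-weighted",
        meta={"kind": "harmonic-1d", "omega": omega},
    )


def spring_network_system(coords, labels, k=0.3):
    """A molecule held together by harmonic springs between every atom pair,
    at equilibrium at the given geometry: zero gradient, positive-definite
    projected Hessian — a generic minimum fixture of any size."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    system = sv.MolecularSystem(
        atom_labels=tuple(labels),
        masses=np.array([ATOMIC_MASSES[el] for el in labels]),
        q_eq=coords,
    )
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[i] - coords[j]
            u = d / np.linalg.norm(d)
            blk = k * np.outer(u, u)
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += blk
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += blk
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= blk
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= blk
    return system, H


@pytest.fixture(scope="session")
def oh_morse():
    """O–H-like Morse oscillator: Cartesian model, mass-weighted model, and
    the matching harmonic frequency."""
    morse = sv.make_morse(MORSE_D, MORSE_A, OH_MU, x0=OH_REQ)
    pes_mw = sv.to_mass_weighted(morse, np.array([OH_MU]), np.array([OH_REQ]))
    return {
        "cart": morse, "mw": pes_mw, "mu": OH_MU, "D": MORSE_D, "a": MORSE_A,
        "x0": OH_REQ, "omega0": morse.meta["omega0"],
        "omega": np.array([morse.meta["omega0"]]),
    }


@pytest.fixture(scope="session")
def oh_morse_trajs(oh_morse):
    """Quasi-classical ground and fundamental trajectories on the Morse well
    (dt = 1 a.u., 2^16 steps — enough for sub-0.1% eigenvalues in 1D)."""
    out = {}
    for exc in [(0,), (1,)]:
        Q0, P0 = sv.initial_conditions_for_state(oh_morse["omega"], exc)
        out[exc] = sv.propagate(oh_morse["mw"], Q0, P0, dt=1.0, nsteps=2 ** 16)
    return out


@pytest.fixture(scope="session")
def oh_morse_states(oh_morse, oh_morse_trajs):
    """Semiclassical ground/fundamental eigenvalues and expansions for the
    O–H Morse well, shared by the eigenfunction and density tests."""
    omega = oh_morse["omega"]
    basis_states = sv.enumerate_basis(1, 6)
    states = {}
    for exc in [(0,), (1,)]:
        traj = oh_morse_trajs[exc]
        ref = sv.build_mc_reference(omega, exc)
        E_harm = float(np.dot(np.asarray(exc) + 0.5, omega))
        spec = sv.ta_scivr_spectrum(traj, ref, 0.25 * E_harm, 2.0 * E_harm)
        peaks = sv.find_peaks(spec)
        E = min(peaks, key=lambda p: abs(p.energy - E_harm)).energy
        exp = sv.expansion_coefficients(traj, ref, basis_states, E, omega)
        states[exc] = {"E": E, "exp": exp, "traj": traj, "ref": ref}
    states[(1,)]["exp"] = sv.gram_schmidt(states[(1,)]["exp"], states[(0,)]["exp"])
    return states


@pytest.fixture(scope="session")
def oh_diatomic():
    """Harmonic O–H diatomic with its normal-mode basis (frequency matched
    to the Morse well's harmonic limit)."""
    k = 2 * MORSE_D * MORSE_A * MORSE_A
    system, pes = sv.make_fixture_diatomic(("O", "H"), k, r_eq=OH_REQ)
    basis = sv.normal_mode_analysis(system, pes.hessian(system.q_eq.ravel()))
    return {"system": system, "pes": pes, "basis": basis,
            "omega": float(basis.omega[0])}


@pytest.fixture(scope="session")
def eleven_atom_fixture():
    """An 11-atom nonlinear spring-network molecule: 27 vibrational modes,
    the dimensionality of protonated glycine."""
    rng = np.random.default_rng(11)
    labels = ["C", "C", "O", "O", "N", "H", "H", "H", "H", "H", "H"]
    coords = rng.normal(scale=2.0, size=(11, 3))
    return spring_network_system(coords, labels)
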