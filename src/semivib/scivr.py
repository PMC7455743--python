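"""Time-averaged semiclassical (TA-SCIVR) power spectra.

One classical trajectory, its action S(t) and the phase of the
Herman–Kluk prefactor φ(t) yield the positive-definite time-averaged
power spectrum

    I(E) ∝ (1/T) | ∫₀ᵀ dt exp{i[S(t) + E t + φ(t)]} ⟨χ|g(Q(t),P(t))⟩ |²

whose peaks sit at the vibrational eigenvalues.  The reference |χ⟩ is a
small combination of coherent states placed at (Q0, ±P0) with signs
chosen to match the parity of the target harmonic state — the "multiple
coherent" trick that makes a single trajectory resolve individual
states.  Energies are measured from the potential minimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .dynamics import Trajectory, initial_conditions_for_state

__all__ = [
    "CoherentState",
    "ReferenceState",
    "coherent_overlap",
    "build_mc_reference",
    "ta_scivr_spectrum",
    "PowerSpectrum",
    "find_peaks",
    "Peak",
]


@dataclass(frozen=True)
class CoherentState:
    """Minimum-uncertainty Gaussian wavepacket.

    ⟨x|g⟩ = Π_k (γk/π)^{1/4} exp(−γk(x−Q)²/2 + iP(x−Q)), with the width
    matrix Γ diagonal; by default Γkk equals the harmonic frequency ωk so
    the packet matches the harmonic ground state.
    """

    Q: np.ndarray
    P: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        Q = np.atleast_1d(np.asarray(self.Q, float))
        P = np.atleast_1d(np.asarray(self.P, float))
        g = np.atleast_1d(np.asarray(self.gamma, float))
        if not (Q.size == P.size == g.size):
            raise ValueError("Q, P, gamma must have equal length")
        if np.any(g <= 0):
            raise ValueError("width matrix must be positive definite")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "gamma", g)

    @property
    def dim(self) -> int:
        return self.Q.size


def coherent_overlap(g1: CoherentState, g2: CoherentState) -> complex:
    """Closed-form Gaussian overlap ⟨g1|g2⟩ for equal width matrices:

    Π_k exp(−γΔQ²/4 − ΔP²/(4γ) − i(P1+P2)ΔQ/2),  ΔQ=Q2−Q1, ΔP=P2−P1.
    """
    if g1.dim != g2.dim or not np.allclose(g1.gamma, g2.gamma):
        raise ValueError("overlap requires matching dimension and widths")
    dQ = g2.Q - g1.Q
    dP = g2.P - g1.P
    ex = (-g1.gamma * dQ ** 2 / 4.0 - dP ** 2 / (4.0 * g1.gamma)
          - 0.5j * (g1.P + g2.P) * dQ)
    return complex(np.exp(np.sum(ex)))


@dataclass(frozen=True)
class ReferenceState:
    """Normalized linear combination of coherent states, Σ c_j |g_j⟩."""

    coeffs: np.ndarray
    states: tuple[CoherentState, ...]

    def overlaps_with_path(self, Q: np.ndarray, P: np.ndarray) -> np.ndarray:
        """⟨χ|g(Q(t),P(t))⟩ along a phase-space path, vectorized over time."""
        gamma = self.states[0].gamma
        out = np.zeros(Q.shape[0], dtype=complex)
        for c, g in zip(self.coeffs, self.states):
            dQ = Q - g.Q
            dP = P - g.P
            ex = (-gamma * dQ ** 2 / 4.0 - dP ** 2 / (4.0 * gamma)
                  - 0.5j * (g.P + P) * dQ)
            out += np.conj(c) * np.exp(ex.sum(axis=1))
        return out


def build_mc_reference(
    omega: np.ndarray, excitation: tuple[int, ...],
    phases: tuple[int, ...] | None = None,
) -> ReferenceState:
    """Multiple-coherent reference for a target harmonic state.

    Two coherent states at (0, +P0) and (0, −P0) — with P0 the
    quasi-classical momenta of the target state — are combined with signs
    (+1, (−1)^{Σn}) unless an explicit ``phases`` pattern is given.  With
    this parity the combination overlaps the target harmonic state
    constructively while states of opposite total parity drop out.
    """
    omega = np.asarray(omega, dtype=float)
    Q0, P0 = initial_conditions_for_state(omega, excitation)
    if phases is None:
        phases = (1, (-1) ** int(np.sum(excitation)))
    g_plus = CoherentState(Q0, P0, omega)
    g_minus = CoherentState(Q0, -P0, omega)
    states = (g_plus, g_minus)
    c = np.asarray(phases, dtype=complex)
    G = np.array([[coherent_overlap(a, b) for b in states] for a in states])
    norm2 = float(np.real(np.conj(c) @ G @ c))
    if norm2 < 1e-12:
        raise ValueError("reference combination has zero norm")
    return ReferenceState(coeffs=c / math.sqrt(norm2), states=states)


@dataclass
class PowerSpectrum:
    """Power spectrum on an energy grid, with the FT resolution 2π/T."""

    E: np.ndarray
    intensity: np.ndarray
    resolution: float
    meta: dict = field(default_factory=dict)


def hk_prefactor_phase(traj: Trajectory, gamma: np.ndarray,
                       eps: float = 1e-12) -> np.ndarray:
    """Continuous phase φ(t) of the Herman–Kluk prefactor.

    C_t = √det{½[M_qq + Γ⁻¹ M_pp Γ + i Γ⁻¹ M_pq − i M_qp Γ]}; the sign of
    the imaginary blocks is pinned by the harmonic limit, where C_t must
    reduce to e^{−iωt/2} so that the time-averaged spectrum peaks at
    (n+½)ω.  The square root's branch is fixed by unwrapping the
    determinant's phase along the trajectory and halving it.  A tiny
    regularization keeps the argument away from the origin at caustics.
    """
    d = traj.dim
    Mqq = traj.M[:, :d, :d]
    Mqp = traj.M[:, :d, d:]
    Mpq = traj.M[:, d:, :d]
    Mpp = traj.M[:, d:, d:]
    gi = 1.0 / gamma
    A = 0.5 * (Mqq + gi[:, None] * Mpp * gamma[None, :]
               + 1j * gi[:, None] * Mpq - 1j * Mqp * gamma[None, :])
    det = np.linalg.det(A) + eps
    ang = np.unwrap(np.angle(det))
    jumps = np.max(np.abs(np.diff(ang)), initial=0.0)
    if jumps > math.pi:
        warnings.warn(
            "prefactor phase jumps by more than π per step; decrease dt",
            stacklevel=2)
    return 0.5 * ang


def _phase_series(traj: Trajectory, ref: ReferenceState,
                  prefactor: str = "separable") -> np.ndarray:
    gamma = ref.states[0].gamma
    if prefactor == "separable":
        phi = hk_prefactor_phase(traj, gamma)
        amp = 1.0
    elif prefactor == "none":
        phi = np.zeros(len(traj.t))
        amp = 1.0
    else:
        raise ValueError(f"unknown prefactor mode {prefactor!r}")
    ov = ref.overlaps_with_path(traj.Q, traj.P)
    return amp * np.exp(1j * (traj.S + phi)) * ov


def ta_scivr_spectrum(
    traj: Trajectory,
    ref: ReferenceState,
    emin: float,
    emax: float,
    pad_factor: int = 8,
    window: str | None = None,
    prefactor: str = "separable",
) -> PowerSpectrum:
    """Time-averaged semiclassical power spectrum on [emin, emax].

    The time integral is evaluated by FFT over a zero-padded grid (the
    padding only refines the energy sampling; the physical resolution
    stays ΔE = 2π/T).  Intensities are ≥ 0 by construction.
    """
    t = traj.t
    if len(t) < 4:
        raise ValueError("trajectory too short for a spectrum")
    dt = traj.dt
    if not np.allclose(np.diff(t), dt, rtol=1e-9):
        raise ValueError("non-uniform time grid")
    u = _phase_series(traj, ref, prefactor)
    if window == "hann":
        u = u * np.hanning(len(u))
    elif window not in (None, "rect"):
        raise ValueError(f"unknown window {window!r}")
    # trapezoid end-point weights for the finite-T time average
    w = np.ones(len(u))
    w[0] = w[-1] = 0.5
    uw = u * w
    T = t[-1]
    n_pad = pad_factor * len(uw)
    # ∫ u e^{iEt} dt on the grid E_m = 2π m/(n_pad dt); ifft carries e^{+i...}
    F = np.fft.ifft(uw, n=n_pad) * n_pad * dt
    Egrid = 2.0 * np.pi * np.arange(n_pad) / (n_pad * dt)
    sel = (Egrid >= emin) & (Egrid <= emax)
    if not np.any(sel):
        raise ValueError("no FFT energies inside [emin, emax]; widen the range")
    E = Egrid[sel]
    intensity = np.abs(F[sel]) ** 2 / (2.0 * np.pi * T)
    return PowerSpectrum(
        E=E, intensity=intensity, resolution=2.0 * np.pi / T,
        meta={"T": T, "dt": dt, "pad_factor": pad_factor, "window": window,
              "prefactor": prefactor, "u": uw, "t": t},
    )


@dataclass(frozen=True)
class Peak:
    """A spectral line: refined position (a.u.), height, and a flag set when
    a neighbouring maximum sits closer than the FT resolution."""

    energy: float
    height: float
    unresolved: bool = False


def _continuous_intensity(u: np.ndarray, t: np.ndarray, E: float) -> float:
    T = t[-1]
    val = np.abs(np.trapezoid(u * np.exp(1j * E * t), dx=t[1] - t[0])) ** 2
    return float(val / (2.0 * np.pi * T))


def find_peaks(
    spec: PowerSpectrum,
    min_height_fraction: float = 0.01,
    sidelobe_radius: float = 6.0,
    sidelobe_fraction: float = 0.1,
) -> list[Peak]:
    """Locate spectral peaks above a fraction of the tallest line.

    Grid maxima are refined by maximizing the continuous finite-T Fourier
    integral in a one-resolution bracket around each candidate (the raw
    grid only samples at the zero-padded FFT spacing).  With the default
    rectangular window each line carries sinc² sidelobes (≈5% height at
    ±1.4 ΔE); candidates within ``sidelobe_radius``·ΔE of a taller peak
    are therefore discarded as sidelobes unless they exceed
    ``sidelobe_fraction`` of its height — genuinely close lines of
    comparable height survive and come back flagged unresolved rather
    than silently merged.  The lowest peak is the ZPE; fundamentals are
    differences from it.
    """
    I = spec.intensity
    if I.size < 3:
        raise ValueError("spectrum grid too small")
    thr = min_height_fraction * float(I.max())
    if thr <= 0 or I.max() <= 0:
        raise ValueError("spectrum has no intensity above threshold")
    cand = [
        i for i in range(1, I.size - 1)
        if I[i] >= thr and I[i] >= I[i - 1] and I[i] > I[i + 1]
    ]
    if not cand:
        raise ValueError("no peak above threshold")
    u = spec.meta.get("u")
    t = spec.meta.get("t")
    peaks: list[Peak] = []
    for i in cand:
        E0 = float(spec.E[i])
        if u is not None and t is not None:
            res = minimize_scalar(
                lambda E: -_continuous_intensity(u, t, E),
                bounds=(E0 - spec.resolution, E0 + spec.resolution),
                method="bounded", options={"xatol": 1e-12},
            )
            peaks.append(Peak(energy=float(res.x), height=float(-res.fun)))
        else:
            # 3-point parabolic refinement on the grid
            y0, y1, y2 = I[i - 1], I[i], I[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            dE = float(spec.E[i + 1] - spec.E[i])
            peaks.append(Peak(energy=E0 + shift * dE, height=float(y1)))
    # merge refinement duplicates (keep the tallest of near-coincident hits)
    peaks.sort(key=lambda p: p.energy)
    merged: list[Peak] = []
    for p in peaks:
        if merged and abs(p.energy - merged[-1].energy) < 1e-3 * spec.resolution:
            if p.height > merged[-1].height:
                merged[-1] = p
            continue
        merged.append(p)
    # greedy sidelobe suppression, tallest first
    accepted: list[Peak] = []
    for p in sorted(merged, key=lambda q: -q.height):
        shadowed = any(
            abs(p.energy - q.energy) < sidelobe_radius * spec.resolution
            and p.height < sidelobe_fraction * q.height
            for q in accepted
        )
        if not shadowed:
            accepted.append(p)
    accepted.sort(key=lambda p: p.energy)
    flagged = []
    for j, p in enumerate(accepted):
        close = (
            (j > 0 and accepted[j - 1].energy > p.energy - spec.resolution)
            or (j + 1 < len(accepted)
                and accepted[j + 1].energy < p.energy + spec.resolution)
        )
        flagged.append(Peak(p.energy, p.height, unresolved=close))
    return flagged
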