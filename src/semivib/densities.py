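"""Quantum nuclear densities and geometry distributions by Monte Carlo.

Normal-mode points are drawn from |ψ(Q)|² with a Metropolis walker
ensemble, mapped to Cartesian space through the linear normal-mode map
about the equilibrium geometry, and binned: per-nucleus 3D histograms on
a cubic grid (default edge 0.049 Å) whose direct sum is the molecular
nuclear density, and 1D distributions of bonds (0.008 Å bins), angles
and dihedrals (0.45° bins).  Densities of two states subtract bin-wise
to give the signed difference maps that visualize which nuclei a
vibrational excitation involves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .dynamics import Trajectory
from .eigenfunctions import WavefunctionExpansion, evaluate_wavefunction
from .normal_modes import NormalModeBasis, normal_to_cart

__all__ = [
    "DEFAULT_GRID_EDGE_ANGSTROM",
    "DEFAULT_BOND_BIN_ANGSTROM",
    "DEFAULT_ANGLE_BIN_DEGREES",
    "NuclearDensityGrid",
    "GeometryDistribution",
    "sample_wavefunction",
    "one_nucleus_density",
    "density_difference",
    "geometry_distribution",
    "quasiclassical_histogram",
    "position_stddev_report",
    "descriptor_values",
]

DEFAULT_GRID_EDGE_ANGSTROM = 0.049
DEFAULT_BOND_BIN_ANGSTROM = 0.008
DEFAULT_ANGLE_BIN_DEGREES = 0.45
DEFAULT_ISOSURFACE_AU = 0.15


@dataclass
class NuclearDensityGrid:
    """Per-nucleus 3D histograms of |ψ|² in Cartesian space.

    ``per_nucleus[i]`` integrates to 1 over the grid (Bohr³ voxels), so
    the summed density integrates to the number of nuclei.  Difference
    grids (signed) reuse the container with ``is_difference=True``.
    """

    origin: np.ndarray            # (3,) Bohr
    spacing: float                # cubic voxel edge, Bohr
    shape: tuple[int, int, int]
    per_nucleus: np.ndarray       # (N, nx, ny, nz)
    n_samples: int
    is_difference: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        """Direct sum of the per-nucleus densities."""
        return self.per_nucleus.sum(axis=0)

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def integral(self) -> float:
        return float(self.total.sum() * self.voxel_volume)


@dataclass
class GeometryDistribution:
    """Normalized histogram of one internal coordinate.

    Bonds are in Å, angles and dihedrals in degrees.  ``stderr`` holds
    per-bin Monte Carlo standard errors from block averaging.
    """

    descriptor: tuple
    edges: np.ndarray
    hist: np.ndarray              # density: integrates to 1
    stderr: np.ndarray
    mean: float
    std: float
    mode: float                   # bin-center of the maximum
    n_used: int
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


# ---------------------------------------------------------------------------
# Metropolis sampling of |ψ|²


def sample_wavefunction(
    exp: WavefunctionExpansion,
    n_samples: int,
    seed: int,
    n_walkers: int = 64,
    burn_in: int = 400,
    thin: int = 1,
    sampler: str = "metropolis",
    target_acceptance: tuple[float, float] = (0.3, 0.5),
    independence_fraction: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Draw normal-mode samples distributed ∝ |ψ(Q)|².

    An ensemble of Metropolis–Hastings walkers alternates two proposal
    kernels: a local Gaussian random walk (per-mode scale s/√(2ωk), s
    tuned during burn-in to 30–50% acceptance, then frozen) and an
    independence proposal drawn from the dominant harmonic state's
    Gaussian envelope (per-mode variance (2n_k+1)/(2ω_k)).  The
    independence moves decorrelate the chain almost completely for
    near-harmonic targets while the local moves guarantee mixing near
    nodes where the envelope is a poor guess.  ``sampler="walk"``
    restricts to the pure random walk.  The stream is fully determined
    by ``seed``; the info dict records the tuned step, acceptance,
    burn-in and thinning.
    """
    if sampler not in ("metropolis", "walk"):
        raise ValueError(f"unknown sampler {sampler!r}")
    if sampler == "walk":
        independence_fraction = 0.0
    rng = np.random.default_rng(seed)
    d = exp.n_modes
    sigma0 = 1.0 / np.sqrt(2.0 * exp.omega)
    n_dom = np.asarray(exp.dominant_state.n, dtype=float)
    sigma_env = np.sqrt((2.0 * n_dom + 1.0) / (2.0 * exp.omega))

    def logdens(Q):
        a = np.abs(evaluate_wavefunction(exp, Q))
        with np.errstate(divide="ignore"):
            return 2.0 * np.log(a)

    def log_env(Q):
        return -0.5 * np.sum((Q / sigma_env) ** 2, axis=-1)

    # start walkers from the envelope, avoiding nodes
    Q = rng.normal(scale=sigma_env, size=(n_walkers, d))
    lp = logdens(Q)
    for _ in range(20):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        Q[bad] = rng.normal(scale=sigma_env, size=(int(bad.sum()), d))
        lp[bad] = logdens(Q[bad])
    if not np.isfinite(lp).all():
        raise ValueError("could not find nonzero-density starting points")

    s = 2.4 / math.sqrt(d)  # classic Gaussian-target starting scale
    acc_hist = []

    def sweep(s, collect=None):
        nonlocal Q, lp
        indep = rng.random(n_walkers) < independence_fraction
        prop = Q + rng.normal(scale=s * sigma0, size=Q.shape)
        if indep.any():
            prop[indep] = rng.normal(scale=sigma_env,
                                     size=(int(indep.sum()), d))
        lp_prop = logdens(prop)
        # Hastings correction: zero for the symmetric walk, envelope ratio
        # for independence proposals
        log_ratio = lp_prop - lp
        if indep.any():
            log_ratio[indep] += log_env(Q[indep]) - log_env(prop[indep])
        u = np.log(rng.random(n_walkers))
        accept = u < log_ratio
        Q = np.where(accept[:, None], prop, Q)
        lp = np.where(accept, lp_prop, lp)
        if collect is not None:
            collect.append(Q.copy())
        local = ~indep
        acc_local = float(accept[local].mean()) if local.any() else math.nan
        return float(accept.mean()), acc_local

    # burn-in with step adaptation of the local kernel
    lo, hi = target_acceptance
    for it in range(burn_in):
        _, acc = sweep(s)
        acc_hist.append(acc)
        if (it + 1) % 25 == 0:
            recent = float(np.nanmean(acc_hist[-25:]))
            if recent < lo:
                s *= 0.8
            elif recent > hi:
                s *= 1.25
    final_acc = float(np.nanmean(acc_hist[-100:])) if acc_hist else 1.0
    if final_acc < 0.05:
        raise ValueError(
            f"Metropolis acceptance {final_acc:.3f} below 5% after tuning; "
            "the target density is too hard for the Gaussian proposal")

    n_sweeps = math.ceil(n_samples / n_walkers) * thin
    chains: list[np.ndarray] = []
    acc_run = []
    for it in range(n_sweeps):
        acc, _ = sweep(s, collect=chains if (it + 1) % thin == 0 else None)
        acc_run.append(acc)
    samples = np.concatenate(chains, axis=0)[:n_samples]
    info = {
        "seed": seed, "n_walkers": n_walkers, "burn_in": burn_in,
        "thin": thin, "step_scale": s, "sampler": sampler,
        "acceptance": float(np.mean(acc_run)),
    }
    return samples, info


def _block_stderr(per_block: np.ndarray) -> np.ndarray:
    """Standard error of the mean across sequential blocks (leading axis)."""
    nb = per_block.shape[0]
    return per_block.std(axis=0, ddof=1) / math.sqrt(nb)


# ---------------------------------------------------------------------------
# 3D nuclear densities


def one_nucleus_density(
    samples: np.ndarray,
    basis: NormalModeBasis,
    spacing_angstrom: float = DEFAULT_GRID_EDGE_ANGSTROM,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    coverage_sigmas: float = 5.0,
    max_outside_fraction: float = 0.01,
) -> NuclearDensityGrid:
    """Bin Monte Carlo samples into per-nucleus 3D histograms.

    Each normal-mode sample is mapped to Cartesian space with the linear
    map about ``q_eq`` (body-fixed frame) and every nucleus is binned into
    its own histogram on a shared cubic grid.  By default the grid covers
    every nucleus's mean ± ``coverage_sigmas``·σ and its origin is snapped
    so that the equilibrium position of atom 1 falls on a grid point.
    """
    spacing = spacing_angstrom * ANGSTROM_TO_BOHR
    cart = normal_to_cart(samples, basis)       # (n, N, 3)
    n, n_atoms, _ = cart.shape

    if origin is None or shape is None:
        mu = cart.mean(axis=0)                   # (N, 3)
        sd = cart.std(axis=0)
        lo = (mu - coverage_sigmas * sd - spacing).min(axis=0)
        hi = (mu + coverage_sigmas * sd + spacing).max(axis=0)
        anchor = basis.q_eq[0]
        origin = anchor - np.ceil((anchor - lo) / spacing) * spacing
        shape = tuple(int(v) for v in np.ceil((hi - origin) / spacing) + 1)

    origin = np.asarray(origin, dtype=float)
    edges = [origin[a] + spacing * np.arange(shape[a] + 1) for a in range(3)]
    per = np.empty((n_atoms,) + tuple(shape))
    outside = 0
    for i in range(n_atoms):
        h, _ = np.histogramdd(cart[:, i, :], bins=edges)
        outside += n - int(h.sum())
        per[i] = h / (n * spacing ** 3)
    frac_out = outside / (n * n_atoms)
    if frac_out > max_outside_fraction:
        raise ValueError(
            f"{frac_out:.1%} of samples fall outside the grid; enlarge it")
    return NuclearDensityGrid(
        origin=origin, spacing=float(spacing), shape=tuple(shape),
        per_nucleus=per, n_samples=n,
        meta={"outside_fraction": frac_out,
              "spacing_angstrom": spacing_angstrom},
    )


def density_difference(d1: NuclearDensityGrid, d2: NuclearDensityGrid,
                       labels: tuple[str, str] = ("state1", "state2")
                       ) -> NuclearDensityGrid:
    """Signed bin-wise difference d1 − d2 of two densities on one grid."""
    if (d1.shape != d2.shape or abs(d1.spacing - d2.spacing) > 1e-12
            or not np.allclose(d1.origin, d2.origin, atol=1e-10)):
        raise ValueError("density grids do not match (origin/spacing/shape)")
    return NuclearDensityGrid(
        origin=d1.origin.copy(), spacing=d1.spacing, shape=d1.shape,
        per_nucleus=d1.per_nucleus - d2.per_nucleus,
        n_samples=min(d1.n_samples, d2.n_samples),
        is_difference=True,
        meta={"labels": labels, "isosurface_au": DEFAULT_ISOSURFACE_AU},
    )


# ---------------------------------------------------------------------------
# internal-coordinate distributions


def descriptor_values(cart: np.ndarray, descriptor: tuple) -> tuple[np.ndarray, int]:
    """Evaluate a geometry descriptor on Cartesian geometries ``(n, N, 3)``.

    descriptor = ("bond", i, j) | ("angle", i, j, k) | ("dihedral", i, j, k, l)
    with zero-based atom indices, the angle vertex at j, and the dihedral
    measured between the planes (i,j,k) and (j,k,l), signed, in
    (−180°, 180°].  Bonds come back in Å, angles in degrees.  Returns the
    values and the number of geometries excluded as degenerate (colinear
    atoms in a dihedral).
    """
    kind = descriptor[0]
    idx = descriptor[1:]
    n_atoms = cart.shape[1]
    if any(not (0 <= a < n_atoms) for a in idx):
        raise ValueError(f"descriptor atoms {idx} outside molecule of {n_atoms}")
    if kind == "bond":
        i, j = idx
        r = np.linalg.norm(cart[:, i] - cart[:, j], axis=1)
        return r * BOHR_TO_ANGSTROM, 0
    if kind == "angle":
        i, j, k = idx
        a = cart[:, i] - cart[:, j]
        b = cart[:, k] - cart[:, j]
        cosang = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))), 0
    if kind == "dihedral":
        i, j, k, l = idx
        b1 = cart[:, j] - cart[:, i]
        b2 = cart[:, k] - cart[:, j]
        b3 = cart[:, l] - cart[:, k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        degenerate = (np.linalg.norm(n1, axis=1) < 1e-10) | (
            np.linalg.norm(n2, axis=1) < 1e-10)
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(np.cross(n1, n2) * (b2 / np.maximum(b2n, 1e-300)[:, None]),
                   axis=1)
        ang = np.degrees(np.arctan2(y, x))
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
        return ang[~degenerate], int(degenerate.sum())
    raise ValueError(f"unknown descriptor kind {kind!r}")


def _histogram_distribution(
    values: np.ndarray,
    bin_width: float,
    descriptor: tuple,
    n_excluded: int = 0,
    n_blocks: int = 16,
    edges: np.ndarray | None = None,
    meta: dict | None = None,
) -> GeometryDistribution:
    if values.size == 0:
        raise ValueError("no values to histogram")
    if edges is None:
        lo = math.floor(values.min() / bin_width) * bin_width - bin_width
        hi = math.ceil(values.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    hist, _ = np.histogram(values, bins=edges, density=True)
    nb = min(n_blocks, max(2, values.size // 64))
    usable = (values.size // nb) * nb
    blocks = values[:usable].reshape(nb, -1)
    bh = np.stack([np.histogram(b, bins=edges, density=True)[0] for b in blocks])
    stderr = _block_stderr(bh)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return GeometryDistribution(
        descriptor=descriptor, edges=edges, hist=hist, stderr=stderr,
        mean=float(values.mean()), std=float(values.std()),
        mode=float(centers[int(np.argmax(hist))]),
        n_used=int(values.size), n_excluded=n_excluded,
        meta=meta or {},
    )


def geometry_distribution(
    samples: np.ndarray,
    basis: NormalModeBasis,
    descriptor: tuple,
    bin_width: float | None = None,
    edges: np.ndarray | None = None,
) -> GeometryDistribution:
    """Quantum distribution of a bond length, angle or dihedral from
    normal-mode Monte Carlo samples (default bins: 0.008 Å, 0.45°)."""
    if bin_width is None:
        bin_width = (DEFAULT_BOND_BIN_ANGSTROM if descriptor[0] == "bond"
                     else DEFAULT_ANGLE_BIN_DEGREES)
    cart = normal_to_cart(samples, basis)
    vals, excl = descriptor_values(cart, descriptor)
    if excl:
        warnings.warn(f"{excl} degenerate geometries excluded from "
                      f"{descriptor}", stacklevel=2)
    return _histogram_distribution(vals, bin_width, descriptor, excl,
                                   edges=edges, meta={"source": "quantum"})


def quasiclassical_histogram(
    traj: Trajectory,
    basis: NormalModeBasis,
    descriptor: tuple,
    bin_width: float | None = None,
    edges: np.ndarray | None = None,
) -> GeometryDistribution:
    """Classical distribution of the same descriptor along a trajectory,
    binned with the same rule so it overlays the quantum one.  For a bound
    mode it piles up at the turning points (arcsine-like), whereas the
    quantum distribution leaks beyond them."""
    if bin_width is None:
        bin_width = (DEFAULT_BOND_BIN_ANGSTROM if descriptor[0] == "bond"
                     else DEFAULT_ANGLE_BIN_DEGREES)
    cart = normal_to_cart(traj.Q, basis)
    vals, excl = descriptor_values(cart, descriptor)
    return _histogram_distribution(vals, bin_width, descriptor, excl,
                                   edges=edges, meta={"source": "quasiclassical"})


# ---------------------------------------------------------------------------
# per-nucleus spread metrics


def position_stddev_report(
    samples: np.ndarray, basis: NormalModeBasis
) -> dict[str, np.ndarray]:
    """Per-nucleus standard deviation of the Cartesian position.

    Returns per-axis σ (N, 3) and the norm √(σx²+σy²+σz²) (N,), both in
    Bohr — the spread metric whose state-to-state differences identify
    which nuclei an excitation involves.
    """
    cart = normal_to_cart(samples, basis)
    sd = cart.std(axis=0)
    return {"sigma_axes": sd, "sigma_norm": np.linalg.norm(sd, axis=1)}


def stddev_difference(
    report_a: dict[str, np.ndarray], report_b: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Differences of the σ metrics between two states (a − b)."""
    return {
        "dsigma_axes": report_a["sigma_axes"] - report_b["sigma_axes"],
        "dsigma_norm": report_a["sigma_norm"] - report_b["sigma_norm"],
    }
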