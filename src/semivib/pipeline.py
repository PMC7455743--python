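"""End-to-end workflow: spectrum → eigenvalues → eigenfunctions → densities.

A RunConfig describes one study (which system, propagation settings,
basis truncation, target states, sampling sizes, master seed); the
pipeline executes the stages in order and writes a manifest recording
every derived seed and output so a run is reproducible bit for bit.

Built-in systems
----------------
``morse_oh``   an O–H-like diatomic whose bond potential is a Morse
               oscillator (the standard anharmonic benchmark at the
               ~3700 cm⁻¹ stretch scale); supports every stage through
               densities and geometry distributions.
``coupled2d``  a two-mode cubically coupled model (spectrum and
               eigenfunction stages).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .constants import AMU_TO_ME, ATOMIC_MASSES, HARTREE_TO_CM
from .cubeio import write_cube
from .densities import (
    DEFAULT_ANGLE_BIN_DEGREES,
    DEFAULT_BOND_BIN_ANGSTROM,
    DEFAULT_GRID_EDGE_ANGSTROM,
    geometry_distribution,
    one_nucleus_density,
    quasiclassical_histogram,
    sample_wavefunction,
)
from .dynamics import initial_conditions_for_state, propagate
from .eigenfunctions import (
    enumerate_basis,
    expansion_coefficients,
    gram_schmidt,
    symmetrize,
)
from .model_systems import make_coupled_model, make_fixture_diatomic, make_morse, to_mass_weighted
from .normal_modes import normal_mode_analysis
from .scivr import build_mc_reference, find_peaks, ta_scivr_spectrum

__all__ = ["RunConfig", "run_pipeline", "builtin_system"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (all defaults match the
    method's standard settings where it states one)."""

    system: str = "morse_oh"
    # morse_oh parameters (Hartree, 1/Bohr, Bohr)
    morse_D: float = 0.1994
    morse_a: float = 1.11
    r_eq: float = 1.832
    # coupled2d parameters
    frequencies_cm: tuple = (1200.0, 3400.0)
    coupling: float = -1.0e-6
    # dynamics
    dt: float = 1.0
    nsteps: int = 2 ** 17
    # basis truncation
    n_max: int = 6
    # targets: tuples of quanta per mode
    target_states: tuple = ((0,), (1,))
    symmetrize_irrep: str | None = None
    # sampling / binning
    n_samples: int = 200_000
    grid_edge_angstrom: float = DEFAULT_GRID_EDGE_ANGSTROM
    bond_bin_angstrom: float = DEFAULT_BOND_BIN_ANGSTROM
    angle_bin_degrees: float = DEFAULT_ANGLE_BIN_DEGREES
    coefficient_threshold: float = 1e-3
    seed: int = 2020
    outdir: str = "semivib_out"

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("frequencies_cm", "target_states"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key]) if key == "target_states" \
                    else tuple(raw[key])
        return cls(**raw)


def builtin_system(config: RunConfig):
    """Instantiate a built-in model: (pes_mass_weighted, omega, system, basis).

    ``system``/``basis`` are None for models without a molecular frame.
    """
    if config.system == "morse_oh":
        D, a, r0 = config.morse_D, config.morse_a, config.r_eq
        mu = (ATOMIC_MASSES["O"] * ATOMIC_MASSES["H"]
              / (ATOMIC_MASSES["O"] + ATOMIC_MASSES["H"])) * AMU_TO_ME
        morse = make_morse(D, a, mu, x0=r0)
        pes_mw = to_mass_weighted(morse, np.array([mu]), np.array([r0]))
        # harmonic frame from the matching harmonic diatomic (k = V''(r0))
        system, pes_cart = make_fixture_diatomic(("O", "H"), 2 * D * a * a, r_eq=r0)
        basis = normal_mode_analysis(system, pes_cart.hessian(system.q_eq.ravel()))
        omega = basis.omega
        pes_mw.meta["morse"] = morse.meta
        return pes_mw, omega, system, basis
    if config.system == "coupled2d":
        lam = config.coupling
        pes = make_coupled_model(config.frequencies_cm,
                                 {(0, 0, 1): lam} if lam else {})
        return pes, pes.meta["omega"], None, None
    raise ValueError(f"unknown builtin system {config.system!r}")


def _state_tag(n: tuple) -> str:
    return "gs" if not any(n) else "-".join(f"m{k+1}q{v}" for k, v in enumerate(n) if v)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for every target state and write a manifest.

    Returns the manifest dict (also written to ``outdir/manifest.json``).
    Identical config + seed reproduce every output byte for byte.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "stages": [],
        "outputs": {},
        "child_seeds": {},
    }
    stage = "setup"
    try:
        pes, omega, system, basis = builtin_system(config)
        d = omega.size
        seed_seq = np.random.SeedSequence(config.seed)
        children = seed_seq.spawn(len(config.target_states))

        basis_states = enumerate_basis(d, config.n_max)
        expansions = {}
        ground_exp = None
        for istate, n in enumerate(config.target_states):
            n = tuple(int(v) for v in n)
            tag = _state_tag(n)
            child_seed = int(children[istate].generate_state(1)[0] % (2 ** 31))
            manifest["child_seeds"][tag] = child_seed

            stage = f"propagate[{tag}]"
            Q0, P0 = initial_conditions_for_state(omega, n)
            traj = propagate(pes, Q0, P0, config.dt, config.nsteps)

            stage = f"spectrum[{tag}]"
            ref = build_mc_reference(omega, n)
            E_harm = float(np.dot(np.asarray(n) + 0.5, omega))
            spec = ta_scivr_spectrum(traj, ref, emin=0.25 * E_harm,
                                     emax=2.0 * E_harm)
            spec_path = out / f"spectrum_{tag}.tsv"
            np.savetxt(spec_path,
                       np.column_stack([spec.E * HARTREE_TO_CM, spec.intensity]),
                       header="energy_cm-1\tintensity", fmt="%.10e")
            peaks = find_peaks(spec)
            E = min(peaks, key=lambda p: abs(p.energy - E_harm)).energy

            stage = f"wavefunction[{tag}]"
            exp = expansion_coefficients(traj, ref, basis_states, E, omega)
            if config.symmetrize_irrep is not None:
                exp = symmetrize(exp, config.symmetrize_irrep)
            if ground_exp is None and not any(n):
                ground_exp = exp
            elif ground_exp is not None and any(n):
                exp = gram_schmidt(exp, ground_exp)
            exp = exp.pruned(config.coefficient_threshold)
            expansions[tag] = (exp, traj)
            wf_path = out / f"wavefunction_{tag}.tsv"
            with open(wf_path, "w") as fh:
                fh.write(f"# eigenvalue_hartree {exp.E:.17e}\n")
                fh.write("# state\tRe(c)\tIm(c)\n")
                for st, cv in zip(exp.states, exp.c):
                    if cv != 0:
                        fh.write(f"{st.label()}\t{cv.real:.17e}\t{cv.imag:.17e}\n")
            manifest["outputs"][f"spectrum_{tag}"] = spec_path.name
            manifest["outputs"][f"wavefunction_{tag}"] = wf_path.name
            manifest["stages"].append({
                "state": tag, "eigenvalue_cm": E * HARTREE_TO_CM,
                "energy_drift": traj.energy_drift,
            })

            if basis is not None and system is not None:
                stage = f"density[{tag}]"
                samples, info = sample_wavefunction(
                    exp, config.n_samples, seed=child_seed)
                grid = one_nucleus_density(
                    samples, basis, spacing_angstrom=config.grid_edge_angstrom)
                cube_path = out / f"density_{tag}.cube"
                write_cube(cube_path, grid, system,
                           comment=f"summed nuclear density {tag}")
                dist = geometry_distribution(
                    samples, basis, ("bond", 0, 1),
                    bin_width=config.bond_bin_angstrom)
                qc = quasiclassical_histogram(traj, basis, ("bond", 0, 1),
                                              bin_width=config.bond_bin_angstrom,
                                              edges=dist.edges)
                dist_path = out / f"bond_0-1_{tag}.tsv"
                np.savetxt(dist_path,
                           np.column_stack([dist.centers, dist.hist,
                                            dist.stderr, qc.hist]),
                           header="bond_angstrom\tquantum\tstderr\tquasiclassical",
                           fmt="%.10e")
                manifest["outputs"][f"density_{tag}"] = cube_path.name
                manifest["outputs"][f"bond_{tag}"] = dist_path.name
                manifest["stages"][-1]["mc_acceptance"] = info["acceptance"]
    except Exception as exc:  # persist a partial manifest before re-raising
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed in stage {stage}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
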