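"""Monte Carlo nuclear densities and geometry-parameter distributions."""

import numpy as np
import pytest
from scipy.stats import norm

import semivib as sv
from semivib.constants import BOHR_TO_ANGSTROM
from semivib.densities import (
    DEFAULT_ANGLE_BIN_DEGREES,
    DEFAULT_BOND_BIN_ANGSTROM,
    descriptor_values,
    stddev_difference,
)

from conftest import spring_network_system
from test_eigenfunctions import pure_state


W = 0.017


class TestSampling:
    def test_harmonic_ground_variance(self, oh_diatomic):
        w = oh_diatomic["omega"]
        exp = pure_state((0,), np.array([w]))
        samples, info = sv.sample_wavefunction(exp, 60000, seed=11)
        se = samples.var() * np.sqrt(2.0 / len(samples)) * 3  # ~3σ for var
        assert abs(samples.var() - 1 / (2 * w)) < max(3 * se, 0.05 / (2 * w))
        assert 0.05 < info["acceptance"] < 0.95

    def test_node_is_local_minimum(self):
        exp = pure_state((1,), np.array([W]))
        samples, _ = sv.sample_wavefunction(exp, 60000, seed=3)
        s = samples[:, 0]
        sig = 1 / np.sqrt(2 * W)
        center = np.mean(np.abs(s) < 0.2 * sig)
        flank = np.mean((np.abs(s) > 0.8 * sig) & (np.abs(s) < 1.0 * sig))
        assert center < 0.5 * flank

    def test_same_seed_is_bit_identical(self):
        exp = pure_state((0,), np.array([W]))
        s1, _ = sv.sample_wavefunction(exp, 5000, seed=42)
        s2, _ = sv.sample_wavefunction(exp, 5000, seed=42)
        assert np.array_equal(s1, s2)

    def test_different_seed_differs(self):
        exp = pure_state((0,), np.array([W]))
        s1, _ = sv.sample_wavefunction(exp, 2000, seed=1)
        s2, _ = sv.sample_wavefunction(exp, 2000, seed=2)
        assert not np.array_equal(s1, s2)


class TestNuclearDensity:
    def test_sum_integrates_to_atom_count(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 40000, seed=5)
        grid = sv.one_nucleus_density(samples, oh_diatomic["basis"])
        assert grid.integral() == pytest.approx(2.0, abs=1e-6)
        assert np.all(grid.per_nucleus >= 0)

    def test_default_spacing_is_0049_angstrom(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 5000, seed=5)
        grid = sv.one_nucleus_density(samples, oh_diatomic["basis"])
        assert grid.spacing * BOHR_TO_ANGSTROM == pytest.approx(0.049)

    def test_equilibrium_on_grid_point(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 5000, seed=5)
        grid = sv.one_nucleus_density(samples, oh_diatomic["basis"])
        frac = (oh_diatomic["basis"].q_eq[0] - grid.origin) / grid.spacing
        assert np.allclose(frac, np.round(frac), atol=1e-9)

    def test_undersized_grid_raises(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 5000, seed=5)
        with pytest.raises(ValueError, match="enlarge"):
            sv.one_nucleus_density(
                samples, oh_diatomic["basis"],
                origin=oh_diatomic["basis"].q_eq[0] - 0.05,
                shape=(3, 3, 3))

    def test_hydrogen_marginal_matches_analytic_gaussian(self, oh_diatomic):
        """The H nucleus z-marginal is a Gaussian with variance
        (L_z/√m)² / (2ω) — checked bin-wise against block-averaged MC errors."""
        basis = oh_diatomic["basis"]
        w = oh_diatomic["omega"]
        exp = pure_state((0,), np.array([w]))
        samples, _ = sv.sample_wavefunction(exp, 200000, seed=17)
        cart = sv.normal_to_cart(samples, basis)
        zH = cart[:, 1, 2]
        coef = basis.L[5, 0] / np.sqrt(basis.masses_au[1])  # H z-row of the map
        sigma = abs(coef) / np.sqrt(2 * w)
        mu = basis.q_eq[1, 2]
        edges = np.linspace(mu - 4 * sigma, mu + 4 * sigma, 13)
        nb = 16
        blocks = zH[: (len(zH) // nb) * nb].reshape(nb, -1)
        bh = np.stack([np.histogram(b, bins=edges)[0] / b.size for b in blocks])
        obs = bh.mean(axis=0)
        expected = np.diff(norm.cdf(edges, loc=mu, scale=sigma))
        # block SE captures chain correlation; the binomial SE is a floor
        # against the χ² noise of the block estimate itself
        se_block = bh.std(axis=0, ddof=1) / np.sqrt(nb)
        se_iid = np.sqrt(expected * (1 - expected) / len(zH))
        se = np.maximum(se_block, se_iid)
        assert np.all(np.abs(obs - expected) <= 3 * se + 1e-4)


class TestDensityDifference:
    def _grid(self, oh_diatomic, n, seed):
        exp = pure_state((n,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 60000, seed=seed)
        return sv.one_nucleus_density(
            samples, oh_diatomic["basis"],
            origin=np.array([-0.5, -0.5, -1.2]), shape=(12, 12, 48))

    def test_self_difference_vanishes(self, oh_diatomic):
        d = self._grid(oh_diatomic, 0, 9)
        diff = sv.density_difference(d, d)
        assert diff.is_difference
        assert np.all(diff.per_nucleus == 0)

    def test_antisymmetry(self, oh_diatomic):
        d0 = self._grid(oh_diatomic, 0, 9)
        d1 = self._grid(oh_diatomic, 1, 10)
        ab = sv.density_difference(d1, d0)
        ba = sv.density_difference(d0, d1)
        assert np.allclose(ab.per_nucleus, -ba.per_nucleus)

    def test_excited_minus_ground_structure(self, oh_diatomic):
        """One quantum on the stretch: density moves from the center of the
        H marginal to the flanks, and the difference integrates to ~0."""
        d0 = self._grid(oh_diatomic, 0, 9)
        d1 = self._grid(oh_diatomic, 1, 10)
        diff = sv.density_difference(d1, d0)
        dz = diff.per_nucleus[1].sum(axis=(0, 1))  # H z-profile
        z = d0.origin[2] + d0.spacing * (np.arange(d0.shape[2]) + 0.5)
        mu = oh_diatomic["basis"].q_eq[1, 2]
        w = oh_diatomic["omega"]
        sigH = (abs(oh_diatomic["basis"].L[5, 0])
                / np.sqrt(oh_diatomic["basis"].masses_au[1]) / np.sqrt(2 * w))
        center = np.abs(z - mu) < 0.7 * sigH
        flank = (np.abs(z - mu) > 1.2 * sigH) & (np.abs(z - mu) < 2.5 * sigH)
        assert dz[center].sum() < 0
        assert dz[flank].sum() > 0
        assert abs(diff.integral()) < 1e-6

    def test_grid_mismatch_rejected(self, oh_diatomic):
        d0 = self._grid(oh_diatomic, 0, 9)
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 5000, seed=1)
        other = sv.one_nucleus_density(samples, oh_diatomic["basis"])
        with pytest.raises(ValueError, match="grids"):
            sv.density_difference(d0, other)


class TestGeometryDistributions:
    def test_bond_distribution_gaussian(self, oh_diatomic):
        """Ground-state bond length: Gaussian at r_eq with σ² = 1/(2μω) —
        closed form for the single stretching mode."""
        w = oh_diatomic["omega"]
        mu_red = oh_diatomic["pes"].meta["mu"]
        exp = pure_state((0,), np.array([w]))
        samples, _ = sv.sample_wavefunction(exp, 100000, seed=21)
        dist = sv.geometry_distribution(samples, oh_diatomic["basis"],
                                        ("bond", 0, 1))
        r_eq = oh_diatomic["pes"].meta["r_eq"] * BOHR_TO_ANGSTROM
        sigma = np.sqrt(1 / (2 * mu_red * w)) * BOHR_TO_ANGSTROM
        assert dist.mean == pytest.approx(r_eq, abs=4 * sigma / np.sqrt(1e5))
        assert dist.std == pytest.approx(sigma, rel=0.03)
        assert dist.mode == pytest.approx(r_eq, abs=2 * DEFAULT_BOND_BIN_ANGSTROM)
        area = np.sum(dist.hist * np.diff(dist.edges))
        assert area == pytest.approx(1.0, rel=1e-9)

    def test_default_bin_widths(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 20000, seed=2)
        bond = sv.geometry_distribution(samples, oh_diatomic["basis"],
                                        ("bond", 0, 1))
        assert np.diff(bond.edges)[0] == pytest.approx(DEFAULT_BOND_BIN_ANGSTROM)
        assert DEFAULT_ANGLE_BIN_DEGREES == 0.45

    def test_excited_bond_distribution_bimodal(self, oh_diatomic):
        exp = pure_state((1,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 100000, seed=23)
        dist = sv.geometry_distribution(samples, oh_diatomic["basis"],
                                        ("bond", 0, 1))
        r_eq = oh_diatomic["pes"].meta["r_eq"] * BOHR_TO_ANGSTROM
        i_eq = int(np.argmin(np.abs(dist.centers - r_eq)))
        near = dist.hist[max(i_eq - 1, 0):i_eq + 2].mean()
        left = dist.hist[:i_eq - 1].max()
        right = dist.hist[i_eq + 2:].max()
        assert near < 0.6 * left and near < 0.6 * right

    def test_angle_and_dihedral_descriptors(self):
        # bent 4-atom chain with a known dihedral of 90 degrees
        cart = np.array([[
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, -1.0, 1.0],
        ]])
        ang, _ = descriptor_values(cart, ("angle", 0, 1, 2))
        assert ang[0] == pytest.approx(90.0)
        dih, nexc = descriptor_values(cart, ("dihedral", 0, 1, 2, 3))
        assert nexc == 0
        assert abs(dih[0]) == pytest.approx(90.0)

    def test_colinear_dihedral_excluded(self):
        cart = np.array([[
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 2.0],
            [0.0, 1.0, 3.0],
        ]])
        vals, nexc = descriptor_values(cart, ("dihedral", 0, 1, 2, 3))
        assert nexc == 1
        assert vals.size == 0

    def test_unknown_atom_index_rejected(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 1000, seed=2)
        with pytest.raises(ValueError, match="outside"):
            sv.geometry_distribution(samples, oh_diatomic["basis"],
                                     ("bond", 0, 5))


@pytest.fixture(scope="module")
def harmonic_fundamental(oh_diatomic):
    w = oh_diatomic["omega"]
    pes1 = sv.PESModel(
        dim=1,
        energy=lambda q: 0.5 * w * w * float(q[0] * q[0]),
        gradient=lambda q: w * w * np.asarray(q, float),
        hessian=lambda q: np.array([[w * w]]),
        coords="mass-weighted")
    Q0, P0 = sv.initial_conditions_for_state(np.array([w]), (1,))
    traj = sv.propagate(pes1, Q0, P0, 2.0, 20000)
    exp = pure_state((1,), np.array([w]))
    samples, _ = sv.sample_wavefunction(exp, 120000, seed=31)
    return {"traj": traj, "samples": samples, "w": w}


class TestQuasiclassical:
    def test_classical_histogram_peaks_at_turning_points(
            self, oh_diatomic, harmonic_fundamental):
        hf = harmonic_fundamental
        dist = sv.geometry_distribution(hf["samples"], oh_diatomic["basis"],
                                        ("bond", 0, 1))
        qc = sv.quasiclassical_histogram(hf["traj"], oh_diatomic["basis"],
                                         ("bond", 0, 1), edges=dist.edges)
        populated = np.where(qc.hist > 0)[0]
        lo, hi = populated[0], populated[-1]
        top2 = set(np.argsort(qc.hist)[-2:])
        # maxima sit in the outermost populated bins (arcsine density)
        assert top2 <= {lo, lo + 1, hi - 1, hi}
        area = np.sum(qc.hist * np.diff(qc.edges))
        assert area == pytest.approx(1.0, rel=1e-9)

    def test_quantum_mass_beyond_classical_turning_points(
            self, oh_diatomic, harmonic_fundamental):
        """Tunneling tails: the n=1 quantum distribution keeps ≥1% of its
        mass outside the classical turning points (11.6% in closed form)."""
        hf = harmonic_fundamental
        qmax = np.max(np.abs(hf["traj"].Q))
        frac = np.mean(np.abs(hf["samples"][:, 0]) > qmax)
        assert frac >= 0.01
        # classical motion stays at the turning points (up to Verlet
        # discretization error in the conserved energy)
        assert np.max(np.abs(hf["traj"].Q)) <= np.sqrt(3 / hf["w"]) * (1 + 1e-3)


class TestStddevReport:
    def test_harmonic_sigma_closed_form(self, oh_diatomic):
        w = oh_diatomic["omega"]
        basis = oh_diatomic["basis"]
        exp = pure_state((0,), np.array([w]))
        samples, _ = sv.sample_wavefunction(exp, 100000, seed=41)
        rep = sv.position_stddev_report(samples, basis)
        sigH = (abs(basis.L[5, 0]) / np.sqrt(basis.masses_au[1])
                / np.sqrt(2 * w))
        assert rep["sigma_norm"][1] == pytest.approx(sigH, rel=0.03)

    def test_identical_state_difference_is_zero(self, oh_diatomic):
        exp = pure_state((0,), np.array([oh_diatomic["omega"]]))
        samples, _ = sv.sample_wavefunction(exp, 50000, seed=43)
        rep = sv.position_stddev_report(samples, oh_diatomic["basis"])
        diff = stddev_difference(rep, rep)
        assert np.all(diff["dsigma_norm"] == 0)

    def test_excited_to_ground_ratio_sqrt3(self, oh_diatomic):
        w = np.array([oh_diatomic["omega"]])
        s0, _ = sv.sample_wavefunction(pure_state((0,), w), 150000, seed=45)
        s1, _ = sv.sample_wavefunction(pure_state((1,), w), 150000, seed=46)
        r0 = sv.position_stddev_report(s0, oh_diatomic["basis"])
        r1 = sv.position_stddev_report(s1, oh_diatomic["basis"])
        ratio = r1["sigma_norm"][1] / r0["sigma_norm"][1]
        assert ratio == pytest.approx(np.sqrt(3.0), rel=0.02)


def test_error_bars_shrink_with_sample_size(oh_diatomic):
    """Mean bin-wise MC standard error scales like 1/√n (block average)."""
    w = np.array([oh_diatomic["omega"]])
    exp = pure_state((0,), w)
    edges = None
    ses = []
    for n, seed in [(30000, 51), (120000, 52)]:
        samples, _ = sv.sample_wavefunction(exp, n, seed=seed)
        dist = sv.geometry_distribution(samples, oh_diatomic["basis"],
                                        ("bond", 0, 1), edges=edges)
        edges = dist.edges
        core = dist.hist > 0.1 * dist.hist.max()
        ses.append(dist.stderr[core].mean())
    assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.4)
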