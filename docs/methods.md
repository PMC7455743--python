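# Methods

This note documents the models, numerical choices and limitations behind
`semivib`, in the order the pipeline uses them. Internal units are
Hartree atomic units throughout (ħ = 1); cm⁻¹ and Å appear only at I/O
boundaries, with CODATA-2018 conversion factors frozen in
`semivib.constants`.

## Model surfaces

Every stage consumes a `PESModel` exposing energy, gradient and Hessian
at arbitrary points; the Hessian is needed along trajectories because the
monodromy matrix is propagated with the local curvature at every step.
Three families ship with the package:

- **Morse oscillator** `V(x) = D(1−e^{−a(x−x₀)})²` with the closed-form
  spectrum `E_n = ω₀(n+½) − [ω₀(n+½)]²/(4D)`, `ω₀ = a√(2D/m)`. The
  default O–H-like parameterization (D = 0.1994 Ha, a = 1.11 Bohr⁻¹,
  O–H reduced mass) puts the harmonic frequency at 3700.7 cm⁻¹ and the
  anharmonic fundamental near 3544 cm⁻¹ — the energy scale of hydride
  stretches, where anharmonicity matters most.
- **Cubically coupled few-mode models** `V = ½Σω_k²q_k² + Σλ_ijk q_iq_jq_k`
  in mass-weighted coordinates. Cubic (not bilinear) couplings keep the
  Hessian at the minimum diagonal, so the harmonic analysis is untouched
  and every anharmonic effect is attributable to the couplings. Because a
  cubic surface is globally unbounded, construction scans a declared
  sampling box (default ±4σ_k of each mode's ground-state width,
  σ_k = 1/√(2ω_k), the region quantum sampling actually visits) and
  rejects parameter sets whose potential dips below the minimum inside
  it. For soft modes this caps |λ| at a few 10⁻⁶ — larger values would
  not represent a bound molecule at these frequencies.
- **Harmonic diatomic fixture** with the bond potential ½k(r−r_eq)²
  expressed over all six Cartesian coordinates, so the full
  normal-mode/projection machinery is exercised (3N−5 = 1 mode).

Gradients and Hessians are analytic everywhere; a finite-difference
consistency check at 10⁻⁶ relative tolerance is part of the test suite.

## Normal-mode analysis

The Cartesian Hessian is mass-weighted and the rigid-body space
(translations plus infinitesimal rotations about the center of mass,
null rotations dropped for linear molecules) is projected out before
diagonalization. Eigenvalues above −10⁻⁸ a.u. are treated as numerical
zeros; anything below raises, because the semiclassical method assumes a
minimum. Modes are sorted by ascending frequency — "the last mode" is
always the highest-frequency one (the hydroxyl stretch in the
protonated-glycine setting this package models its workflow on) — and
eigenvector signs are fixed deterministically. Eckart-frame refinement
is deliberately not applied: densities are defined in the body-fixed
frame of the linear normal-mode map (below), and a per-sample rotational
re-fit would change the reported per-nucleus lobes.

Mirror-plane (Cs-type) irrep labels are assigned automatically when the
declared plane is a true symmetry element (reflection must permute atoms
onto equivalent positions and send each mode to ±itself); otherwise
labels are user input.

## Trajectories, action, monodromy

Velocity Verlet in mass-weighted coordinates. The classical action
∫(T−V)dt is accumulated by the trapezoid rule; the monodromy matrix is
pushed forward with the exact Jacobian of the discrete Verlet map — a
composition of shears — so symplecticity (det M = 1, MᵀJM = J) holds to
round-off by construction rather than by tolerance. Initial conditions
follow the quasi-classical prescription: Q₀ = 0, P_k = √((2n_k+1)ω_k),
placing the trajectory energy at the harmonic estimate of the target
state, one trajectory per state. A coordinate box truncates
dissociating trajectories with a warning.

Defaults: dt = 1.0 a.u. and 2¹⁷ steps (T ≈ 1.3·10⁵ a.u., Fourier
resolution ≈ 10.5 cm⁻¹). These were chosen so that the Verlet frequency
error (~(ωdt)²/24 relative) stays near 10⁻⁵ at hydride-stretch
frequencies — an order below the accuracy the eigenvalue extraction
itself delivers; both are configuration values. Trajectories persist to
HDF5, and a plain-text columnar layout (t, Q, P, S, E, Hessian) serves
as the import path for externally computed ab initio trajectories; the
monodromy is rebuilt from the stored Hessians with the same update.

## Time-averaged semiclassical spectra

The positive-definite single-trajectory form is

    I(E) ∝ (1/2πT) |∫₀ᵀ dt exp{i[S(t) + Et + φ(t)]} ⟨χ|g(Q(t),P(t))⟩|²

with coherent states of diagonal width Γ_kk = ω_k and φ(t) the phase of
the Herman–Kluk prefactor

    C_t = √det{½[M_qq + Γ⁻¹M_ppΓ + iΓ⁻¹M_pq − iM_qpΓ]}.

The sign convention of the imaginary blocks is pinned by the harmonic
limit: C_t must reduce to e^{−iωt/2} so that peaks land at (n+½)ω. Only
the phase of C_t enters (the separable/phase-only practice for
single-trajectory time averaging, which guarantees I ≥ 0); the branch is
made continuous by unwrapping the determinant's phase, with a 10⁻¹²
regularization at caustics, and a warning fires if the phase jumps by
more than π per step (dt too large).

The reference |χ⟩ is the "multiple coherent" two-term combination at
(Q₀, +P₀) and (Q₀, −P₀) with signs (1, (−1)^Σn): it doubles the overlap
with harmonic states of the target total parity and cancels the opposite
parity exactly in the harmonic limit. On anharmonic surfaces the
cancellation is only approximate — opposite-parity lines can appear with
small weight — which is why eigenvalues are read from the peak nearest
the harmonic estimate of the target state rather than blindly from the
tallest or lowest line.

The time integral is evaluated by FFT over an 8× zero-padded grid
(padding refines sampling; the physical resolution stays ΔE = 2π/T).
Peak positions are then refined by bounded maximization of the
continuous finite-T Fourier integral within one resolution of the grid
maximum — the grid only locates peaks, the refinement is what delivers
eigenvalues well below ΔE. With the rectangular window (default;
positions, not lineshapes, are the contract) each line carries sinc²
sidelobes of 1–5% height, so `find_peaks` suppresses candidates within
6ΔE of a taller peak unless they exceed 10% of its height; genuinely
close lines of comparable height survive and are flagged unresolved. A
Hann window is available.

Measured on the O–H Morse well at the default settings: ZPE within
0.011% and the n = 1 level within 0.006% of the sinc-DVR oracle;
fundamental within 0.015% of the analytic Morse transition.

## Eigenfunction expansion

The truncated basis keeps the ground state, all single-mode excitations
and all two-mode simultaneous excitations with up to n_max = 6 quanta
per mode — 1 + M·n_max + C(M,2)·n_max² states, i.e. 12,799 for M = 27 —
in frozen graded-lexicographic order so coefficient files are
byte-reproducible. Coefficients are time averages
c_n ∝ (1/T)∫dt e^{i[S+Et+φ]}⟨Φ_n|g(t)⟩ evaluated with the closed-form
ladder representation of the coherent-state/Hermite overlaps (no
quadrature); per-mode overlap tables make the sweep linear in basis
size. The eigenvalue fed in is the refined peak, not a grid point.

The global phase makes the largest coefficient real positive (any
convention cancels in |ψ|²). Two failure modes raise: a collapsed raw
norm (E off every spectral line) and a near-zero overlap between the
extracted eigenfunction and the reference state itself — the correlation
functions are reference-independent, so this overlap is what detects a
parity-mismatched reference. Symmetrization zeroes coefficients outside
the requested irrep (product-state parity from per-mode labels);
Gram–Schmidt orthogonalizes excited against ground expansions in
coefficient space, the only well-posed reading at this representation
level. Pruning at |c| ≤ 10⁻³ is available and leaves ⟨Q⟩ and ⟨Q²⟩
(computed exactly via ladder matrix elements) essentially unchanged.

Wavefunction evaluation uses the stable normalized Hermite recurrence;
at n_max = 6 overflow is not a concern but the recurrence is kept in
normalized form regardless.

## Monte Carlo densities

Sampling of |ψ(Q)|² uses an ensemble of 64 Metropolis–Hastings walkers
alternating two kernels per sweep: a local Gaussian random walk
(per-mode scale s/√(2ω_k), s adapted during 400 burn-in sweeps to 30–50%
acceptance, then frozen) and, with probability ½, an independence
proposal from the dominant harmonic state's Gaussian envelope (per-mode
variance (2n_k+1)/(2ω_k), a slightly heavier-tailed exact envelope of
the target for pure states). The independence moves decorrelate the
chain almost completely for near-harmonic targets while the local moves
guarantee mixing near nodes; a pure-walk sampler remains available as a
cross-check. Everything is driven by one master seed; child seeds are
spawned deterministically and logged, so fixed seed ⇒ bit-identical
sample streams.

Samples map to Cartesian space through the linear normal-mode map about
q_eq (body-fixed frame — the frame in which per-nucleus density lobes
are well defined; no rotational re-sampling). Per-nucleus histograms
live on a shared cubic grid, default edge 0.049 Å, auto-sized to cover
every nucleus's mean ± 5σ and snapped so the equilibrium position of
atom 1 is a grid point; each nucleus's histogram is normalized to unit
integral so the direct sum integrates to the atom count. More than 1% of
samples outside the grid raises. Output is the standard Gaussian cube
format (origin/axes in Bohr, Z-fastest ordering) written with 17
significant digits so write→read round trips are exact; difference cubes
are signed, and the customary ±0.15 a.u. isosurface level is recorded in
the metadata for visualizers.

Geometry distributions (bond |r_i−r_j| in Å, angle via arccos, dihedral
via the signed two-plane atan2 formula on (−180°, 180°]) use 0.008 Å and
0.45° default bins; colinear dihedral geometries are excluded and
counted. Error bars come from 16-block averaging of the sample stream;
where an analytic reference exists the tests floor the block estimate
with the iid binomial error, since the block estimator itself carries
χ² noise at this block count. Quasi-classical histograms bin the same
descriptor along the trajectory with the same edges, reproducing the
turning-point-peaked classical density that the quantum distribution
overshoots (≈11% of the n = 1 mass lies beyond the turning points).

## DVR oracle

Uniform-grid sinc DVR (kinetic matrix π²/3 on the diagonal,
2(−1)^{i−j}/(i−j)² off it, over 2mΔx²), dense symmetric eigensolve, 1D
and tensor-product 2D (capped at 128² points). Eigenvectors are
grid-normalized; boundary amplitude above 10⁻⁶ raises a widen-the-grid
error. Its role is small-instance ground truth: eigenvalues for the
spectra, and coefficient vectors (by quadrature projection onto the same
harmonic basis) for eigenfunction fidelity. It is not used anywhere in
the production path.

## Problem sizes and what the tests show

The test suite and the acceptance script run entirely on 1D/2D model
systems: 2¹⁴–2¹⁷ trajectory steps, 10⁵–10⁶ Monte Carlo samples, bases of
≤ 19 states plus the 12,799-state enumeration check. These sizes make
every claim checkable against closed forms or the DVR oracle. What
passing does **not** show: performance of the separable-prefactor
approximation on strongly chaotic high-dimensional surfaces, rotational
effects (the body-fixed linear map ignores ro-vibrational coupling), or
any statement about real ab initio surfaces — on real molecules the
trajectory input would come from electronic-structure dynamics through
the text import path, and accuracy is then limited by that surface.

## Known limitations

- Single-trajectory-per-state scheme; no Husimi-weighted multi-trajectory
  averaging (config-level extension point).
- Harmonic basis truncated at pair excitations; states dominated by
  triple combinations are not representable.
- No IR intensities (power spectra only), no transition-state support
  (one imaginary mode aborts), no ≥3D exact reference.
- The MC reference's parity cancellation is exact only in the harmonic
  limit; peak selection near the harmonic estimate is the mitigation.
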