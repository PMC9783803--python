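# Methods

This note records the models, estimators and numerical choices behind
`hbridge`, and what the synthetic generator does and does not emulate.

## The model bridges

The package analyses D-H...A hydrogen bridges. Because ab initio forces
are out of scope, trajectories are generated on analytic model surfaces
chosen to have the statistical structure the analyses assume:

* **harmonic** — `V(x) = k x²/2`. Default `k = 987 kcal/mol/Å²`, which for
  a 1.008 amu proton gives a 3398 cm⁻¹ stretch, the free X-H reference in
  the 2800-3700 cm⁻¹ signature region.
* **double_well** — `V(x) = V0 ((x/a0)² − 1)²`, minima at `x = ±a0`,
  barrier `V0` at the bridge midpoint. Defaults `V0 = 3.1 kcal/mol`,
  `a0 = 0.35 Å`: a moderately strong bridge whose classical transfer
  barrier sits at the few-kcal/mol scale reported for carboxylic O-H...O
  dimers, with wells ~0.7 Å apart inside a 2.6 Å bridge.
* **coupled_bridge** — the double well with `a(R) = a0 + c_a (R − R0)`
  and `V0(R) = V0 + c_V (R − R0)` plus a harmonic restraint
  `k_R (R − R0)²/2` on the donor-acceptor distance (`R0 = 2.6 Å`,
  `k_R = 100 kcal/mol/Å²`, `c_a = 0.25`, `c_V = 8 kcal/mol/Å`). Bridge
  compression brings the wells together and lowers the barrier — the
  geometric coupling that gates proton transfer. The R coordinate
  carries the heavy-pair reduced mass (`m_heavy/2`).

Forces are exact analytic gradients (tested against 5-point stencils to
1e-6 relative). Deuteration is modelled by `mass_H = 2.014 amu`.

Units: Å, fs, amu and kcal/mol everywhere in memory; bohr and atomic time
units appear only at the CPMD-dialect file boundary (0.52917721 Å/bohr,
0.02418884 fs per a.u. of time); `k_B = 0.0019872 kcal/mol/K`,
hartree → kcal/mol = 627.5095.

## Sampling

Classical MD is velocity-Verlet with Nosé-Hoover chains (length 4,
default time constant 20 fs), Maxwell-Boltzmann initial velocities from
an explicit integer seed, default `dt = 0.1 fs` and `T = 297 K`. Identical
seed and settings give bit-identical trajectories. For the 1- and 2-DOF
bridges the integrator runs in a specialized scalar loop (same algorithm;
the array path remains for the bead systems) so that the multi-million-step
Boltzmann-inversion runs stay cheap. Energy conservation is verified as a
secular-drift bound on block-averaged total energy (the instantaneous
total energy of a symplectic integrator oscillates at O(dt²) but does not
drift): |ΔE/E₀| < 1e-4 over 10 ps at dt = 0.1 fs.

PIMD samples the P-bead discretized path distribution

    exp(−β Σ_k [ m P/(2 β² ħ²) (x_k − x_{k+1})² + V(x_k)/P ])

in staging coordinates (u₁ = x₁, u_k = x_k − ((k−1)x_{k+1} + x₁)/k),
which diagonalize the spring term; staging masses are m, m·k/(k−1), and
every staging mode carries its own (massive) Nosé-Hoover chain — the
stiff bead springs are not ergodic under a single global thermostat.
Non-centroid modes are thermostatted on the spring timescale 1/ω_P with
ω_P = √P/(βħ); the centroid uses the classical time constant. P = 1
collapses exactly to classical sampling (zero spring, identity staging).

Estimator checks: the primitive and centroid-virial total-energy
estimators (block-averaged standard errors, 10 blocks by default, warning
below that) agree with each other and, for the harmonic bridge, with the
(ħω/2)·coth(βħω/2) law. The exact finite-P harmonic moments
⟨x²⟩_P = (1/βm) Σ_q 1/(ω² + ω_q²), ω_q = (2P/βħ)·sin(πq/P), derived from
the normal-mode Gaussian integrals, serve as an independent oracle for
the Trotter convergence trend (P = 1, 8, 16, 32 monotone toward the coth
law). The independent quantum reference for anharmonic wells is a
finite-difference diagonalization of the 1D Hamiltonian with Boltzmann
weighting of all eigenstates; a grid is rejected if halving its spacing
moves the ground state by more than 1e-6 hartree.

## Analyses

* **Spectra.** The vibrational density of states is a Welch-averaged
  periodogram (Hann window, 50% overlap, mass weighting — all exposed) of
  the selected atoms' velocity components, not a cosine transform of the
  VACF, so nonnegativity is structural. Normalization is fixed by the
  Parseval identity: with a rectangular window and one segment the
  spectrum integrates over its cm⁻¹ axis to the mean squared
  mass-weighted velocity, which also makes per-atom decompositions
  exactly additive over disjoint selections. Band maxima break ties
  toward lower wavenumber; shifts are reported as (later − reference), so
  blueshifts are positive. No quantum correction factors are applied;
  absolute intensities are arbitrary and only peak positions and shifts
  are meaningful.
* **Proton distributions and PMFs.** 2D (r_DH, r_HA) histograms are
  normalized to unit integral (Å⁻² density, matching the 1 Å⁻²
  isocontour convention); PMFs are A(ξ) = −k_BT ln p(ξ) shifted to zero
  at the minimum, with empty bins masked. No r² Jacobian is applied by
  default — the bridge coordinate is treated as a 1D coordinate matching
  the distance axis of the histograms; a volume-corrected variant is
  available. For bead trajectories the default position statistic pools
  all beads (the quantum estimator); a centroid variant exists. A pooled-
  bead "PMF" therefore includes ring-polymer spread, and is reported as
  such rather than as a centroid free energy.
* **Transfer events.** On ξ = r_DH − r_HA a two-threshold (hysteresis)
  state machine counts only confirmed crossings of the far band
  (default h = 0.1 Å, chosen to suppress thermal recrossing noise);
  residence fractions are computed over state-assigned frames and sum to
  one exactly.
* **Minimum-image distances** wrap the separation into the central cell
  in fractional coordinates and minimize over the 27 nearest images of a
  (possibly triclinic) cell built with **a** along x and **b** in the
  xy-plane.
* **Descriptors.** Espinosa bond energies use E = ½|V_BCP| (hartree →
  kcal/mol 627.5095), returned as positive magnitudes; the relation is
  withheld for shared-shell bonds (∇²ρ < 0). Covalency classes follow the
  sign pattern of ∇²ρ and H_BCP, with |H_BCP| < 1e-6 a.u. treated as zero
  (logged, classed electrostatic). SAPT totals are plain component sums;
  the audit flags deviations from a reported total beyond a tolerance
  (default 0.01 kcal/mol — the published tables round to 3 decimals, so
  sums can differ from printed totals by ~0.001) and reports the sign of
  the steric balance E_elst + E_exch.

## Problem sizes

The statistical test points were sized once, as study conditions, and are
not tuned: harmonic PIMD checks use P = 32 with ~1e6 sampled bead
configurations (32768 steps at dt = 0.25 fs); the double-well bead density
uses 60k steps; classical Boltzmann-inversion recovery uses 1.2e6 steps at
dt = 0.5 fs (recovers the 3.1 kcal/mol barrier within 0.3); the
quantum-vs-classical barrier comparison uses 1e6 classical and 1.2e5
8-bead steps and requires a 3-SE separation. Kinetic-energy equipartition
is averaged over six independent seeds because single-trajectory kinetic
energy decorrelates slowly under Nosé-Hoover chains, making block errors
unreliable there.

## What the generator does and does not emulate

It reproduces: thermostatted sampling of a double-well proton coordinate
coupled to a breathing donor-acceptor distance, quantum delocalization
and barrier lowering under Trotter quantization, redshifted stretch bands
for bound vs free protons, and trajectory files in the two supported
dialects. It does not contain electronic structure: no anharmonic
couplings beyond the quartic form, no Fermi resonances, no environment
(crystal field) fluctuations, no dipole surface (so no IR intensities),
and its barrier/geometry parameters are chosen at the reported scale
rather than fitted to any system. Passing tests therefore validate the
estimators and the direction of physical effects, not the ab initio
magnitudes of any real compound.

## Known limitations

* PIMD supports the analytic bridges only (reduced coordinates), not
  arbitrary atomistic systems.
* The minimum-image search covers the first image shell after fractional
  wrapping; for extremely skewed cells (far beyond the crystallographic
  cells handled here) a wider search could in principle be needed.
* The pooled-bead PMF and the centroid PMF answer different questions;
  neither is asserted to be "the" published curve.
* Espinosa energies inherit the 4-decimal rounding of tabulated V_BCP
  (~0.5% on the weakest contacts).
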