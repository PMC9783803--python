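"""Exact quantum references for the one-dimensional bridge potentials.

The thermal position density is obtained by diagonalizing the 1D
Hamiltonian on a uniform grid (second-order finite differences) and
Boltzmann-weighting the eigenstates:  n(x) = Σ_n |ψ_n(x)|² e^{-βE_n} / Z.
This is the independent oracle against which the path-integral sampler is
validated; closed forms for the harmonic oscillator are provided as well.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import eigh_tridiagonal

from ..errors import ConfigurationError, DataError
from ..units import HARTREE_TO_KCAL, HBAR_MECH, KB_MECH, KCAL_PER_MOL_TO_MECH
from .potentials import ModelPotential, evaluate_potential

__all__ = [
    "reference_quantum_density",
    "harmonic_quantum_msd",
    "harmonic_quantum_energy",
    "harmonic_classical_msd",
    "harmonic_finite_p_msd",
    "harmonic_omega",
]

_GS_TOL_KCAL = 1.0e-6 * HARTREE_TO_KCAL  # grid-refinement tolerance


def _solve_grid(model: ModelPotential, grid: np.ndarray):
    dx = grid[1] - grid[0]
    v_kcal, _ = evaluate_potential(model, grid[:, None])
    v = v_kcal * KCAL_PER_MOL_TO_MECH
    t = HBAR_MECH**2 / (2.0 * model.mass_H * dx**2)
    evals, evecs = eigh_tridiagonal(v + 2.0 * t, np.full(grid.size - 1, -t))
    return evals, evecs


def reference_quantum_density(
    model: ModelPotential, temperature: float, grid: np.ndarray
) -> np.ndarray:
    """Exact thermal position density (Å⁻¹) on ``grid`` for a 1D model.

    Raises a resolution error when halving the grid spacing still moves
    the ground-state energy by more than 1e-6 hartree.
    """
    if model.n_dof != 1:
        raise ConfigurationError(
            "reference density requires a 1D potential (harmonic/double_well)")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 16:
        raise DataError("grid must be 1D with at least 16 points")
    if not np.all(np.diff(grid) > 0):
        raise DataError("grid must be strictly increasing")
    dx = np.diff(grid)
    if not np.allclose(dx, dx[0], rtol=1e-10):
        raise DataError("grid must be uniform")

    evals, evecs = _solve_grid(model, grid)
    fine = np.linspace(grid[0], grid[-1], 2 * grid.size - 1)
    evals_f, _ = _solve_grid(model, fine)
    if abs(evals_f[0] - evals[0]) / KCAL_PER_MOL_TO_MECH > _GS_TOL_KCAL:
        raise DataError(
            "grid too coarse: ground-state energy shifts by more than "
            "1e-6 hartree on refinement")

    beta_mech = 1.0 / (KB_MECH * temperature)
    weights = np.exp(-beta_mech * (evals - evals[0]))
    weights /= weights.sum()
    density = (evecs**2 * weights[None, :]).sum(axis=1) / (grid[1] - grid[0])
    density /= np.trapezoid(density, grid)
    return density


# -- harmonic-oscillator closed forms ---------------------------------------

def harmonic_omega(model: ModelPotential) -> float:
    """Angular frequency ω = √(k/m) of the harmonic model, rad/fs."""
    if model.kind != "harmonic":
        raise ConfigurationError("harmonic model required")
    return math.sqrt(model.k_harm * KCAL_PER_MOL_TO_MECH / model.mass_H)


def harmonic_quantum_msd(omega: float, mass: float, temperature: float) -> float:
    """⟨x²⟩ = (ħ/2mω)·coth(βħω/2) in Å² (ω in rad/fs, mass in amu)."""
    beta = 1.0 / (KB_MECH * temperature)
    return HBAR_MECH / (2.0 * mass * omega) \
        / math.tanh(beta * HBAR_MECH * omega / 2.0)


def harmonic_classical_msd(omega: float, mass: float, temperature: float) -> float:
    """Classical equipartition ⟨x²⟩ = k_BT/(mω²) in Å²."""
    return KB_MECH * temperature / (mass * omega**2)


def harmonic_quantum_energy(omega: float, temperature: float) -> float:
    """⟨E⟩ = (ħω/2)·coth(βħω/2) in kcal/mol."""
    beta = 1.0 / (KB_MECH * temperature)
    e_mech = HBAR_MECH * omega / 2.0 \
        / math.tanh(beta * HBAR_MECH * omega / 2.0)
    return e_mech / KCAL_PER_MOL_TO_MECH


def harmonic_finite_p_msd(omega: float, mass: float, temperature: float,
                          P: int) -> float:
    """Exact ⟨x²⟩ of the P-bead ring polymer for a harmonic mode (Å²).

    From the normal-mode Gaussian integrals of the discretized path:
    ⟨x²⟩_P = (1/βm) Σ_q 1/(ω² + ω_q²),  ω_q = (2P/βħ)·sin(πq/P).
    """
    beta = 1.0 / (KB_MECH * temperature)
    q = np.arange(P)
    omega_q = (2.0 * P / (beta * HBAR_MECH)) * np.sin(np.pi * q / P)
    return float(np.sum(1.0 / (omega**2 + omega_q**2)) / (beta * mass))
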