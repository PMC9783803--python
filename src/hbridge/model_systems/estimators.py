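"""Primitive and centroid-virial energy estimators for PIMD runs.

Both estimators have the same expectation — the thermodynamic energy of
the P-bead ring polymer — but very different variances; agreement within
error bars is the standard internal consistency check for path-integral
sampling.  Standard errors come from block averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import DataError
from ..trajectory_io import BeadTrajectory
from ..units import HBAR_MECH, KB_MECH, KCAL_PER_MOL_TO_MECH
from .engines import extract_bridge_coords
from .potentials import ModelPotential, evaluate_potential

__all__ = ["EnergyEstimate", "energy_estimators", "block_standard_error"]


@dataclass(frozen=True)
class EnergyEstimate:
    """Energy estimate (kcal/mol) with a block-averaged standard error."""

    value: float
    stderr: float
    estimator: str


def block_standard_error(series: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from ``n_blocks`` contiguous blocks."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if n_blocks < 2 or n < n_blocks:
        return float("nan")
    usable = n - n % n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def energy_estimators(
    btraj: BeadTrajectory,
    model: ModelPotential,
    temperature: float,
    n_blocks: int = 10,
) -> dict[str, EnergyEstimate]:
    """Primitive and centroid-virial total-energy estimators (kcal/mol).

    The primitive estimator is  d·P/(2β) − Σ_k mP/(2β²ħ²)|x_k − x_{k+1}|²
    + (1/P)Σ_k V(x_k); the centroid-virial estimator replaces the
    spring-heavy kinetic part with  d/(2β) + (1/2P)Σ_k (x_k − x_c)·∇V(x_k).
    """
    P = btraj.P
    n_frames = btraj.n_frames
    if n_frames < 1:
        raise DataError("empty production segment")
    if n_frames < n_blocks:
        warnings.warn(
            f"only {n_frames} frames for {n_blocks} blocks; "
            "standard errors unreliable", stacklevel=2)
    ndof = model.n_dof
    m_dof = model.dof_masses
    beta = 1.0 / (KB_MECH * temperature)

    # beads: (n_frames, P, ndof)
    beads = np.stack(
        [extract_bridge_coords(rep, model) for rep in btraj.replicas], axis=1)
    energies, forces = evaluate_potential(model, beads)  # kcal/mol units
    grad = -forces * KCAL_PER_MOL_TO_MECH  # mech units
    v_mean = energies.mean(axis=1)  # per-frame mean bead potential, kcal/mol

    kT_kcal = 1.0 / (beta * KCAL_PER_MOL_TO_MECH)
    if P > 1:
        diff = beads - np.roll(beads, -1, axis=1)
        spring_coeff = m_dof * P / (2.0 * beta**2 * HBAR_MECH**2)  # mech
        spring = np.einsum("npd,d->n", diff**2, spring_coeff) \
            / KCAL_PER_MOL_TO_MECH
    else:
        spring = np.zeros(n_frames)
    prim = ndof * P * kT_kcal / 2.0 - spring + v_mean

    x_c = beads.mean(axis=1, keepdims=True)
    virial_term = np.einsum("npd,npd->n", beads - x_c, grad) / (2.0 * P) \
        / KCAL_PER_MOL_TO_MECH
    vir = ndof * kT_kcal / 2.0 + virial_term + v_mean

    return {
        "primitive": EnergyEstimate(
            float(prim.mean()), block_standard_error(prim, n_blocks),
            "primitive"),
        "centroid_virial": EnergyEstimate(
            float(vir.mean()), block_standard_error(vir, n_blocks),
            "centroid_virial"),
    }
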