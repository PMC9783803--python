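"""Analytic hydrogen-bridge potentials.

Three model surfaces stand in for the ab initio potential felt by a
bridging proton in a D-H...A motif:

``harmonic``
    V(x) = 1/2 k x², a free (non-bonded) X-H stretch reference.
``double_well``
    V(x) = V0 ((x/a0)² - 1)², a symmetric proton-transfer profile with
    minima at x = ±a0 and barrier V0 at the bridge midpoint x = 0.
``coupled_bridge``
    The double well with its half-separation and barrier modulated
    linearly by the donor-acceptor distance R, plus a harmonic restraint
    on R:  a(R) = a0 + c_a (R - R0), V0(R) = V0 + c_V (R - R0),
    V(x, R) = V0(R) ((x/a(R))² - 1)² + 1/2 k_R (R - R0)².
    Shorter bridges thus have closer wells and a lower transfer barrier,
    the geometric coupling that drives proton transfer in strong
    hydrogen bonds.

Energies are kcal/mol, lengths Å, masses amu.  Forces are exact analytic
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError

__all__ = ["ModelPotential", "evaluate_potential"]

_KINDS = ("harmonic", "double_well", "coupled_bridge")


@dataclass(frozen=True)
class ModelPotential:
    """Parameters of one analytic bridge potential.

    Defaults put the classical transfer barrier at the ~3 kcal/mol scale
    typical of moderately strong O-H...O bridges, with wells 0.7 Å apart
    inside a 2.6 Å bridge.
    """

    kind: str = "double_well"
    mass_H: float = 1.008       # amu; 2.014 for deuterium
    mass_heavy: float = 15.999  # amu, donor/acceptor atoms
    k_harm: float = 987.0       # kcal/mol/Å² (≈3400 cm⁻¹ X-H stretch for H)
    V0: float = 3.1             # kcal/mol barrier at R = R0
    a0: float = 0.35            # Å half well separation
    R0: float = 2.6             # Å equilibrium donor-acceptor distance
    k_R: float = 100.0          # kcal/mol/Å² D...A restraint
    c_a: float = 0.25           # dimensionless, da/dR
    c_V: float = 8.0            # kcal/mol/Å, dV0/dR

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown potential kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.V0 < 0:
            raise ConfigurationError("V0 must be >= 0")
        if self.a0 <= 0:
            raise ConfigurationError("a0 must be > 0")
        if self.R0 <= 2 * self.a0:
            raise ConfigurationError("R0 must exceed 2*a0 (wells inside bridge)")
        if self.mass_H <= 0 or self.mass_heavy <= 0:
            raise ConfigurationError("masses must be positive")

    @property
    def n_dof(self) -> int:
        """Dynamical coordinates: (x,) or (x, R)."""
        return 2 if self.kind == "coupled_bridge" else 1

    @property
    def dof_masses(self) -> np.ndarray:
        """Masses (amu) per coordinate; R carries the heavy-pair reduced mass."""
        if self.kind == "coupled_bridge":
            return np.array([self.mass_H, self.mass_heavy / 2.0])
        return np.array([self.mass_H])

    def minimum(self) -> np.ndarray:
        """One potential minimum (the +x well for the double wells)."""
        if self.kind == "harmonic":
            return np.zeros(1)
        if self.kind == "double_well":
            return np.array([self.a0])
        return np.array([self.a0, self.R0])

    def energy_forces(self, coords: np.ndarray):
        return evaluate_potential(self, coords)


def evaluate_potential(model: ModelPotential, coords) -> tuple:
    """Energy (kcal/mol) and forces for bridge coordinates.

    ``coords`` has shape ``(..., n_dof)`` (a bare length-``n_dof`` vector is
    accepted); energy comes back with shape ``(...)`` and forces with the
    input shape.  Forces are the exact analytic negative gradients.
    """
    coords = np.asarray(coords, dtype=float)
    squeeze = coords.ndim == 1
    c = np.atleast_2d(coords)
    if c.shape[-1] != model.n_dof:
        raise ConfigurationError(
            f"{model.kind} expects {model.n_dof} coordinate(s), got {c.shape[-1]}"
        )
    x = c[..., 0]
    if model.kind == "harmonic":
        energy = 0.5 * model.k_harm * x**2
        forces = (-model.k_harm * x)[..., None]
    elif model.kind == "double_well":
        u = (x / model.a0) ** 2 - 1.0
        energy = model.V0 * u**2
        forces = (-model.V0 * 2.0 * u * 2.0 * x / model.a0**2)[..., None]
    else:  # coupled_bridge
        R = c[..., 1]
        dR = R - model.R0
        a = model.a0 + model.c_a * dR
        if np.any(a <= 0):
            raise ConfigurationError(
                "coupled_bridge: a(R) <= 0 outside the model's domain"
            )
        v0 = model.V0 + model.c_V * dR
        u = (x / a) ** 2 - 1.0
        energy = v0 * u**2 + 0.5 * model.k_R * dR**2
        dv_dx = v0 * 2.0 * u * 2.0 * x / a**2
        dv_dR = (
            model.c_V * u**2
            + v0 * 2.0 * u * (-2.0 * x**2 / a**3) * model.c_a
            + model.k_R * dR
        )
        forces = np.stack([-dv_dx, -dv_dR], axis=-1)
    if squeeze:
        return float(energy[0]), forces[0]
    return energy, forces
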