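"""Classical MD and staging path-integral MD on the analytic bridges.

Both engines propagate the reduced bridge coordinates (the proton
displacement x and, for the coupled bridge, the donor-acceptor distance R)
with velocity-Verlet, optionally coupled to Nosé-Hoover chains.  The PIMD
engine samples the discretized path distribution

    exp(-β Σ_k [ m P / (2 β² ħ²) (x_k - x_{k+1})² + V(x_k)/P ]),

using the staging transformation that diagonalizes the bead-spring term,
with a massive (per-staging-mode) Nosé-Hoover chain — the stiff bead
springs are non-ergodic without it.  P = 1 reduces exactly to classical
sampling.

Trajectories are emitted as three collinear atoms D(0,0,0)-H-A(R,0,0)
with the proton at x measured from the bridge midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, IntegrationFailureError
from ..trajectory_io import BeadTrajectory, Trajectory
from ..units import HBAR_MECH, KB_MECH, KCAL_PER_MOL_TO_MECH
from .potentials import ModelPotential, evaluate_potential

__all__ = [
    "SimulationSettings",
    "PathSettings",
    "simulate_md",
    "simulate_pimd",
    "staging_transform",
    "inverse_staging",
    "embed_bridge",
    "extract_bridge_coords",
]

_ENERGY_DIVERGENCE = 1.0e6  # kcal/mol


@dataclass(frozen=True)
class SimulationSettings:
    """Time-integration and thermostat settings (fs, K, steps)."""

    dt: float = 0.1
    n_steps: int = 10000
    n_equil: int = 0
    temperature: float = 297.0
    thermostat: str = "nose_hoover_chain"  # or "none"
    chain_length: int = 4
    thermostat_time: float = 20.0  # fs
    seed: int = 0
    sample_stride: int = 1  # store every k-th step

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.thermostat not in ("none", "nose_hoover_chain"):
            raise ConfigurationError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0 when thermostatted")
        if self.n_equil >= self.n_steps:
            raise ConfigurationError(
                "empty production segment: n_equil must be < n_steps"
            )
        if self.chain_length < 2:
            raise ConfigurationError("chain_length must be >= 2")
        if self.sample_stride < 1:
            raise ConfigurationError("sample_stride must be >= 1")


@dataclass(frozen=True)
class PathSettings:
    """Trotter discretization: P replicas, massive NHC on staging modes."""

    P: int = 8
    bead_thermostat: str = "massive_nhc"

    def __post_init__(self):
        if self.P < 1:
            raise ConfigurationError("P must be >= 1")

    def spring_frequency(self, temperature: float) -> float:
        """ω_P = √P/(βħ) in rad/fs."""
        beta = 1.0 / (KB_MECH * temperature)
        return math.sqrt(self.P) / (beta * HBAR_MECH)


# ---------------------------------------------------------------------------
# staging transformation
# ---------------------------------------------------------------------------

def staging_transform(beads: np.ndarray) -> np.ndarray:
    """Bead positions -> staging coordinates (first axis is the bead index).

    u_1 = x_1;  u_k = x_k - ((k-1) x_{k+1} + x_1)/k  for k = 2..P, with the
    cyclic convention x_{P+1} = x_1.
    """
    x = np.asarray(beads, dtype=float)
    if x.ndim == 0 or x.shape[0] < 1:
        raise ConfigurationError("need at least one bead")
    P = x.shape[0]
    u = np.empty_like(x)
    u[0] = x[0]
    for k in range(2, P + 1):
        nxt = x[k % P]  # x_{k+1}, cyclic
        u[k - 1] = x[k - 1] - ((k - 1) * nxt + x[0]) / k
    return u


def inverse_staging(staging: np.ndarray) -> np.ndarray:
    """Staging coordinates -> bead positions (exact inverse recursion)."""
    u = np.asarray(staging, dtype=float)
    if u.ndim == 0 or u.shape[0] < 1:
        raise ConfigurationError("need at least one staging mode")
    P = u.shape[0]
    x = np.empty_like(u)
    x[0] = u[0]
    # downward recursion: x_k = u_k + ((k-1)/k) x_{k+1} + x_1/k
    for k in range(P, 1, -1):
        nxt = x[k % P] if k < P else x[0]
        x[k - 1] = u[k - 1] + ((k - 1) * nxt + u[0]) / k
    return x


def _staging_matrix(P: int) -> np.ndarray:
    """Matrix A with beads = A @ staging (columns are inverse images)."""
    A = np.empty((P, P))
    eye = np.eye(P)
    for j in range(P):
        A[:, j] = inverse_staging(eye[:, j])
    return A


# ---------------------------------------------------------------------------
# Nosé-Hoover chains (massive: one chain per degree of freedom)
# ---------------------------------------------------------------------------

class _NHChains:
    """Per-DOF Nosé-Hoover chains, integrated with the standard
    Martyna-Tuckerman-Klein half-step update."""

    def __init__(self, n_dof: int, chain_length: int, kT: float,
                 tau: np.ndarray):
        self.M = chain_length
        self.kT = kT
        # Q_j = kT tau^2 per chain link; tau may differ per DOF
        self.Q = np.broadcast_to(
            (kT * np.asarray(tau, dtype=float) ** 2)[:, None],
            (n_dof, chain_length),
        ).copy()
        self.xi = np.zeros((n_dof, chain_length))
        self.vxi = np.zeros((n_dof, chain_length))

    def half_step(self, v: np.ndarray, masses: np.ndarray, dt: float) -> None:
        """Advance the chains by dt and rescale particle velocities in place."""
        M, kT, Q, vxi = self.M, self.kT, self.Q, self.vxi
        dt2, dt4, dt8 = dt, dt / 2.0, dt / 4.0
        ke2 = masses * v * v  # 2*KE per dof
        vxi[:, M - 1] += (Q[:, M - 2] * vxi[:, M - 2] ** 2 - kT) / Q[:, M - 1] * dt4
        for j in range(M - 2, -1, -1):
            ef = np.exp(-dt8 * vxi[:, j + 1])
            G = (ke2 - kT) / Q[:, 0] if j == 0 else \
                (Q[:, j - 1] * vxi[:, j - 1] ** 2 - kT) / Q[:, j]
            vxi[:, j] = (vxi[:, j] * ef + G * dt4) * ef
        scale = np.exp(-dt2 * vxi[:, 0])
        v *= scale
        ke2 *= scale**2
        self.xi += vxi * dt2
        for j in range(M - 1):
            ef = np.exp(-dt8 * vxi[:, j + 1])
            G = (ke2 - kT) / Q[:, 0] if j == 0 else \
                (Q[:, j - 1] * vxi[:, j - 1] ** 2 - kT) / Q[:, j]
            vxi[:, j] = (vxi[:, j] * ef + G * dt4) * ef
        vxi[:, M - 1] += (Q[:, M - 2] * vxi[:, M - 2] ** 2 - kT) / Q[:, M - 1] * dt4


# ---------------------------------------------------------------------------
# embedding reduced coordinates as 3-atom frames
# ---------------------------------------------------------------------------

def _bridge_labels(model: ModelPotential) -> list[str]:
    return ["O", "H", "O"]


def embed_bridge(model: ModelPotential, coords: np.ndarray,
                 vels: np.ndarray | None = None):
    """Map reduced coordinates to collinear D-H-A Cartesian frames.

    ``coords`` has shape (n_frames, n_dof).  The donor sits at the origin,
    the acceptor at (R, 0, 0) and the proton at (R/2 + x, 0, 0); for 1-DOF
    models R is frozen at R0.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    pos = np.zeros((n, 3, 3))
    x = coords[:, 0]
    R = coords[:, 1] if model.n_dof == 2 else np.full(n, model.R0)
    pos[:, 1, 0] = R / 2.0 + x
    pos[:, 2, 0] = R
    vel = None
    if vels is not None:
        vels = np.atleast_2d(np.asarray(vels, dtype=float))
        vel = np.zeros((n, 3, 3))
        vdot_R = vels[:, 1] if model.n_dof == 2 else 0.0
        vel[:, 1, 0] = vels[:, 0] + vdot_R / 2.0
        vel[:, 2, 0] = vdot_R
    return _bridge_labels(model), pos, vel


def extract_bridge_coords(traj: Trajectory, model: ModelPotential) -> np.ndarray:
    """Invert :func:`embed_bridge`: recover (x[, R]) from the 3-atom frames."""
    R = traj.positions[:, 2, 0] - traj.positions[:, 0, 0]
    x = traj.positions[:, 1, 0] - traj.positions[:, 0, 0] - R / 2.0
    if model.n_dof == 2:
        return np.stack([x, R], axis=1)
    return x[:, None]


# ---------------------------------------------------------------------------
# classical MD
# ---------------------------------------------------------------------------

def _run_verlet(model, settings, masses, q0, v0, force_fn, thermostat, kT,
                record_vel=True):
    """Shared velocity-Verlet loop; returns (coords, vels, energies) arrays
    of recorded production samples.  force_fn(q) -> (E_kcal, F_mech)."""
    dt = settings.dt
    inv_m = 1.0 / masses
    q = q0.copy()
    v = v0.copy()
    energy, force = force_fn(q)
    n_rec = (settings.n_steps - settings.n_equil + settings.sample_stride - 1) \
        // settings.sample_stride
    coords = np.empty((n_rec, *q.shape))
    vels = np.empty_like(coords) if record_vel else None
    energies = np.empty(n_rec)
    rec = 0
    half = 0.5 * dt
    for step in range(settings.n_steps):
        if thermostat is not None:
            thermostat.half_step(v, masses, half)
        v += force * inv_m * half
        q += v * dt
        energy, force = force_fn(q)
        v += force * inv_m * half
        if thermostat is not None:
            thermostat.half_step(v, masses, half)
        if abs(energy) > _ENERGY_DIVERGENCE or not np.isfinite(energy):
            raise IntegrationFailureError(step, float(energy))
        if step >= settings.n_equil and (step - settings.n_equil) \
                % settings.sample_stride == 0:
            coords[rec] = q
            if record_vel:
                vels[rec] = v
            energies[rec] = energy
            rec += 1
    return coords[:rec], (None if vels is None else vels[:rec]), energies[:rec]


def _run_verlet_scalar_1d(model, settings, mass, q0, v0, kT):
    """Specialized plain-float loop for the 1-DOF bridges.

    Same integrator and thermostat as the array path, written with scalar
    arithmetic: the per-step cost of small-array bookkeeping dominates for
    one degree of freedom, and the long Boltzmann-inversion runs need
    millions of steps.
    """
    import math as _m

    dt = settings.dt
    half = 0.5 * dt
    inv_m = 1.0 / mass
    kind = model.kind
    if kind == "harmonic":
        k_harm = model.k_harm * KCAL_PER_MOL_TO_MECH

        def force(x):
            return 0.5 * k_harm * x * x, -k_harm * x
    else:  # double_well
        v0_m = model.V0 * KCAL_PER_MOL_TO_MECH
        inv_a2 = 1.0 / (model.a0 * model.a0)

        def force(x):
            u = x * x * inv_a2 - 1.0
            return v0_m * u * u, -4.0 * v0_m * u * x * inv_a2

    use_nhc = settings.thermostat == "nose_hoover_chain"
    M = settings.chain_length
    kT_m = kT
    if use_nhc:
        Q = [kT_m * settings.thermostat_time**2] * M
        vxi = [0.0] * M
        d2, d4, d8 = half, half / 2.0, half / 4.0

    def nhc(v):
        ke2 = mass * v * v
        vxi[M - 1] += (Q[M - 2] * vxi[M - 2] ** 2 - kT_m) / Q[M - 1] * d4
        for j in range(M - 2, -1, -1):
            ef = _m.exp(-d8 * vxi[j + 1])
            G = (ke2 - kT_m) / Q[0] if j == 0 else \
                (Q[j - 1] * vxi[j - 1] ** 2 - kT_m) / Q[j]
            vxi[j] = (vxi[j] * ef + G * d4) * ef
        scale = _m.exp(-d2 * vxi[0])
        v *= scale
        ke2 *= scale * scale
        for j in range(M - 1):
            ef = _m.exp(-d8 * vxi[j + 1])
            G = (ke2 - kT_m) / Q[0] if j == 0 else \
                (Q[j - 1] * vxi[j - 1] ** 2 - kT_m) / Q[j]
            vxi[j] = (vxi[j] * ef + G * d4) * ef
        vxi[M - 1] += (Q[M - 2] * vxi[M - 2] ** 2 - kT_m) / Q[M - 1] * d4
        return v

    q = float(q0)
    v = float(v0)
    e, f = force(q)
    n_rec = (settings.n_steps - settings.n_equil + settings.sample_stride - 1) \
        // settings.sample_stride
    coords = np.empty((n_rec, 1))
    vels = np.empty((n_rec, 1))
    energies = np.empty(n_rec)
    rec = 0
    n_equil, stride = settings.n_equil, settings.sample_stride
    for step in range(settings.n_steps):
        if use_nhc:
            v = nhc(v)
        v += f * inv_m * half
        q += v * dt
        e, f = force(q)
        v += f * inv_m * half
        if use_nhc:
            v = nhc(v)
        e_kcal = e / KCAL_PER_MOL_TO_MECH
        if abs(e_kcal) > _ENERGY_DIVERGENCE or e_kcal != e_kcal:
            raise IntegrationFailureError(step, e_kcal)
        if step >= n_equil and (step - n_equil) % stride == 0:
            coords[rec, 0] = q
            vels[rec, 0] = v
            energies[rec] = e_kcal
            rec += 1
    return coords[:rec], vels[:rec], energies[:rec]


def _run_verlet_scalar_2d(model, settings, masses, q0, v0, kT):
    """Plain-float loop for the coupled bridge (x, R), mirroring the array
    path with per-DOF Nosé-Hoover chains."""
    import math as _m

    dt = settings.dt
    half = 0.5 * dt
    m_x, m_R = float(masses[0]), float(masses[1])
    a0, c_a, c_V, R0 = model.a0, model.c_a, model.c_V, model.R0
    V0_m = model.V0 * KCAL_PER_MOL_TO_MECH
    cV_m = model.c_V * KCAL_PER_MOL_TO_MECH
    kR_m = model.k_R * KCAL_PER_MOL_TO_MECH

    def force(x, R):
        dR = R - R0
        a = a0 + c_a * dR
        if a <= 0:
            raise ConfigurationError(
                "coupled_bridge: a(R) <= 0 outside the model's domain")
        v0r = V0_m + cV_m * dR
        u = (x / a) ** 2 - 1.0
        e = v0r * u * u + 0.5 * kR_m * dR * dR
        fx = -v0r * 4.0 * u * x / (a * a)
        fR = -(cV_m * u * u - v0r * 4.0 * u * x * x * c_a / (a**3)
               + kR_m * dR)
        return e, fx, fR

    use_nhc = settings.thermostat == "nose_hoover_chain"
    M = settings.chain_length
    d2, d4, d8 = half, half / 2.0, half / 4.0
    Q = kT * settings.thermostat_time**2
    chains = [[0.0] * M, [0.0] * M]

    def nhc(v, mass, vxi):
        ke2 = mass * v * v
        vxi[M - 1] += (Q * vxi[M - 2] ** 2 - kT) / Q * d4
        for j in range(M - 2, -1, -1):
            ef = _m.exp(-d8 * vxi[j + 1])
            G = (ke2 - kT) / Q if j == 0 else (Q * vxi[j - 1] ** 2 - kT) / Q
            vxi[j] = (vxi[j] * ef + G * d4) * ef
        scale = _m.exp(-d2 * vxi[0])
        v *= scale
        ke2 *= scale * scale
        for j in range(M - 1):
            ef = _m.exp(-d8 * vxi[j + 1])
            G = (ke2 - kT) / Q if j == 0 else (Q * vxi[j - 1] ** 2 - kT) / Q
            vxi[j] = (vxi[j] * ef + G * d4) * ef
        vxi[M - 1] += (Q * vxi[M - 2] ** 2 - kT) / Q * d4
        return v

    x, R = float(q0[0]), float(q0[1])
    vx, vR = float(v0[0]), float(v0[1])
    e, fx, fR = force(x, R)
    n_rec = (settings.n_steps - settings.n_equil + settings.sample_stride - 1) \
        // settings.sample_stride
    coords = np.empty((n_rec, 2))
    vels = np.empty((n_rec, 2))
    energies = np.empty(n_rec)
    rec = 0
    n_equil, stride = settings.n_equil, settings.sample_stride
    inv_mx, inv_mR = 1.0 / m_x, 1.0 / m_R
    for step in range(settings.n_steps):
        if use_nhc:
            vx = nhc(vx, m_x, chains[0])
            vR = nhc(vR, m_R, chains[1])
        vx += fx * inv_mx * half
        vR += fR * inv_mR * half
        x += vx * dt
        R += vR * dt
        e, fx, fR = force(x, R)
        vx += fx * inv_mx * half
        vR += fR * inv_mR * half
        if use_nhc:
            vx = nhc(vx, m_x, chains[0])
            vR = nhc(vR, m_R, chains[1])
        e_kcal = e / KCAL_PER_MOL_TO_MECH
        if abs(e_kcal) > _ENERGY_DIVERGENCE or e_kcal != e_kcal:
            raise IntegrationFailureError(step, e_kcal)
        if step >= n_equil and (step - n_equil) % stride == 0:
            coords[rec, 0] = x
            coords[rec, 1] = R
            vels[rec, 0] = vx
            vels[rec, 1] = vR
            energies[rec] = e_kcal
            rec += 1
    return coords[:rec], vels[:rec], energies[:rec]


def simulate_md(model: ModelPotential, settings: SimulationSettings) -> Trajectory:
    """Classical MD of the bridge; returns the production-segment trajectory.

    Initial velocities are Maxwell-Boltzmann at ``settings.temperature``
    drawn with ``settings.seed``; identical seed and settings give a
    bit-identical trajectory.
    """
    rng = np.random.default_rng(settings.seed)
    masses = model.dof_masses
    kT = KB_MECH * settings.temperature
    q0 = model.minimum()
    v0 = rng.normal(0.0, np.sqrt(kT / masses))

    if model.n_dof == 1:
        coords, vels, energies = _run_verlet_scalar_1d(
            model, settings, float(masses[0]), q0[0], v0[0], kT)
    elif model.kind == "coupled_bridge":
        coords, vels, energies = _run_verlet_scalar_2d(
            model, settings, masses, q0, v0, kT)
    else:
        def force_fn(q):
            e, f = evaluate_potential(model, q)
            return e, f * KCAL_PER_MOL_TO_MECH

        thermostat = None
        if settings.thermostat == "nose_hoover_chain":
            tau = np.full(masses.shape, settings.thermostat_time)
            thermostat = _NHChains(masses.size, settings.chain_length, kT, tau)

        coords, vels, energies = _run_verlet(
            model, settings, masses, q0, v0, force_fn, thermostat, kT)
    labels, pos, vel = embed_bridge(model, coords, vels)
    meta = {
        "seed": settings.seed,
        "model": model.kind,
        "temperature": settings.temperature,
        "n_equil_trimmed": settings.n_equil,
        "atom_masses": [model.mass_heavy, model.mass_H, model.mass_heavy],
        "potential_energy": energies,
    }
    return Trajectory(atom_labels=labels, positions=pos, velocities=vel,
                      dt=settings.dt * settings.sample_stride, metadata=meta)


# ---------------------------------------------------------------------------
# staging PIMD
# ---------------------------------------------------------------------------

def simulate_pimd(model: ModelPotential, settings: SimulationSettings,
                  path: PathSettings) -> BeadTrajectory:
    """Staging PIMD of the bridge; returns P replica trajectories.

    All staging modes carry massive Nosé-Hoover chains; non-centroid modes
    are thermostatted on the bead-spring timescale 1/ω_P, the centroid on
    ``settings.thermostat_time``.  With P = 1 the path collapses to a
    single classical bead.
    """
    if settings.thermostat == "none" and path.P > 1:
        raise ConfigurationError("PIMD sampling requires the thermostat")
    P = path.P
    rng = np.random.default_rng(settings.seed)
    ndof = model.n_dof
    m_dof = model.dof_masses
    kT = KB_MECH * settings.temperature
    beta = 1.0 / kT
    omega_P = path.spring_frequency(settings.temperature)

    # staging masses: m_1 = m, m_k = m k/(k-1); springs act on modes k >= 2
    fac = np.ones(P)
    if P > 1:
        ks = np.arange(2, P + 1)
        fac[1:] = ks / (ks - 1.0)
    m_stag = (fac[:, None] * m_dof[None, :]).reshape(-1)
    spring_k = m_stag * omega_P**2
    spring_k[:ndof] = 0.0  # centroid mode feels no spring
    A = _staging_matrix(P)

    def force_fn(u_flat):
        u = u_flat.reshape(P, ndof)
        x = A @ u
        e_beads, f_beads = evaluate_potential(model, x)
        f_u = (A.T @ f_beads) / P * KCAL_PER_MOL_TO_MECH
        f_u = f_u.reshape(-1) - spring_k * u_flat
        # report the mean bead potential (the quantity that can diverge)
        return float(np.mean(e_beads)), f_u

    q0 = np.tile(model.minimum(), (P, 1))
    u0 = staging_transform(q0).reshape(-1)
    v0 = rng.normal(0.0, np.sqrt(kT / m_stag))

    tau = np.empty(P * ndof)
    tau[:] = 1.0 / omega_P if P > 1 else settings.thermostat_time
    tau[:ndof] = settings.thermostat_time
    thermostat = None
    if settings.thermostat == "nose_hoover_chain":
        thermostat = _NHChains(P * ndof, settings.chain_length, kT, tau)

    coords_u, vels_u, _ = _run_verlet(
        model, settings, m_stag, u0, v0, force_fn, thermostat, kT)

    n_rec = coords_u.shape[0]
    beads = np.einsum("pq,nqd->npd", A, coords_u.reshape(n_rec, P, ndof))
    bead_v = np.einsum("pq,nqd->npd", A, vels_u.reshape(n_rec, P, ndof))

    replicas = []
    for k in range(P):
        labels, pos, vel = embed_bridge(model, beads[:, k], bead_v[:, k])
        meta = {
            "seed": settings.seed,
            "model": model.kind,
            "temperature": settings.temperature,
            "P": P,
            "replica": k + 1,
            "n_equil_trimmed": settings.n_equil,
            "atom_masses": [model.mass_heavy, model.mass_H, model.mass_heavy],
        }
        replicas.append(Trajectory(
            atom_labels=labels, positions=pos, velocities=vel,
            dt=settings.dt * settings.sample_stride, metadata=meta))
    return BeadTrajectory(replicas=replicas)
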