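"""Hydrogen-bridge geometry, proton distributions, PMFs and transfer events.

A bridge is the D-H...A triple (donor, shared proton, acceptor).  From a
trajectory this module extracts the per-frame distances r(D-H), r(H...A)
and r(D...A) (minimum-image when a cell is present), builds the 2D
(r_DH, r_HA) proton-position histogram, Boltzmann-inverts 1D marginals
into potentials of mean force A(ξ) = −k_B T ln p(ξ), and counts proton
transfer events on the asymmetry coordinate ξ = r_DH − r_HA with a
hysteresis band that suppresses thermal recrossing noise.

For path-integral trajectories the position statistics may be pooled over
all beads (the quantum position estimator) or taken from the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, RangeError, SelectionError
from .trajectory_io import (
    BeadTrajectory,
    CellParameters,
    Trajectory,
    minimum_image_distance,
)
from .units import KB_KCAL

__all__ = [
    "BridgeDefinition",
    "HBGeometrySeries",
    "Histogram2D",
    "PMFProfile",
    "TransferEvents",
    "distance_series",
    "pooled_bead_series",
    "proton_histogram2d",
    "pmf_from_series",
    "pmf_from_samples",
    "locate_minima_barrier",
    "detect_transfers",
]


@dataclass(frozen=True)
class BridgeDefinition:
    """Atom indices of one D-H...A bridge plus a display label."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    label: str = "bridge"

    def __post_init__(self):
        idx = (self.donor_index, self.hydrogen_index, self.acceptor_index)
        if len(set(idx)) != 3:
            raise SelectionError(f"bridge {self.label!r}: indices must be distinct")
        if min(idx) < 0:
            raise SelectionError(f"bridge {self.label!r}: negative atom index")


@dataclass
class HBGeometrySeries:
    """Per-frame bridge distances in Å (times in fs)."""

    times: np.ndarray
    r_DH: np.ndarray
    r_HA: np.ndarray
    r_DA: np.ndarray
    label: str = "bridge"

    @property
    def delta(self) -> np.ndarray:
        """Proton-transfer asymmetry coordinate ξ = r_DH − r_HA (Å)."""
        return self.r_DH - self.r_HA

    def coordinate(self, name: str) -> np.ndarray:
        if name == "r_HA":
            return self.r_HA
        if name == "r_DH":
            return self.r_DH
        if name == "r_DA":
            return self.r_DA
        if name == "delta":
            return self.delta
        raise SelectionError(f"unknown bridge coordinate {name!r}")


@dataclass
class Histogram2D:
    """Normalized (unit-integral) density over (r_DH, r_HA), Å⁻²."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (nx, ny)


@dataclass
class PMFProfile:
    """Potential of mean force along one bridge coordinate (kcal/mol)."""

    coordinate_name: str
    bin_centers: np.ndarray
    free_energy: np.ndarray      # NaN where masked
    temperature: float
    mask: np.ndarray             # True where counts > 0
    counts: np.ndarray | None = None


@dataclass
class TransferEvents:
    """Confirmed donor<->acceptor proton transfers and residence fractions."""

    event_times: np.ndarray
    n_events: int
    residence_donor: float
    residence_acceptor: float
    hysteresis: float


def distance_series(traj: Trajectory, bridge: BridgeDefinition,
                    cell: Optional[CellParameters] = None) -> HBGeometrySeries:
    """Minimum-image r(D-H), r(H...A), r(D...A) per frame."""
    for idx in (bridge.donor_index, bridge.hydrogen_index, bridge.acceptor_index):
        if idx >= traj.n_atoms:
            raise SelectionError(
                f"bridge {bridge.label!r}: atom index {idx} out of range "
                f"(trajectory has {traj.n_atoms} atoms)")
    cell = cell if cell is not None else traj.cell
    pos = traj.positions
    d = pos[:, bridge.donor_index]
    h = pos[:, bridge.hydrogen_index]
    a = pos[:, bridge.acceptor_index]
    if cell is None:
        r_dh = np.linalg.norm(h - d, axis=1)
        r_ha = np.linalg.norm(a - h, axis=1)
        r_da = np.linalg.norm(a - d, axis=1)
    else:
        n = traj.n_frames
        r_dh = np.array([minimum_image_distance(d[i], h[i], cell) for i in range(n)])
        r_ha = np.array([minimum_image_distance(h[i], a[i], cell) for i in range(n)])
        r_da = np.array([minimum_image_distance(d[i], a[i], cell) for i in range(n)])
    return HBGeometrySeries(times=traj.times, r_DH=r_dh, r_HA=r_ha, r_DA=r_da,
                            label=bridge.label)


def pooled_bead_series(btraj: BeadTrajectory, bridge: BridgeDefinition,
                       cell: Optional[CellParameters] = None) -> HBGeometrySeries:
    """Concatenate the distance series of all beads (quantum statistics)."""
    parts = [distance_series(rep, bridge, cell) for rep in btraj.replicas]
    return HBGeometrySeries(
        times=np.concatenate([p.times for p in parts]),
        r_DH=np.concatenate([p.r_DH for p in parts]),
        r_HA=np.concatenate([p.r_HA for p in parts]),
        r_DA=np.concatenate([p.r_DA for p in parts]),
        label=bridge.label,
    )


def proton_histogram2d(series: HBGeometrySeries, bin_width: float = 0.02,
                       x_range=None, y_range=None) -> Histogram2D:
    """2D proton-position density over (r_DH, r_HA), unit integral (Å⁻²)."""
    if bin_width <= 0:
        raise RangeError("bin_width must be positive")
    x, y = series.r_DH, series.r_HA
    if x.size == 0:
        raise DataError("empty geometry series")

    def edges(vals, rng):
        lo, hi = (vals.min(), vals.max()) if rng is None else rng
        n = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
        return lo + np.arange(n + 1) * bin_width

    xe, ye = edges(x, x_range), edges(y, y_range)
    hist, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    density = hist / (hist.sum() * bin_width * bin_width)
    return Histogram2D(x_edges=xe, y_edges=ye, density=density)


def pmf_from_samples(samples: np.ndarray, coordinate_name: str, n_bins: int,
                     temperature: float, sample_range=None,
                     jacobian_r2: bool = False) -> PMFProfile:
    """Boltzmann-invert a 1D sample set: A(ξ) = −k_B T ln p(ξ), min = 0.

    ``jacobian_r2`` optionally divides the density by ξ² before inversion
    (radial volume correction); off by default — the bridge coordinate is
    treated as a 1D coordinate matching the distance axis convention.
    """
    if temperature <= 0:
        raise DataError("temperature must be positive")
    samples = np.asarray(samples, dtype=float)
    if np.ndim(n_bins) == 0:
        if n_bins < 2:
            raise RangeError("need at least 2 bins")
    else:
        n_bins = np.asarray(n_bins, dtype=float)  # explicit shared edges
    counts, edges = np.histogram(samples, bins=n_bins, range=sample_range)
    n_bins = counts.size
    if (counts > 0).sum() < 2:
        raise DataError("fewer than 2 occupied bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    if jacobian_r2:
        if np.any(centers <= 0):
            raise DataError("r² Jacobian requires positive coordinate values")
        density = density / centers**2
    mask = counts > 0
    free = np.full(n_bins, np.nan)
    free[mask] = -KB_KCAL * temperature * np.log(density[mask])
    free -= np.nanmin(free)
    return PMFProfile(coordinate_name=coordinate_name, bin_centers=centers,
                      free_energy=free, temperature=temperature, mask=mask,
                      counts=counts)


def pmf_from_series(series: HBGeometrySeries, coordinate: str = "r_HA",
                    n_bins: int = 60, temperature: float = 297.0,
                    sample_range=None, jacobian_r2: bool = False) -> PMFProfile:
    """PMF along a named bridge coordinate (``r_HA`` or ``delta`` ...)."""
    return pmf_from_samples(series.coordinate(coordinate), coordinate, n_bins,
                            temperature, sample_range, jacobian_r2)


def locate_minima_barrier(pmf: PMFProfile, smooth_window: int = 0):
    """Local minima positions (Å) and the transfer barrier (kcal/mol).

    Minima come from a discrete 3-point test (after an optional moving-
    average smoothing over ``smooth_window`` bins).  The barrier is the
    lowest ridge between the two deepest minima, measured from the global
    minimum; profiles with fewer than two minima return ``None``.
    """
    vals = pmf.free_energy[pmf.mask]
    pos = pmf.bin_centers[pmf.mask]
    if vals.size < 3:
        raise DataError("need at least 3 defined bins")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(vals, pad, mode="edge")
        vals = np.convolve(padded, kernel, mode="valid")[: pos.size]
    interior = (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:]) \
        & ((vals[1:-1] < vals[:-2]) | (vals[1:-1] < vals[2:]))
    idx = np.nonzero(interior)[0] + 1
    # endpoints count as minima when the profile rises away from them
    if vals.size >= 2 and vals[0] < vals[1]:
        idx = np.insert(idx, 0, 0)
    if vals.size >= 2 and vals[-1] < vals[-2]:
        idx = np.append(idx, vals.size - 1)
    minima_pos = pos[idx]
    if idx.size < 2:
        return minima_pos, None
    order = np.argsort(vals[idx])
    i, j = sorted((idx[order[0]], idx[order[1]]))
    saddle = float(np.max(vals[i:j + 1]))
    barrier = saddle - float(np.min(vals[idx]))
    return minima_pos, barrier


def detect_transfers(series: HBGeometrySeries | Sequence[float],
                     hysteresis: float = 0.1, dt: float | None = None
                     ) -> TransferEvents:
    """Count confirmed proton transfers on ξ = r_DH − r_HA.

    The proton is at the donor while ξ < −h and at the acceptor while
    ξ > +h; inside the band it keeps its last confirmed state, so an event
    is only counted when the far threshold is actually crossed.  Residence
    fractions are computed over the frames with an assigned state.
    """
    if hysteresis < 0:
        raise RangeError("hysteresis must be >= 0")
    if isinstance(series, HBGeometrySeries):
        xi = series.delta
        times = series.times
    else:
        xi = np.asarray(series, dtype=float)
        times = np.arange(xi.size) * (dt if dt else 1.0)
    state = 0  # 0 unassigned, -1 donor, +1 acceptor
    events = []
    n_donor = n_acceptor = 0
    for i, val in enumerate(xi):
        new = -1 if val < -hysteresis else (1 if val > hysteresis else 0)
        if new != 0:
            if state != 0 and new != state:
                events.append(times[i])
            state = new
        if state == -1:
            n_donor += 1
        elif state == 1:
            n_acceptor += 1
    assigned = n_donor + n_acceptor
    if assigned:
        res_d, res_a = n_donor / assigned, n_acceptor / assigned
    else:
        res_d = res_a = 0.0
    return TransferEvents(event_times=np.asarray(events), n_events=len(events),
                          residence_donor=res_d, residence_acceptor=res_a,
                          hysteresis=hysteresis)
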