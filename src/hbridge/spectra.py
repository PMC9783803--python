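"""Velocity autocorrelation functions and vibrational power spectra.

The vibrational density of states is estimated from atomic velocities as
a Welch-averaged periodogram of the mass-weighted velocity components
(Hann window, 50% overlap by default), summed over a selection of atoms.
Averaging periodograms rather than cosine-transforming the autocorrelation
makes the intensities nonnegative by construction.  Per-atom selections
decompose the spectrum additively, which is how individual X-H stretches
are attributed inside a crowded band.

Wavenumber axes are cm⁻¹: ν̃_k = k / (c · N_seg · dt) with c the speed of
light and N_seg the segment length in frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, RangeError, SelectionError
from .trajectory_io import Trajectory
from .units import C_CM_PER_FS, atomic_mass

__all__ = [
    "VACFSeries",
    "PowerSpectrum",
    "compute_vacf",
    "power_spectrum",
    "band_maximum",
    "spectral_shift",
    "parse_selection",
]


@dataclass
class VACFSeries:
    """Normalized (mass-weighted) velocity autocorrelation: C(0) = 1."""

    lags: np.ndarray          # fs
    values: np.ndarray        # dimensionless
    selection: list[int]
    mass_weighted: bool = True


@dataclass
class PowerSpectrum:
    """One-sided velocity power spectrum on a cm⁻¹ axis."""

    wavenumbers: np.ndarray   # cm⁻¹, strictly increasing
    intensity: np.ndarray     # arbitrary units, >= 0
    resolution: float         # cm⁻¹, 1/(c * segment duration)
    selection: list[int] = field(default_factory=list)
    window: str = "hann"


def parse_selection(traj: Trajectory, selection) -> list[int]:
    """Resolve a selection to atom indices.

    Accepts a sequence of integer indices, an element symbol (``"H"``,
    all matching atoms), or a label with index (``"H1"``, the atom of that
    element with the given 0-based position among same-element atoms).
    """
    if selection is None:
        return list(range(traj.n_atoms))
    if isinstance(selection, str):
        sym = selection.rstrip("0123456789")
        idx_part = selection[len(sym):]
        matches = [i for i, lab in enumerate(traj.atom_labels) if lab == sym]
        if not matches:
            raise SelectionError(f"no atoms with label {sym!r}")
        if idx_part:
            k = int(idx_part)
            if k >= len(matches):
                raise SelectionError(
                    f"selection {selection!r}: only {len(matches)} "
                    f"{sym} atoms present")
            return [matches[k]]
        return matches
    indices = [int(i) for i in selection]
    if not indices:
        raise SelectionError("empty selection")
    for i in indices:
        if not 0 <= i < traj.n_atoms:
            raise SelectionError(f"atom index {i} out of range")
    if len(set(indices)) != len(indices):
        raise SelectionError("duplicate atom indices in selection")
    return indices


def _masses(traj: Trajectory, indices: Sequence[int]) -> np.ndarray:
    stored = traj.metadata.get("atom_masses")
    if stored is not None:
        return np.asarray([stored[i] for i in indices], dtype=float)
    return np.asarray([atomic_mass(traj.atom_labels[i]) for i in indices])


def compute_vacf(traj: Trajectory, selection=None, max_lag: float | None = None,
                 mass_weighted: bool = True) -> VACFSeries:
    """Mass-weighted velocity autocorrelation averaged over all time origins.

    C(τ) = Σ_{i∈sel} m_i ⟨v_i(t)·v_i(t+τ)⟩_t, normalized so C(0) = 1.
    ``max_lag`` (fs) must not exceed half the production length so every
    lag keeps at least half the origins.
    """
    if traj.velocities is None:
        raise DataError("trajectory has no velocities")
    indices = parse_selection(traj, selection)
    n = traj.n_frames
    half_span = (n - 1) * traj.dt / 2.0
    if max_lag is None:
        max_lag = half_span
    if max_lag > half_span + 1e-9:
        raise RangeError(
            f"max_lag {max_lag:g} fs exceeds half the production span "
            f"({half_span:g} fs)")
    n_lags = int(round(max_lag / traj.dt)) + 1

    v = traj.velocities[:, indices, :]  # (n, sel, 3)
    w = _masses(traj, indices) if mass_weighted else np.ones(len(indices))
    # FFT-based autocorrelation per atom/component, summed with mass weights
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fv = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft(np.abs(fv) ** 2, n=nfft, axis=0)[:n_lags]
    counts = (n - np.arange(n_lags))[:, None, None]
    acf = acf / counts
    series = np.einsum("lac,a->l", acf, w)
    if series[0] <= 0:
        raise DataError("zero-velocity trajectory: VACF undefined")
    series = series / series[0]
    lags = np.arange(n_lags) * traj.dt
    return VACFSeries(lags=lags, values=series, selection=indices,
                      mass_weighted=mass_weighted)


def power_spectrum(traj: Trajectory, selection=None, window: str = "hann",
                   n_segments: int = 1, mass_weighted: bool = True,
                   overlap: float = 0.5) -> PowerSpectrum:
    """Welch-averaged one-sided power spectrum of the selected velocities.

    With a rectangular window and one segment the spectrum integrates
    (over the cm⁻¹ axis) to the mean squared mass-weighted velocity of the
    selection — the Parseval normalization that makes per-atom spectra
    additive over disjoint selections.
    """
    if traj.velocities is None:
        raise DataError("trajectory has no velocities")
    if n_segments < 1:
        raise RangeError("n_segments must be >= 1")
    indices = parse_selection(traj, selection)
    n = traj.n_frames
    # segment length with 50% overlap: n = L + (n_segments-1)*L*(1-overlap)
    denom = 1.0 + (n_segments - 1) * (1.0 - overlap)
    seg_len = int(n / denom)
    if seg_len < 2:
        raise RangeError("segments longer than the production run")
    step = max(1, int(seg_len * (1.0 - overlap))) if n_segments > 1 else seg_len

    if window == "hann":
        win = np.hanning(seg_len)
    elif window in ("rect", "rectangular", "boxcar"):
        win = np.ones(seg_len)
    else:
        raise RangeError(f"unknown window {window!r}")
    win_power = np.mean(win**2)

    w = _masses(traj, indices) if mass_weighted else np.ones(len(indices))
    v = traj.velocities[:, indices, :]
    dt = traj.dt
    d_nu = 1.0 / (C_CM_PER_FS * seg_len * dt)  # cm⁻¹ per bin

    n_freq = seg_len // 2 + 1
    acc = np.zeros(n_freq)
    count = 0
    start = 0
    while count < n_segments and start + seg_len <= n:
        seg = v[start:start + seg_len] * win[:, None, None]
        fseg = np.fft.rfft(seg, axis=0)
        p = np.einsum("kac,a->k", np.abs(fseg) ** 2, w)
        acc += p
        count += 1
        start += step
    if count == 0:
        raise RangeError("segments longer than the production run")
    # one-sided: double the interior bins; normalize so Σ I Δν̃ = m⟨v²⟩
    acc /= count * win_power
    scale = np.full(n_freq, 2.0)
    scale[0] = 1.0
    if seg_len % 2 == 0:
        scale[-1] = 1.0
    intensity = acc * scale / (seg_len**2 * d_nu)
    wavenumbers = np.arange(n_freq) * d_nu
    return PowerSpectrum(wavenumbers=wavenumbers, intensity=intensity,
                         resolution=d_nu, selection=indices, window=window)


def band_maximum(spec: PowerSpectrum, lo: float, hi: float) -> tuple[float, float]:
    """Peak position (cm⁻¹) and height on [lo, hi]; ties break low."""
    if lo > hi:
        raise RangeError("lo must not exceed hi")
    if lo < spec.wavenumbers[0] - 1e-9 or hi > spec.wavenumbers[-1] + 1e-9:
        raise RangeError(
            f"window [{lo:g}, {hi:g}] cm⁻¹ outside the spectral axis "
            f"[{spec.wavenumbers[0]:g}, {spec.wavenumbers[-1]:g}]")
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if not np.any(mask):
        raise RangeError("no spectral bins inside the window")
    sub_w = spec.wavenumbers[mask]
    sub_i = spec.intensity[mask]
    k = int(np.argmax(sub_i))  # argmax returns the first (lowest-ν̃) maximum
    return float(sub_w[k]), float(sub_i[k])


def spectral_shift(spec_a: PowerSpectrum, spec_b: PowerSpectrum,
                   lo: float, hi: float) -> float:
    """Band-maximum shift b − a in cm⁻¹ (positive: blueshift)."""
    pos_a, _ = band_maximum(spec_a, lo, hi)
    pos_b, _ = band_maximum(spec_b, lo, hi)
    return pos_b - pos_a
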