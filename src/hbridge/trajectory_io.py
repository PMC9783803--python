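"""Trajectory containers, file formats and periodic geometry.

Two text formats are supported: multi-frame XYZ (Å) and the CPMD-style
TRAJECTORY dialect (step index, positions in bohr, velocities in atomic
units, atom order repeating within each step block).  All in-memory
coordinates are Å and fs; unit conversions happen only here, at the file
boundary, with the fixed constants from :mod:`hbridge.units`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, GeometryError, RangeError
from .units import AU_TIME_TO_FS, AU_VELOCITY_TO_ANGSTROM_FS, BOHR_TO_ANGSTROM

logger = logging.getLogger(__name__)

__all__ = [
    "CellParameters",
    "Trajectory",
    "BeadTrajectory",
    "read_cpmd_trajectory",
    "write_cpmd_trajectory",
    "read_xyz",
    "write_xyz",
    "trim_equilibration",
    "minimum_image_distance",
    "centroid",
    "read_bead_trajectory",
    "write_bead_trajectory",
]


@dataclass(frozen=True)
class CellParameters:
    """Triclinic cell: lengths in Å, angles in degrees.

    The lattice matrix follows the crystallographic convention with **a**
    along x and **b** in the xy-plane (row vectors).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError("cell angles must lie in (0°, 180°)")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise GeometryError("cell volume must be positive")

    @property
    def lattice_matrix(self) -> np.ndarray:
        """3×3 row-vector lattice matrix in Å."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ax = self.a
        bx, by = self.b * math.cos(ga), self.b * math.sin(ga)
        cx = self.c * math.cos(be)
        cy = self.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = self.c**2 - cx**2 - cy**2
        if cz_sq <= 0:
            raise GeometryError("cell angles do not define a real cell")
        return np.array([[ax, 0.0, 0.0], [bx, by, 0.0], [cx, cy, math.sqrt(cz_sq)]])

    @property
    def volume(self) -> float:
        try:
            return float(abs(np.linalg.det(self.lattice_matrix)))
        except GeometryError:
            return -1.0


@dataclass
class Trajectory:
    """Frames of labelled positions (Å) and optional velocities (Å/fs)."""

    atom_labels: list[str]
    positions: np.ndarray  # (n_frames, n_atoms, 3), Å
    velocities: Optional[np.ndarray] = None  # same shape, Å/fs
    dt: float = 1.0  # fs between stored frames
    cell: Optional[CellParameters] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError("positions must have shape (frames, atoms, 3)")
        if self.positions.shape[0] < 1:
            raise FormatError("trajectory needs at least one frame")
        if self.positions.shape[1] != len(self.atom_labels):
            raise FormatError("atom_labels length does not match positions")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise FormatError("velocities shape differs from positions")
        if not self.dt > 0:
            raise FormatError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs, starting at 0."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class BeadTrajectory:
    """P replica trajectories sharing one topology (Trotter beads)."""

    replicas: list[Trajectory]

    def __post_init__(self):
        if len(self.replicas) < 1:
            raise FormatError("need at least one replica (P >= 1)")
        ref = self.replicas[0]
        for k, rep in enumerate(self.replicas[1:], start=2):
            if rep.positions.shape != ref.positions.shape:
                raise FormatError(f"replica {k} shape differs from replica 1")
            if rep.atom_labels != ref.atom_labels:
                raise FormatError(f"replica {k} labels differ from replica 1")

    @property
    def P(self) -> int:
        return len(self.replicas)

    @property
    def n_frames(self) -> int:
        return self.replicas[0].n_frames


# ---------------------------------------------------------------------------
# CPMD-style TRAJECTORY dialect
# ---------------------------------------------------------------------------

def read_cpmd_trajectory(
    path,
    dt_au: float = 3.0,
    stride: int = 1,
    atom_labels: Optional[Sequence[str]] = None,
) -> Trajectory:
    """Read a CPMD-style TRAJECTORY file.

    Each line is ``step  x y z  vx vy vz`` in atomic units (bohr, bohr per
    a.u. time); atoms repeat within one step block and the atom count is
    inferred from the repeating step index.  ``dt_au`` is the integration
    step in a.u. of time, ``stride`` the file-write interval, so the stored
    frame spacing is ``dt_au * 0.02418884 fs * stride``.  A trailing partial
    frame is dropped with a warning.
    """
    path = Path(path)
    rows: list[tuple[int, list[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 7 columns "
                    f"(step x y z vx vy vz), got {len(parts)}"
                )
            try:
                step = int(float(parts[0]))
                vals = [float(p) for p in parts[1:]]
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric field in {line!r}"
                ) from None
            rows.append((step, vals))
    if not rows:
        raise FormatError(f"{path.name}: empty trajectory file")

    steps = np.array([r[0] for r in rows])
    # atoms per frame = run length of the first step index
    first = steps[0]
    n_atoms = int(np.argmax(steps != first)) if np.any(steps != first) else len(steps)
    n_full, rem = divmod(len(rows), n_atoms)
    if rem:
        logger.warning(
            "%s: dropping trailing partial frame (%d of %d atoms)",
            path.name, rem, n_atoms,
        )
        rows = rows[: n_full * n_atoms]
        steps = steps[: n_full * n_atoms]
    blocks = steps.reshape(n_full, n_atoms)
    bad = np.nonzero(blocks != blocks[:, :1])[0]
    if bad.size:
        line_no = int(bad[0]) * n_atoms + int(np.nonzero(
            blocks[bad[0]] != blocks[bad[0], 0])[0][0]) + 1
        raise FormatError(
            f"{path.name}: inconsistent atoms per frame near data line {line_no}"
        )

    data = np.array([r[1] for r in rows]).reshape(n_full, n_atoms, 6)
    positions = data[:, :, :3] * BOHR_TO_ANGSTROM
    velocities = data[:, :, 3:] * AU_VELOCITY_TO_ANGSTROM_FS
    labels = list(atom_labels) if atom_labels else ["X"] * n_atoms
    if len(labels) != n_atoms:
        raise FormatError(
            f"{path.name}: {len(labels)} labels given for {n_atoms} atoms"
        )
    dt = dt_au * AU_TIME_TO_FS * stride
    return Trajectory(
        atom_labels=labels,
        positions=positions,
        velocities=velocities,
        dt=dt,
        metadata={"source": str(path), "dt_au": dt_au, "stride": stride},
    )


def write_cpmd_trajectory(traj: Trajectory, path) -> None:
    """Write the CPMD-style dialect (a.u.); velocities default to zero."""
    vel = traj.velocities
    if vel is None:
        vel = np.zeros_like(traj.positions)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            for a in range(traj.n_atoms):
                p = traj.positions[f, a] / BOHR_TO_ANGSTROM
                v = vel[f, a] / AU_VELOCITY_TO_ANGSTROM_FS
                fh.write(
                    f"{f + 1:8d} "
                    + " ".join(f"{x: .12e}" for x in (*p, *v))
                    + "\n"
                )


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------

def _parse_comment_metadata(comment: str) -> dict:
    """Pull ``key=value`` tokens (e.g. ``dt=0.1``) out of an XYZ comment."""
    meta: dict = {}
    for token in comment.split():
        if "=" in token:
            key, _, val = token.partition("=")
            try:
                meta[key] = float(val)
            except ValueError:
                meta[key] = val
    return meta


def read_xyz(path) -> Trajectory:
    """Read a multi-frame XYZ file (Å); comment-line ``key=value`` tokens
    (notably ``dt=<fs>``) land in ``metadata`` and set the frame spacing."""
    path = Path(path)
    labels: list[str] = []
    frames: list[np.ndarray] = []
    meta: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path.name}:{i + 1}: expected atom count") from None
        if n <= 0:
            raise FormatError(f"{path.name}:{i + 1}: empty frame body")
        if i + 2 + n > len(lines):
            raise FormatError(
                f"{path.name}:{i + 1}: frame declares {n} atoms but file ends early"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if not frames:
            meta.update(_parse_comment_metadata(comment))
        frame_labels, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name}:{i + 3 + j}: expected 'element x y z'"
                )
            frame_labels.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{i + 3 + j}: non-numeric coordinate"
                ) from None
        if not labels:
            labels = frame_labels
        elif frame_labels != labels:
            raise FormatError(f"{path.name}: atom labels change between frames")
        frames.append(np.array(coords))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path.name}: no frames found")
    dt = float(meta.get("dt", 1.0))
    meta.setdefault("source", str(path))
    return Trajectory(atom_labels=labels, positions=np.stack(frames), dt=dt,
                      metadata=meta)


def write_xyz(traj: Trajectory, path) -> None:
    """Write multi-frame XYZ; the comment line carries ``dt=<fs>`` plus any
    scalar metadata (seed etc.) as ``key=value`` tokens."""
    tokens = [f"dt={traj.dt:g}"]
    for key, val in traj.metadata.items():
        if key == "dt" or not isinstance(val, (int, float, str)):
            continue
        if isinstance(val, str) and (" " in val or "=" in val):
            continue
        tokens.append(f"{key}={val}")
    comment = " ".join(tokens)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment}\n")
            for label, (x, y, z) in zip(traj.atom_labels, traj.positions[f]):
                fh.write(f"{label:<3s} {x: .8f} {y: .8f} {z: .8f}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def trim_equilibration(traj: Trajectory, n_frames: int) -> Trajectory:
    """Drop the first ``n_frames`` frames (equilibration segment)."""
    if n_frames < 0:
        raise RangeError("n_frames must be >= 0")
    if n_frames >= traj.n_frames:
        raise RangeError(
            f"cannot trim {n_frames} frames from a {traj.n_frames}-frame trajectory"
        )
    if n_frames == 0:
        return traj
    meta = dict(traj.metadata)
    meta["n_equil_trimmed"] = meta.get("n_equil_trimmed", 0) + n_frames
    return replace(
        traj,
        positions=traj.positions[n_frames:],
        velocities=None if traj.velocities is None else traj.velocities[n_frames:],
        metadata=meta,
    )


_IMAGE_SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def minimum_image_distance(p1, p2, cell: Optional[CellParameters] = None) -> float:
    """Shortest distance (Å) between two points under periodic boundaries.

    With no cell this is the plain Euclidean distance.  For a (possibly
    triclinic) cell the separation is wrapped into the central cell in
    fractional coordinates and then minimized over the 27 nearest images,
    which is exact for any cell whose Wigner-Seitz cell is covered by the
    first shell (all crystallographically reasonable cells).
    """
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    if cell is None:
        return float(np.linalg.norm(d))
    lattice = cell.lattice_matrix
    if abs(np.linalg.det(lattice)) <= 0:
        raise GeometryError("degenerate cell")
    frac = np.linalg.solve(lattice.T, d)
    frac -= np.round(frac)
    cands = (frac[None, :] + _IMAGE_SHIFTS) @ lattice
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", cands, cands))))


def centroid(btraj: BeadTrajectory) -> Trajectory:
    """Bead-averaged (centroid) trajectory; identity for P = 1."""
    if btraj.P == 1:
        return btraj.replicas[0]
    ref = btraj.replicas[0]
    mean_pos = np.mean([r.positions for r in btraj.replicas], axis=0)
    vels = None
    if all(r.velocities is not None for r in btraj.replicas):
        vels = np.mean([r.velocities for r in btraj.replicas], axis=0)
    meta = dict(ref.metadata)
    meta["centroid_of_P"] = btraj.P
    return Trajectory(
        atom_labels=list(ref.atom_labels),
        positions=mean_pos,
        velocities=vels,
        dt=ref.dt,
        cell=ref.cell,
        metadata=meta,
    )


def write_bead_trajectory(btraj: BeadTrajectory, base_path, fmt: str = "xyz") -> list[Path]:
    """Write replicas as ``<base>_k.<ext>`` for k = 1..P; returns the paths."""
    base = Path(base_path)
    ext = {"xyz": ".xyz", "cpmd": ".trj"}[fmt]
    paths = []
    for k, rep in enumerate(btraj.replicas, start=1):
        p = base.with_name(f"{base.name}_{k}{ext}")
        (write_xyz if fmt == "xyz" else write_cpmd_trajectory)(rep, p)
        paths.append(p)
    return paths


def read_bead_trajectory(base_path, P: int, fmt: str = "xyz", **kwargs) -> BeadTrajectory:
    """Read ``<base>_k.<ext>`` replica files written by ``write_bead_trajectory``."""
    base = Path(base_path)
    ext = {"xyz": ".xyz", "cpmd": ".trj"}[fmt]
    reader = read_xyz if fmt == "xyz" else read_cpmd_trajectory
    reps = [reader(base.with_name(f"{base.name}_{k}{ext}"), **kwargs)
            for k in range(1, P + 1)]
    return BeadTrajectory(replicas=reps)
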