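import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbridge.errors import FormatError, GeometryError, RangeError
from hbridge.trajectory_io import (
    BeadTrajectory,
    CellParameters,
    Trajectory,
    centroid,
    minimum_image_distance,
    read_bead_trajectory,
    read_cpmd_trajectory,
    read_xyz,
    trim_equilibration,
    write_bead_trajectory,
    write_cpmd_trajectory,
    write_xyz,
)
from hbridge.units import AU_TIME_TO_FS, BOHR_TO_ANGSTROM

TRICLINIC_C = CellParameters(6.910, 12.289, 12.647, 112.713, 93.424, 103.103)


def _simple_traj(n_frames=3, dt=0.1, velocities=True, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(0, 1, (n_frames, 3, 3))
    vel = rng.normal(0, 0.01, (n_frames, 3, 3)) if velocities else None
    return Trajectory(["O", "H", "O"], pos, vel, dt=dt, metadata={"seed": seed})


class TestCPMDFormat:
    def test_unit_conversion_single_atom(self, tmp_path):
        path = tmp_path / "TRAJECTORY"
        path.write_text("1  1.0 0.0 0.0  0.0 0.0 0.0\n")
        traj = read_cpmd_trajectory(path, dt_au=3.0)
        assert traj.positions[0, 0, 0] == pytest.approx(0.52917721, abs=1e-12)

    def test_stored_dt_from_au_step(self, tmp_path):
        path = tmp_path / "TRAJECTORY"
        lines = []
        for step in (1, 2, 3):
            for _ in range(2):
                lines.append(f"{step} 0.1 0.2 0.3 0.0 0.0 0.0")
        path.write_text("\n".join(lines) + "\n")
        traj = read_cpmd_trajectory(path, dt_au=3.0)
        assert traj.n_frames == 3 and traj.n_atoms == 2
        assert traj.dt == pytest.approx(0.07256652, abs=1e-9)
        assert traj.dt == pytest.approx(3.0 * AU_TIME_TO_FS)

    def test_column_count_error_names_line(self, tmp_path):
        path = tmp_path / "TRAJECTORY"
        path.write_text(
            "1 0 0 0 0 0 0\n"
            "2 0 0 0 0 0\n")
        with pytest.raises(FormatError, match=":2"):
            read_cpmd_trajectory(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "TRAJECTORY"
        path.write_text("\n")
        with pytest.raises(FormatError, match="empty"):
            read_cpmd_trajectory(path)

    def test_trailing_partial_frame_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "TRAJECTORY"
        path.write_text(
            "1 0 0 0 0 0 0\n1 1 0 0 0 0 0\n"
            "2 0 0 0 0 0 0\n2 1 0 0 0 0 0\n"
            "3 0 0 0 0 0 0\n")
        with caplog.at_level("WARNING"):
            traj = read_cpmd_trajectory(path)
        assert traj.n_frames == 2
        assert any("partial frame" in rec.message for rec in caplog.records)

    def test_round_trip_positions_and_velocities(self, tmp_path):
        traj = _simple_traj(seed=3)
        path = tmp_path / "TRAJECTORY"
        write_cpmd_trajectory(traj, path)
        back = read_cpmd_trajectory(path, atom_labels=traj.atom_labels)
        assert np.allclose(back.positions, traj.positions, atol=1e-9)
        assert np.allclose(back.velocities, traj.velocities, atol=1e-9)
        # the dialect stores bohr: a 1-bohr coordinate reads as 0.52917721 Å
        assert BOHR_TO_ANGSTROM == 0.52917721


class TestXYZFormat:
    def test_round_trip(self, tmp_path):
        traj = _simple_traj(seed=4)
        path = tmp_path / "t.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert back.atom_labels == traj.atom_labels
        assert np.allclose(back.positions, traj.positions, atol=1e-6)
        assert back.dt == pytest.approx(traj.dt)

    def test_comment_metadata_parsed(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("1\ndt=0.5 seed=9\nH 0.0 0.0 0.0\n")
        traj = read_xyz(path)
        assert traj.dt == 0.5
        assert traj.metadata["seed"] == 9

    def test_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("3\ncomment\nH 0 0 0\nO 1 0 0\n")
        with pytest.raises(FormatError):
            read_xyz(path)

    def test_empty_frame_rejected(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("0\ncomment\n")
        with pytest.raises(FormatError, match="empty frame"):
            read_xyz(path)


class TestTrim:
    def test_slicing_contract(self):
        traj = _simple_traj(n_frames=100)
        out = trim_equilibration(traj, 10)
        assert out.n_frames == 90
        assert np.array_equal(out.positions[0], traj.positions[10])
        assert out.metadata["n_equil_trimmed"] == 10

    def test_zero_trim_is_identity(self):
        traj = _simple_traj()
        assert trim_equilibration(traj, 0) is traj

    def test_full_trim_rejected(self):
        traj = _simple_traj(n_frames=100)
        with pytest.raises(RangeError):
            trim_equilibration(traj, 100)


class TestMinimumImage:
    def test_cubic_wraparound(self):
        cell = CellParameters(10, 10, 10)
        d = minimum_image_distance([1, 0, 0], [9, 0, 0], cell)
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_identical_points(self):
        assert minimum_image_distance([1, 2, 3], [1, 2, 3], TRICLINIC_C) == 0.0

    def test_no_cell_is_euclidean(self):
        assert minimum_image_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)

    def test_triclinic_matches_exhaustive_search(self):
        """100 random pairs in the triclinic co-crystal cell agree with a
        brute-force search over the wrapped separation's 27 images."""
        lattice = TRICLINIC_C.lattice_matrix
        shifts = np.array([[i, j, k] for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)])
        rng = np.random.default_rng(99)
        for _ in range(100):
            p1 = rng.uniform(-25, 25, 3)
            p2 = rng.uniform(-25, 25, 3)
            diff = p2 - p1
            frac = np.linalg.solve(lattice.T, diff)
            frac -= np.round(frac)
            wrapped = frac @ lattice
            brute = min(np.linalg.norm(wrapped + s @ lattice) for s in shifts)
            assert minimum_image_distance(p1, p2, TRICLINIC_C) == \
                pytest.approx(brute, abs=1e-9)

    @given(st.lists(st.floats(-30, 30), min_size=6, max_size=6))
    def test_symmetric_and_bounded_by_euclidean(self, coords):
        p1, p2 = np.array(coords[:3]), np.array(coords[3:])
        d12 = minimum_image_distance(p1, p2, TRICLINIC_C)
        d21 = minimum_image_distance(p2, p1, TRICLINIC_C)
        assert d12 == pytest.approx(d21, abs=1e-9)
        assert d12 <= np.linalg.norm(p2 - p1) + 1e-9

    def test_degenerate_cell_rejected(self):
        with pytest.raises(GeometryError):
            CellParameters(0.0, 10, 10)
        with pytest.raises(GeometryError):
            CellParameters(10, 10, 10, alpha=180.0)


class TestCentroid:
    def test_single_replica_identity(self):
        traj = _simple_traj()
        assert centroid(BeadTrajectory([traj])) is traj

    def test_mirror_replicas_average_to_zero(self):
        traj = _simple_traj(velocities=False)
        mirrored = Trajectory(traj.atom_labels, -traj.positions, dt=traj.dt)
        mean = centroid(BeadTrajectory([traj, mirrored]))
        assert np.allclose(mean.positions, 0.0, atol=1e-15)

    def test_matches_direct_mean(self, rng):
        reps = [_simple_traj(seed=k) for k in range(8)]
        mean = centroid(BeadTrajectory(reps))
        direct = np.mean([r.positions for r in reps], axis=0)
        assert np.allclose(mean.positions, direct, atol=1e-12)

    def test_incongruent_replicas_rejected(self):
        with pytest.raises(FormatError):
            BeadTrajectory([_simple_traj(n_frames=3), _simple_traj(n_frames=4)])


def test_bead_trajectory_file_round_trip(tmp_path):
    reps = [_simple_traj(seed=k, velocities=False) for k in range(4)]
    btraj = BeadTrajectory(reps)
    paths = write_bead_trajectory(btraj, tmp_path / "beads", fmt="xyz")
    assert [p.name for p in paths] == [f"beads_{k}.xyz" for k in range(1, 5)]
    back = read_bead_trajectory(tmp_path / "beads", P=4)
    for orig, re_read in zip(btraj.replicas, back.replicas):
        assert np.allclose(orig.positions, re_read.positions, atol=1e-6)
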