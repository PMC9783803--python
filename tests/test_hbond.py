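import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbridge.errors import DataError, RangeError, SelectionError
from hbridge.hbond import (
    BridgeDefinition,
    HBGeometrySeries,
    PMFProfile,
    detect_transfers,
    distance_series,
    locate_minima_barrier,
    pmf_from_samples,
    pmf_from_series,
    proton_histogram2d,
)
from hbridge.trajectory_io import CellParameters, Trajectory
from hbridge.units import KB_KCAL


def _series(r_dh, r_ha, dt=1.0):
    r_dh = np.asarray(r_dh, dtype=float)
    r_ha = np.asarray(r_ha, dtype=float)
    return HBGeometrySeries(times=np.arange(r_dh.size) * dt, r_DH=r_dh,
                            r_HA=r_ha, r_DA=r_dh + r_ha)


class TestDistanceSeries:
    def test_collinear_geometry(self):
        pos = np.array([[[0, 0, 0], [1.0, 0, 0], [2.6, 0, 0]]])
        traj = Trajectory(["O", "H", "O"], pos, dt=1.0)
        s = distance_series(traj, BridgeDefinition(0, 1, 2))
        assert s.r_DH[0] == pytest.approx(1.0)
        assert s.r_HA[0] == pytest.approx(1.6)
        assert s.r_DA[0] == pytest.approx(2.6)

    def test_minimum_image_across_cell_boundary(self):
        pos = np.array([[[0, 0, 0], [1.0, 0, 0], [-2.4, 0, 0]]])
        traj = Trajectory(["O", "H", "O"], pos, dt=1.0)
        cell = CellParameters(5, 5, 5)
        s = distance_series(traj, BridgeDefinition(0, 1, 2), cell)
        # brute-force 27-image oracle: nearest image of A(-2.4) is 2.4 away
        lattice = cell.lattice_matrix
        diff = pos[0, 2] - pos[0, 0]
        brute = min(np.linalg.norm(diff + np.array([i, j, k]) @ lattice)
                    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1))
        assert s.r_DA[0] == pytest.approx(brute)
        assert s.r_DA[0] == pytest.approx(2.4)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(SelectionError):
            BridgeDefinition(1, 1, 2)

    def test_out_of_range_index_rejected(self):
        traj = Trajectory(["O", "H", "O"], np.zeros((1, 3, 3)), dt=1.0)
        with pytest.raises(SelectionError):
            distance_series(traj, BridgeDefinition(0, 1, 5))

    def test_triangle_inequality_holds_on_simulated_bridge(self):
        from hbridge.model_systems import (
            ModelPotential,
            SimulationSettings,
            simulate_md,
        )

        traj = simulate_md(ModelPotential(kind="coupled_bridge"),
                           SimulationSettings(n_steps=3000, n_equil=500, seed=2))
        s = distance_series(traj, BridgeDefinition(0, 1, 2))
        assert np.all(s.r_DA <= s.r_DH + s.r_HA + 1e-9)
        assert np.all(s.r_DH > 0) and np.all(s.r_HA > 0)


class TestHistogram2D:
    def test_delta_distribution(self):
        s = _series([1.0] * 50, [1.6] * 50)
        hist = proton_histogram2d(s, bin_width=0.02)
        assert hist.density.max() == pytest.approx(1.0 / 0.02**2)
        assert (hist.density > 0).sum() == 1

    def test_unit_integral(self, rng):
        s = _series(rng.normal(1.0, 0.05, 5000), rng.normal(1.6, 0.07, 5000))
        hist = proton_histogram2d(s, bin_width=0.02)
        dx = np.diff(hist.x_edges)[:, None]
        dy = np.diff(hist.y_edges)[None, :]
        assert np.sum(hist.density * dx * dy) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_product_density_recovered(self, rng):
        """Independent Gaussians on both axes reproduce the analytic product
        density within 4σ Poisson counting error per bin."""
        n = 100_000
        sx = sy = 0.05
        x = rng.normal(1.0, sx, n)
        y = rng.normal(1.6, sy, n)
        hist = proton_histogram2d(_series(x, y), bin_width=0.02,
                                  x_range=(0.8, 1.2), y_range=(1.4, 1.8))
        xc = 0.5 * (hist.x_edges[:-1] + hist.x_edges[1:])
        yc = 0.5 * (hist.y_edges[:-1] + hist.y_edges[1:])
        gx = np.exp(-((xc - 1.0) ** 2) / (2 * sx**2)) / np.sqrt(2 * np.pi * sx**2)
        gy = np.exp(-((yc - 1.6) ** 2) / (2 * sy**2)) / np.sqrt(2 * np.pi * sy**2)
        exact = gx[:, None] * gy[None, :]
        expected_counts = exact * 0.02**2 * n
        sigma = np.sqrt(np.maximum(expected_counts, 1.0)) / (n * 0.02**2)
        assert np.all(np.abs(hist.density - exact) <= 4 * sigma + 1e-12)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(RangeError):
            proton_histogram2d(_series([1.0], [1.6]), bin_width=0.0)


class TestPMF:
    def test_uniform_samples_give_flat_profile(self, rng):
        samples = rng.uniform(1.0, 2.0, 200_000)
        pmf = pmf_from_samples(samples, "r_HA", 20, 297.0)
        # counting noise per bin: sigma_A ~ kT / sqrt(counts); the profile is
        # shifted to its minimum, so the max spans the range of 20 draws
        noise = KB_KCAL * 297.0 / np.sqrt(200_000 / 20)
        assert np.nanmax(pmf.free_energy) < 8 * noise

    def test_gaussian_curvature_matches_kt_over_sigma2(self, rng):
        sigma = 0.1
        samples = rng.normal(0.0, sigma, 300_000)
        pmf = pmf_from_samples(samples, "delta", 41, 297.0,
                               sample_range=(-0.3, 0.3))
        m = pmf.mask
        coeffs = np.polyfit(pmf.bin_centers[m], pmf.free_energy[m], 2)
        expected = KB_KCAL * 297.0 / sigma**2
        assert 2 * coeffs[0] == pytest.approx(expected, rel=0.05)

    def test_min_is_zero_and_empty_bins_masked(self, rng):
        samples = np.concatenate([rng.normal(-1, 0.05, 1000),
                                  rng.normal(1, 0.05, 1000)])
        pmf = pmf_from_samples(samples, "delta", 50, 297.0,
                               sample_range=(-1.5, 1.5))
        assert np.nanmin(pmf.free_energy) == pytest.approx(0.0, abs=1e-12)
        assert np.any(~pmf.mask)
        assert np.all(np.isnan(pmf.free_energy[~pmf.mask]))

    def test_histogram_marginal_consistent_with_pmf(self, rng):
        """−k_BT ln of the 2D histogram's marginal equals the 1D PMF on the
        shared binning to 1e-9."""
        n = 50_000
        x = rng.uniform(0.85, 1.25, n)  # bounded so no sample leaves x_range
        y = rng.uniform(1.3, 1.9, n)
        series = _series(x, y)
        width = 0.05
        hist = proton_histogram2d(series, bin_width=width,
                                  x_range=(0.8, 1.3), y_range=(1.3, 1.9))
        marginal = hist.density.sum(axis=0) * width  # p(r_HA), Å⁻¹
        pmf = pmf_from_samples(y, "r_HA", hist.y_edges, 297.0)
        occupied = pmf.mask & (marginal > 0)
        from_hist = -KB_KCAL * 297.0 * np.log(marginal[occupied])
        from_hist -= from_hist.min()
        direct = pmf.free_energy[occupied] - np.nanmin(pmf.free_energy[occupied])
        assert np.allclose(from_hist, direct, atol=1e-9)

    def test_too_few_occupied_bins_rejected(self):
        with pytest.raises(DataError):
            pmf_from_samples(np.full(100, 1.5), "r_HA", 10, 297.0)

    def test_series_coordinate_dispatch(self):
        s = _series([1.0, 1.1], [1.6, 1.5])
        with pytest.raises(SelectionError):
            pmf_from_series(s, coordinate="bogus")


class TestMinimaBarrier:
    def test_constructed_symmetric_double_well(self):
        centers = np.linspace(-1, 1, 41)
        energy = 3.0 * ((centers / 0.5) ** 2 - 1) ** 2
        energy -= energy.min()
        pmf = PMFProfile("delta", centers, energy, 297.0,
                         np.ones_like(centers, dtype=bool))
        minima, barrier = locate_minima_barrier(pmf)
        assert len(minima) == 2
        assert sorted(np.round(minima, 6).tolist()) == [-0.5, 0.5]
        assert barrier == pytest.approx(3.0)

    def test_monotone_profile_has_no_barrier(self):
        centers = np.linspace(0, 1, 20)
        pmf = PMFProfile("r_HA", centers, centers * 5.0, 297.0,
                         np.ones_like(centers, dtype=bool))
        minima, barrier = locate_minima_barrier(pmf)
        assert len(minima) == 1
        assert barrier is None

    def test_all_masked_rejected(self):
        centers = np.linspace(0, 1, 10)
        pmf = PMFProfile("r_HA", centers, np.full(10, np.nan), 297.0,
                         np.zeros(10, dtype=bool))
        with pytest.raises(DataError):
            locate_minima_barrier(pmf)


def _oracle_state_machine(xi, h):
    """Reference two-threshold state machine, written independently."""
    state = None
    events = 0
    donor_frames = acceptor_frames = 0
    for value in xi:
        if value < -h:
            if state == "A":
                events += 1
            state = "D"
        elif value > h:
            if state == "D":
                events += 1
            state = "A"
        if state == "D":
            donor_frames += 1
        elif state == "A":
            acceptor_frames += 1
    return events, donor_frames, acceptor_frames


class TestTransfers:
    def test_single_crossing(self):
        xi = np.linspace(-0.5, 0.5, 50)
        ev = detect_transfers(xi, hysteresis=0.1)
        assert ev.n_events == 1

    def test_no_crossing_donor_side(self):
        ev = detect_transfers(np.full(100, -0.4), hysteresis=0.1)
        assert ev.n_events == 0
        assert ev.residence_donor == 1.0
        assert ev.residence_acceptor == 0.0

    def test_flicker_inside_band_suppressed(self):
        rng = np.random.default_rng(1)
        xi = np.concatenate([[-0.5], rng.uniform(-0.09, 0.09, 500), [-0.5]])
        ev = detect_transfers(xi, hysteresis=0.1)
        assert ev.n_events == 0

    def test_residence_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        ev = detect_transfers(rng.normal(0, 0.3, 1000), hysteresis=0.1)
        assert ev.residence_donor + ev.residence_acceptor \
            == pytest.approx(1.0, abs=1e-9)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=300),
           st.floats(0.0, 0.4))
    def test_matches_reference_state_machine(self, xi, h):
        xi = np.asarray(xi)
        ev = detect_transfers(xi, hysteresis=h)
        events, nd, na = _oracle_state_machine(xi, h)
        assert ev.n_events == events
        total = nd + na
        if total:
            assert ev.residence_donor == pytest.approx(nd / total)
            assert ev.residence_acceptor == pytest.approx(na / total)

    def test_empty_series_zero_events(self):
        ev = detect_transfers(np.array([]), hysteresis=0.1)
        assert ev.n_events == 0
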