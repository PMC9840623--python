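"""Ground-truth generator: confinement, displacement statistics, rendering."""

import numpy as np
import pandas as pd
import pytest

from smdmap.simkit import (AcquisitionSpec, PopulationSpec, Spherocylinder,
                           render_frames, simulate_dataset)
from smdmap.smdm import extract_displacements
from smdmap.locfit import localize_stack
from smdmap.smdm import _fit_mixture

NM2_PER_MS = 1.0e3


def giant_cell():
    """A cell so large that confinement is negligible over a few steps."""
    return Spherocylinder(400_000.0, 20_000.0, center_nm=(200_000.0, 30_000.0))


def true_pair_displacements(gt):
    d = gt.positions_nm[:, 1::2, :2] - gt.positions_nm[:, 0::2, :2]
    return np.linalg.norm(d, axis=-1).ravel(), d


class TestGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spherocylinder(500.0, 320.0)  # length < 2 radius
        with pytest.raises(ValueError):
            Spherocylinder(2000.0, -1.0)

    def test_interior_sampling_confined(self, rng):
        cell = Spherocylinder(2020.0, 320.0)
        pts = cell.sample_interior(2000, rng)
        assert np.all(cell.contains_local(pts))

    def test_surface_sampling_on_surface(self, rng):
        cell = Spherocylinder(2020.0, 320.0)
        pts = cell.sample_surface(2000, rng)
        np.testing.assert_allclose(cell.distance_to_axis(pts), 320.0,
                                   atol=1e-6)


class TestSimulateDataset:
    def test_zero_diffusion_identity(self):
        cell = Spherocylinder(2020.0, 320.0, (5000.0, 5000.0))
        pops = [PopulationSpec("cytoplasm_3d", 0.0, 1.0, 20)]
        acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=50,
                              loc_sigma_nm=0.0, rng_seed=1, fov_nm=10_000.0)
        table, gt = simulate_dataset([cell], pops, acq)
        # every genuine pair of every molecule has displacement exactly 0
        r, _ = true_pair_displacements(gt)
        assert np.all(r == 0.0)
        assert (gt.loc_pair_id >= 0).all()

    def test_reproducible_bitwise(self):
        cell = Spherocylinder(2020.0, 320.0, (5000.0, 5000.0))
        pops = [PopulationSpec("cytoplasm_3d", 2.0, 1.0, 10)]
        acq = AcquisitionSpec(n_frame_pairs=40, rng_seed=7, fov_nm=10_000.0,
                              background_rate=0.01)
        t1, _ = simulate_dataset([cell], pops, acq)
        t2, _ = simulate_dataset([cell], pops, acq)
        assert t1.equals(t2)

    def test_cytoplasm_confined_membrane_on_surface(self, rng):
        cell = Spherocylinder(2020.0, 320.0, (5000.0, 5000.0),
                              axis_angle_deg=25.0)
        pops = [PopulationSpec("cytoplasm_3d", 5.0, 0.5, 40),
                PopulationSpec("membrane_surface", 0.2, 0.5, 40)]
        acq = AcquisitionSpec(dt_peak_to_peak_ms=10.0, n_frame_pairs=40,
                              rng_seed=3, fov_nm=10_000.0)
        _, gt = simulate_dataset([cell], pops, acq)
        local = cell.world_to_local(gt.positions_nm.reshape(-1, 3))
        local = local.reshape(gt.positions_nm.shape)
        cyto = gt.population_id == 0
        memb = gt.population_id == 1
        assert np.all(cell.contains_local(local[cyto].reshape(-1, 3),
                                          tol=1e-6))
        dist = cell.distance_to_axis(local[memb].reshape(-1, 3))
        np.testing.assert_allclose(dist, 320.0, atol=1e-6)

    def test_displacement_moments_match_theory(self):
        # mean r^2 = 4 D dt in the absence of confinement (3 SE band)
        pops = [PopulationSpec("cytoplasm_3d", 5.0, 1.0, 200)]
        acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=250,
                              loc_sigma_nm=0.0, rng_seed=2, fov_nm=400_000.0)
        _, gt = simulate_dataset([giant_cell()], pops, acq)
        r, _ = true_pair_displacements(gt)
        r2 = r ** 2
        d_hat = r2.mean() / (4 * 1.5 * NM2_PER_MS)
        se = r2.std() / np.sqrt(r2.size) / (4 * 1.5 * NM2_PER_MS)
        assert abs(d_hat - 5.0) <= 3 * se

    def test_step_variance_includes_localization_error(self):
        # per-coordinate variance of recorded pairs: 2 D dt + 2 sigma_loc^2
        pops = [PopulationSpec("cytoplasm_3d", 5.0, 1.0, 200)]
        acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=250,
                              loc_sigma_nm=25.0, rng_seed=4, fov_nm=400_000.0)
        table, _ = simulate_dataset([giant_cell()], pops, acq)
        tab = table[table.pair_id >= 0].sort_values(["pair_id", "frame"])
        arr = tab[["x_nm", "y_nm"]].to_numpy().reshape(-1, 2, 2)
        steps = arr[:, 1] - arr[:, 0]
        expected = 2 * 5.0 * NM2_PER_MS * 1.5 + 2 * 25.0 ** 2
        for axis in range(2):
            v = steps[:, axis] ** 2
            se = v.std() / np.sqrt(v.size)
            assert abs(v.mean() - expected) <= 3 * se

    def test_membrane_projection_underestimates_d(self, rng):
        # lateral diffusion on a cylinder surface, projected to the focal
        # plane and fit with the single-component model, comes out ~30% low
        cell = Spherocylinder(100_000.0, 320.0)
        p0 = cell.sample_surface(30_000, rng)
        p1 = cell.step_surface(p0, 0.2, 10.0, rng)
        r = np.hypot(p1[:, 0] - p0[:, 0], p1[:, 1] - p0[:, 1])
        r = r[r <= 600.0]
        fit = _fit_mixture(r, 10.0, 600.0, 1, fix_b=0.0)
        bias_pct = 100.0 * (1.0 - fit.components[0][0] / 0.2)
        assert bias_pct == pytest.approx(30.0, abs=10.0)

    def test_background_pairing_load(self):
        # immobile molecules + uniform background: false candidates per
        # genuine localization = background_rate * pi * r_max^2
        cell = Spherocylinder(2020.0, 320.0, (10_000.0, 10_000.0))
        pops = [PopulationSpec("cytoplasm_3d", 0.0, 1.0, 1)]
        rate = 0.05  # per frame per um^2
        acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=2000,
                              loc_sigma_nm=0.0, background_rate=rate,
                              rng_seed=9, fov_nm=20_000.0)
        table, gt = simulate_dataset([cell], pops, acq)
        # candidates of *genuine* starts only: keep genuine odd-frame rows
        # plus everything in even frames, then subtract the genuine matches
        odd = (table.frame % 2 == 1).to_numpy()
        genuine = (gt.loc_pair_id >= 0)
        sub = table[(odd & genuine) | ~odd]
        ds = extract_displacements(sub, 1.5, 600.0)
        n_pairs = 2000
        n_false = len(ds) - n_pairs
        lam = rate * np.pi * 0.6 ** 2   # rate per um^2, r_max = 0.6 um
        expected = lam * n_pairs
        assert abs(n_false - expected) <= 3 * np.sqrt(expected)

    def test_fraction_sum_validated(self):
        cell = Spherocylinder(2020.0, 320.0)
        with pytest.raises(ValueError, match="fractions"):
            simulate_dataset([cell],
                             [PopulationSpec("cytoplasm_3d", 1.0, 0.5, 5)],
                             AcquisitionSpec())

    def test_overlapping_cells_rejected(self):
        a = Spherocylinder(2020.0, 320.0, (0.0, 0.0))
        b = Spherocylinder(2020.0, 320.0, (500.0, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            simulate_dataset([a, b],
                             [PopulationSpec("cytoplasm_3d", 1.0, 1.0, 5)],
                             AcquisitionSpec())


class TestRenderFrames:
    def test_empty_table_pure_offset(self):
        t = pd.DataFrame(columns=["frame", "x_nm", "y_nm"])
        stack = render_frames(t, offset=100.0, fov_nm=2000.0, n_frames=3)
        assert stack.shape == (3, 20, 20)
        assert np.all(stack == 100.0)

    def test_photon_conservation(self):
        t = pd.DataFrame([(1, 1050.0, 1050.0)],
                         columns=["frame", "x_nm", "y_nm"])
        stack = render_frames(t, fov_nm=2100.0, offset=5.0,
                              photons_per_spot=1000.0)
        signal = stack[0].sum() - 5.0 * stack[0].size
        assert signal == pytest.approx(1000.0, rel=1e-3)
        iy, ix = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert (ix, iy) == (10, 10)

    def test_out_of_fov_warns(self):
        t = pd.DataFrame([(1, -500.0, 100.0)],
                         columns=["frame", "x_nm", "y_nm"])
        with pytest.warns(UserWarning, match="clipped"):
            render_frames(t, fov_nm=2000.0)

    def test_localizer_roundtrip_grid(self):
        # 9 noiseless emitters recovered by the localizer within 1 nm
        xs = [3050.0, 5020.0, 7000.0]
        ys = [3000.0, 5050.0, 6990.0]
        t = pd.DataFrame([(1, x, y) for x in xs for y in ys],
                         columns=["frame", "x_nm", "y_nm"])
        stack = render_frames(t, fov_nm=10_000.0)
        locs = localize_stack(stack)
        assert len(locs) == 9
        for _, row in locs.iterrows():
            d = np.min(np.hypot(t.x_nm - row.x_nm, t.y_nm - row.y_nm))
            assert d < 1.0
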