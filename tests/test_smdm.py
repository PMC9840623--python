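"""Displacement extraction, the truncated mixture model, MLE and maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from smdmap.smdm import (DisplacementSet, build_diffusion_map,
                         closed_form_diffusion, displacement_pdf,
                         extract_displacements, fit_displacement_mle)

from conftest import (make_displacement_set, sample_mixture_truncated,
                      sample_rayleigh_truncated)


def table_from_rows(rows):
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])


class TestExtractDisplacements:
    def test_single_pair(self):
        t = table_from_rows([(1, 0.0, 0.0), (2, 100.0, 0.0)])
        ds = extract_displacements(t, dt_ms=1.5)
        assert len(ds) == 1
        assert ds.r[0] == pytest.approx(100.0)

    def test_beyond_cutoff_excluded(self):
        t = table_from_rows([(1, 0.0, 0.0), (2, 700.0, 0.0)])
        assert len(extract_displacements(t, dt_ms=1.5, r_max_nm=600.0)) == 0

    def test_all_candidates_retained(self):
        t = table_from_rows([(1, 0.0, 0.0), (2, 100.0, 0.0), (2, 0.0, 400.0)])
        ds = extract_displacements(t, dt_ms=1.5)
        assert sorted(ds.r.round(6)) == [100.0, 400.0]

    def test_nearest_only_flag(self):
        t = table_from_rows([(1, 0.0, 0.0), (2, 100.0, 0.0), (2, 0.0, 400.0)])
        ds = extract_displacements(t, dt_ms=1.5, nearest_only=True)
        assert list(ds.r.round(6)) == [100.0]

    def test_pairing_respects_frame_parity(self):
        # frames 2 and 3 belong to different pairs: no displacement
        t = table_from_rows([(2, 0.0, 0.0), (3, 50.0, 0.0)])
        assert len(extract_displacements(t, dt_ms=1.5)) == 0

    def test_empty_table(self):
        assert len(extract_displacements(table_from_rows([]), dt_ms=1.5)) == 0


class TestDisplacementPdf:
    def test_zero_at_origin(self):
        assert displacement_pdf(0.0, [(1.0, 1.0)], 1e-7, 600.0, 1.5) == 0.0

    @pytest.mark.parametrize("components,b,dt", [
        ([(1.0, 1.0)], 1e-7, 1.5),
        ([(5.0, 1.0)], 0.0, 1.5),
        ([(2.0, 0.6), (0.12, 0.4)], 5e-7, 10.0),
        ([(7.5, 0.3), (1.0, 0.5), (0.05, 0.2)], 2e-6, 1.5),
        ([(0.01, 1.0)], 0.0, 10.0),
    ])
    def test_normalization(self, components, b, dt):
        val, err = quad(lambda r: displacement_pdf(r, components, b, 600.0, dt),
                        0.0, 600.0, limit=300)
        assert abs(val - 1.0) < 1e-8

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(D=st.floats(0.01, 50.0), b=st.floats(0.0, 1e-5),
           dt=st.floats(0.5, 20.0))
    def test_normalization_property(self, D, b, dt):
        val, _ = quad(lambda r: displacement_pdf(r, [(D, 1.0)], b, 600.0, dt),
                      0.0, 600.0, limit=300)
        assert abs(val - 1.0) < 1e-8

    def test_component_merging_identity(self):
        r = np.linspace(0, 600, 301)
        two = displacement_pdf(r, [(1.0, 0.5), (1.0, 0.5)], 3e-7, 600.0, 1.5)
        one = displacement_pdf(r, [(1.0, 1.0)], 3e-7, 600.0, 1.5)
        np.testing.assert_allclose(two, one, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            displacement_pdf(-1.0, [(1.0, 1.0)], 0.0, 600.0, 1.5)
        with pytest.raises(ValueError):
            displacement_pdf(601.0, [(1.0, 1.0)], 0.0, 600.0, 1.5)


class TestClosedFormDiffusion:
    @pytest.mark.parametrize("dt,expected", [(1.5, 60.0), (10.0, 9.0)])
    def test_rmax_sanity_bound(self, dt, expected):
        # all displacements at the 600 nm cutoff
        ds = make_displacement_set(np.full(10, 600.0), dt, 600.0)
        assert closed_form_diffusion(ds) == pytest.approx(expected)

    def test_zero_displacement(self):
        ds = make_displacement_set(np.zeros(1), 1.5, 600.0)
        assert closed_form_diffusion(ds) == 0.0


class TestFitDisplacementMLE:
    def test_degenerate_equal_displacements(self):
        # all r identical, untruncated, b=0: closed-form MLE r^2/(4 dt)
        ds = make_displacement_set(np.full(100, 200.0), 10.0, np.inf)
        fit = fit_displacement_mle(ds, 1, fix_b=0.0)
        assert fit.components[0][0] == pytest.approx(1.0, rel=1e-4)

    def test_single_component_recovery(self, rng):
        r = sample_rayleigh_truncated(rng, 10_000, 5.0, 1.5, 600.0)
        ds = make_displacement_set(r, 1.5, 600.0)
        fit = fit_displacement_mle(ds, 1, fix_b=0.0)
        assert fit.components[0][0] == pytest.approx(5.0, rel=0.05)
        assert fit.converged

    def test_mle_matches_moment_oracle(self, rng):
        # with b=0 and negligible truncation the MLE equals mean r^2/(4 dt)
        r = sample_rayleigh_truncated(rng, 10_000, 0.5, 1.5, 600.0)
        ds = make_displacement_set(r, 1.5, 600.0)
        fit = fit_displacement_mle(ds, 1, fix_b=0.0)
        assert fit.components[0][0] == pytest.approx(
            closed_form_diffusion(ds), rel=0.01)

    def test_two_component_recovery(self, rng):
        r = sample_mixture_truncated(
            rng, 10_000, [(2.0, 0.6), (0.12, 0.4)], 0.0, 10.0, 600.0)
        ds = make_displacement_set(r, 10.0, 600.0)
        fit = fit_displacement_mle(ds, 2, fix_b=0.0)
        (d1, f1), (d2, f2) = fit.components
        assert abs(f1 - 0.6) < 0.05
        assert d1 == pytest.approx(2.0, rel=0.15)
        assert d2 == pytest.approx(0.12, rel=0.15)

    def test_fractions_sum_and_order(self, rng):
        r = sample_mixture_truncated(
            rng, 5000, [(2.0, 0.5), (0.1, 0.5)], 2e-7, 10.0, 600.0)
        fit = fit_displacement_mle(make_displacement_set(r, 10.0, 600.0), 2)
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-9)
        assert fit.D[0] >= fit.D[1]
        assert fit.b >= 0

    def test_background_robustness(self, rng):
        # uniform-area false pairs: absorbed when b is free, inflate D when
        # b is pinned at 0, monotonically in the contamination rate
        n = 6000
        r = sample_rayleigh_truncated(rng, n, 2.0, 10.0, 600.0)
        inflated = []
        for frac in (0.0, 0.1, 0.2):
            nb = int(frac * n)
            rb = 600.0 * np.sqrt(rng.uniform(size=nb))
            ds = make_displacement_set(np.concatenate([r, rb]), 10.0, 600.0)
            free = fit_displacement_mle(ds, 1)
            pinned = fit_displacement_mle(ds, 1, fix_b=0.0)
            assert abs(free.components[0][0] - 2.0) / 2.0 < 0.10
            inflated.append(pinned.components[0][0])
        assert inflated[0] < inflated[1] < inflated[2]
        assert inflated[2] > 2.0 * 1.10

    def test_likelihood_monotone_in_components(self, rng):
        r = sample_rayleigh_truncated(rng, 4000, 1.0, 1.5, 600.0)
        ds = make_displacement_set(r, 1.5, 600.0)
        l1 = fit_displacement_mle(ds, 1, fix_b=0.0).log_likelihood
        l2 = fit_displacement_mle(ds, 2, fix_b=0.0).log_likelihood
        assert l2 >= l1 - 1e-6

    def test_deterministic(self, rng):
        r = sample_mixture_truncated(
            rng, 3000, [(1.0, 0.7), (0.05, 0.3)], 0.0, 10.0, 600.0)
        ds = make_displacement_set(r, 10.0, 600.0)
        a = fit_displacement_mle(ds, 2)
        b = fit_displacement_mle(ds, 2)
        assert a.components == b.components and a.b == b.b

    def test_refuses_small_sets(self):
        ds = make_displacement_set(np.full(10, 100.0), 1.5, 600.0)
        with pytest.raises(ValueError, match="refusing"):
            fit_displacement_mle(ds, 1)

    def test_rejects_bad_component_count(self):
        ds = make_displacement_set(np.full(100, 100.0), 1.5, 600.0)
        with pytest.raises(ValueError):
            fit_displacement_mle(ds, 4)


def _synthetic_cell_displacements(rng, n, d_of_xy, lx=2000.0, ly=600.0,
                                  dt=1.5, r_max=600.0):
    """Displacements on a rectangle with position-dependent D (um^2/s)."""
    x0 = rng.uniform(0, lx, n)
    y0 = rng.uniform(0, ly, n)
    sd = np.sqrt(2.0 * d_of_xy(x0, y0) * 1e3 * dt)
    x1 = x0 + rng.normal(size=n) * sd
    y1 = y0 + rng.normal(size=n) * sd
    keep = np.hypot(x1 - x0, y1 - y0) <= r_max
    return DisplacementSet(x0[keep], y0[keep], x1[keep], y1[keep],
                           np.zeros(int(keep.sum()), int), dt, r_max)


class TestDiffusionMap:
    def test_homogeneous_recovery(self, rng):
        ds = _synthetic_cell_displacements(rng, 60_000, lambda x, y: 5.0)
        m = build_diffusion_map(ds)
        valid = m.valid_mask & np.isfinite(m.D)
        assert valid.sum() > 100
        frac = np.mean(np.abs(m.D[valid] - 5.0) / 5.0 <= 0.25)
        assert frac >= 0.90

    def test_two_zone_contrast(self, rng):
        ds = _synthetic_cell_displacements(
            rng, 60_000, lambda x, y: np.where(x < 1000.0, 5.0, 0.5))
        m = build_diffusion_map(ds)
        centers = m.origin_nm[0] + (np.arange(m.D.shape[1]) + 0.5) * m.pixel_nm
        left = np.nanmedian(m.D[:, centers < 1000.0])
        right = np.nanmedian(m.D[:, centers >= 1000.0])
        assert left / right >= 5.0

    def test_min_count_masking(self, rng):
        ds = _synthetic_cell_displacements(rng, 500, lambda x, y: 1.0)
        m = build_diffusion_map(ds, min_count=20)
        sparse = m.counts < 20
        assert np.all(np.isnan(m.D[sparse]))

    def test_map_global_consistency(self, rng):
        # count-weighted mean of valid pixels tracks the whole-cell fit
        ds = _synthetic_cell_displacements(rng, 40_000, lambda x, y: 2.0)
        whole = fit_displacement_mle(ds, 1, fix_b=0.0).components[0][0]
        m = build_diffusion_map(ds)
        valid = m.valid_mask & np.isfinite(m.D)
        weighted = np.sum(m.D[valid] * m.counts[valid]) / m.counts[valid].sum()
        assert weighted == pytest.approx(whole, rel=0.15)

    def test_empty_set(self):
        ds = make_displacement_set(np.empty(0), 1.5, 600.0)
        m = build_diffusion_map(ds)
        assert m.D.size == 0
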