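"""OPD recovery: minimal-norm lookup and TV-regularized gradient descent."""

import numpy as np
import pytest

from jlphase import (
    CalibrationCurve,
    OPDMap,
    RGBImage,
    ReconstructionConfig,
    cell_phantom,
    evaluate_lut,
    minimal_norm_solution,
    reconstruct_tv,
    render_rgb,
    tv_loss,
    tv_loss_gradient,
    tv_penalty,
)
from jlphase.calibration import PolyLUT
from jlphase.inversion import tv_penalty_gradient


def brute_force_minnorm(image: RGBImage, curve: CalibrationCurve) -> np.ndarray:
    """Scalar reference: exhaustive per-pixel scan over all LUT bins."""
    h, w = image.values.shape[:2]
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            best, best_d = 0, np.inf
            for k in range(len(curve)):
                d = ((image.values[i, j] - curve.mean_rgb[k]) ** 2).sum()
                if d < best_d:
                    best, best_d = k, d
            out[i, j] = curve.opd_bins[best]
    return out


class TestMinimalNorm:
    def test_exact_bin_color_recovers_bin(self, fiber_curve):
        k = 17
        image = RGBImage(np.tile(fiber_curve.mean_rgb[k], (2, 2, 1)))
        opd = minimal_norm_solution(image, fiber_curve)
        assert np.all(opd.values == fiber_curve.opd_bins[k])

    def test_matches_brute_force(self, fiber_curve, rng):
        image = RGBImage(rng.uniform(0, 1, (12, 12, 3)))
        fast = minimal_norm_solution(image, fiber_curve)
        np.testing.assert_array_equal(fast.values, brute_force_minnorm(image, fiber_curve))

    def test_snapped_phantom_recovered_exactly(self, fiber_curve):
        """OPDs snapped to bin centers round-trip through render + lookup."""
        idx = np.arange(0, 50, 3)
        snapped = OPDMap(fiber_curve.opd_bins[idx][None, :])
        image = render_rgb(snapped)
        rec = minimal_norm_solution(image, fiber_curve)
        # rendering at a bin center is not identical to the bin *mean*, so
        # allow the lookup to land in the adjacent bin at worst
        bin_width = fiber_curve.opd_bins[1] - fiber_curve.opd_bins[0]
        assert np.abs(rec.values - snapped.values).max() <= bin_width + 1e-6

    def test_ties_break_to_smaller_opd(self):
        rgb = np.array([[0.2, 0.2, 0.2], [0.2, 0.2, 0.2], [0.9, 0.9, 0.9]])
        curve = CalibrationCurve(np.array([10.0, 20.0, 30.0]), rgb, np.ones(3, dtype=int))
        image = RGBImage(np.full((1, 1, 3), 0.2))
        assert minimal_norm_solution(image, curve).values[0, 0] == 10.0


class TestTVPenalty:
    def test_constant_map_closed_form(self):
        assert tv_penalty(np.full((7, 9), 42.0), eps_c=0.5) == pytest.approx(7 * 9 * 0.5)

    def test_single_jump_closed_form(self):
        # 2×1 map (0, a): one forward difference of magnitude |a|
        a = 137.0
        val = tv_penalty(np.array([[0.0], [a]]), eps_c=1e-9)
        assert val == pytest.approx(a, abs=1e-6)

    def test_matches_double_loop_reference(self, rng):
        values = rng.normal(0, 50, (8, 8))
        eps = 0.75
        ref = 0.0
        for i in range(8):
            for j in range(8):
                gx = values[i, j + 1] - values[i, j] if j < 7 else 0.0
                gy = values[i + 1, j] - values[i, j] if i < 7 else 0.0
                ref += np.sqrt(gx**2 + gy**2 + eps**2)
        assert tv_penalty(values, eps) == pytest.approx(ref, rel=1e-12)

    def test_square_variant(self, rng):
        values = rng.normal(0, 10, (5, 5))
        eps = 0.3
        gx = np.zeros_like(values)
        gy = np.zeros_like(values)
        gx[:, :-1] = np.diff(values, axis=1)
        gy[:-1, :] = np.diff(values, axis=0)
        assert tv_penalty(values, eps, variant="square") == pytest.approx(
            (gx**2 + gy**2 + eps**2).sum()
        )

    def test_gradient_zero_on_constant_map(self):
        g = tv_penalty_gradient(np.full((6, 6), 3.0), eps_c=0.01)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            tv_penalty(np.zeros((3, 3)), eps_c=0.0)


class TestTVLoss:
    def test_zero_lambda_reduces_to_data_term(self, fiber_lut, rng):
        opd = OPDMap(rng.uniform(100, 1500, (6, 6)))
        img = RGBImage(rng.uniform(0, 1, (6, 6, 3)))
        cfg = ReconstructionConfig(lambda_tv=0.0)
        total, data, tv = tv_loss(opd, img, fiber_lut, cfg)
        assert total == pytest.approx(data)
        assert tv > 0

    def test_constant_map_closed_form_data_term(self, fiber_lut):
        opd_val = 700.0
        v = np.array([0.1, 0.4, 0.7])
        opd = OPDMap(np.full((5, 8), opd_val))
        img = RGBImage(np.tile(v, (5, 8, 1)))
        cfg = ReconstructionConfig()
        _, data, _ = tv_loss(opd, img, fiber_lut, cfg)
        from jlphase.calibration import evaluate_lut_raw

        pred, _ = evaluate_lut_raw(fiber_lut, np.array(opd_val))
        assert data == pytest.approx(5 * 8 * ((pred - v) ** 2).sum())

    def test_perfect_lut_round_trip_data_term_vanishes(self):
        """An image rendered through the LUT itself has ~zero data term."""
        # coefficients chosen so every channel stays inside [0, 1] over the
        # domain (no output clipping between render and loss)
        lut = PolyLUT([0.5, 0.3], [0.5, -0.2], [0.4, 0.1], (0.0, 1000.0), order=1)
        opd = OPDMap(np.linspace(100, 900, 36).reshape(6, 6))
        rgb, _ = evaluate_lut(lut, opd.values)
        img = RGBImage(rgb)
        _, data, _ = tv_loss(opd, img, lut, ReconstructionConfig())
        assert data / opd.values.size <= 1e-4

    def test_shape_mismatch_rejected(self, fiber_lut):
        with pytest.raises(ValueError):
            tv_loss(
                OPDMap(np.zeros((4, 4))),
                RGBImage(np.zeros((4, 5, 3))),
                fiber_lut,
                ReconstructionConfig(),
            )


class TestTVLossGradient:
    def test_matches_finite_differences(self, fiber_lut, rng):
        cfg = ReconstructionConfig()
        h = 0.5
        for _ in range(3):
            # avoid sub-nm neighbor differences, where the smoothed-TV
            # curvature exceeds what an h = 0.5 nm difference can resolve
            while True:
                values = rng.uniform(100, 1500, (6, 6))
                if (
                    np.abs(np.diff(values, axis=0)).min() > 5.0
                    and np.abs(np.diff(values, axis=1)).min() > 5.0
                ):
                    break
            opd = OPDMap(values)
            img = RGBImage(rng.uniform(0, 1, (6, 6, 3)))
            g = tv_loss_gradient(opd, img, fiber_lut, cfg)
            fd = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    up = opd.values.copy()
                    up[i, j] += h
                    dn = opd.values.copy()
                    dn[i, j] -= h
                    fd[i, j] = (
                        tv_loss(OPDMap(up), img, fiber_lut, cfg)[0]
                        - tv_loss(OPDMap(dn), img, fiber_lut, cfg)[0]
                    ) / (2 * h)
            # atol floor covers the finite-difference truncation error
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=5e-7)

    def test_stationary_at_perfect_smooth_minimum(self):
        lut = PolyLUT([0.2, 0.3], [0.5, -0.1], [0.4, 0.2], (0.0, 1000.0), order=1)
        opd = OPDMap(np.full((5, 5), 500.0))
        rgb, _ = evaluate_lut(lut, opd.values)
        img = RGBImage(rgb)
        g = tv_loss_gradient(opd, img, lut, ReconstructionConfig(lambda_tv=0.0))
        np.testing.assert_allclose(g, 0.0, atol=1e-10)


class TestReconstructTV:
    @pytest.fixture(scope="class")
    def cell_setup(self, fiber_curve, fiber_lut):
        cell = cell_phantom((96, 96), pixel_size=0.2, opd_peak=500.0, seed=3)
        image = render_rgb(cell)
        return cell, image

    def test_loss_never_worse_than_initialization(self, cell_setup, fiber_curve, fiber_lut):
        cell, image = cell_setup
        cfg = ReconstructionConfig(n_iters=60)
        rec, trace = reconstruct_tv(image, fiber_lut, fiber_curve, cfg)
        final = tv_loss(rec, image, fiber_lut, cfg)[0]
        assert final <= trace.total[0] + 1e-9
        assert len(trace) == 60

    def test_recovers_cell_phantom_within_bin_width(self, cell_setup, fiber_curve, fiber_lut):
        cell, image = cell_setup
        rec, _ = reconstruct_tv(image, fiber_lut, fiber_curve, ReconstructionConfig())
        mask = cell.values > 50.0
        bin_width = fiber_curve.opd_bins[1] - fiber_curve.opd_bins[0]
        assert np.abs(rec.values - cell.values)[mask].mean() <= bin_width

    def test_zero_rate_limit_returns_initialization(self, cell_setup, fiber_curve, fiber_lut):
        cell, image = cell_setup
        cfg = ReconstructionConfig(n_iters=1, learning_rate=1e-9, lr_schedule="constant")
        rec, _ = reconstruct_tv(image, fiber_lut, fiber_curve, cfg)
        init = minimal_norm_solution(image, fiber_curve)
        np.testing.assert_allclose(rec.values, init.values, atol=1e-6)

    def test_deterministic(self, cell_setup, fiber_curve, fiber_lut):
        cell, image = cell_setup
        cfg = ReconstructionConfig(n_iters=20)
        a, ta = reconstruct_tv(image, fiber_lut, fiber_curve, cfg)
        b, tb = reconstruct_tv(image, fiber_lut, fiber_curve, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ta.total, tb.total)

    def test_stronger_regularization_smooths_more(self, cell_setup, fiber_curve, fiber_lut):
        _, image = cell_setup
        tv_terms = []
        for lam in (0.1, 1.0, 10.0):
            cfg = ReconstructionConfig(lambda_tv=lam, n_iters=60)
            rec, _ = reconstruct_tv(image, fiber_lut, fiber_curve, cfg)
            tv_terms.append(
                tv_penalty(rec.values / cfg.tv_opd_unit, cfg.eps_c, cfg.tv_variant)
            )
        assert tv_terms[1] <= tv_terms[0] + 1e-6
        assert tv_terms[2] <= tv_terms[1] + 1e-6

    def test_flat_init_supported(self, cell_setup, fiber_curve, fiber_lut):
        _, image = cell_setup
        cfg = ReconstructionConfig(n_iters=5, init="flat")
        rec, _ = reconstruct_tv(image, fiber_lut, None, cfg)
        assert rec.values.shape == image.values.shape[:2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(lambda_tv=-1.0)
        with pytest.raises(ValueError):
            ReconstructionConfig(eps_c=0.0)
        with pytest.raises(ValueError):
            ReconstructionConfig(n_iters=0)
        with pytest.raises(ValueError):
            ReconstructionConfig(tv_variant="cubic")
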