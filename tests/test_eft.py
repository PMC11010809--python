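import numpy as np
import pytest

from scalemorph.eft import (EFTCoefficients, choose_n_harmonics, coefficient_matrix,
                            eft_forward, eft_inverse, harmonic_power,
                            normalize_phase, shift_start)
from scalemorph.outline import OutlinePolygon, normalize_outline, resample_equidistant


def quadrature_oracle(poly, n_harmonics):
    """Trapezoid-rule Fourier projections of the piecewise-linear x(t), y(t).

    Independent of the closed-form implementation: densely samples the
    parameterized chain (unit parameter per vertex) and integrates the
    projections numerically.
    """
    v = poly.vertices
    big_t = len(v)
    dense = 400  # samples per edge
    t = np.arange(big_t * dense + 1) / dense  # include the closing point t = T
    idx = np.minimum(np.floor(t).astype(int), big_t - 1)
    frac = (t - idx)[:, None]
    pts = v[idx] + frac * (np.roll(v, -1, axis=0)[idx] - v[idx])
    out = []
    for n in range(1, n_harmonics + 1):
        cosn = np.cos(2 * np.pi * n * t / big_t)
        sinn = np.sin(2 * np.pi * n * t / big_t)
        a = 2 * np.trapezoid(pts[:, 0] * cosn, t) / big_t
        b = 2 * np.trapezoid(pts[:, 0] * sinn, t) / big_t
        c = 2 * np.trapezoid(pts[:, 1] * cosn, t) / big_t
        d = 2 * np.trapezoid(pts[:, 1] * sinn, t) / big_t
        out.append((a, b, c, d))
    return np.array(out)


class TestForward:
    def test_ellipse_is_one_harmonic(self, ellipse_poly):
        coef = eft_forward(ellipse_poly, 5)
        np.testing.assert_allclose(coef.harmonics[0], [2, 0, 0, 1], atol=1e-3)
        assert np.abs(coef.harmonics[1:]).max() < 1e-3

    def test_unit_circle_symmetry(self, circle_poly):
        coef = eft_forward(circle_poly, 3)
        a1, b1, c1, d1 = coef.harmonics[0]
        assert a1 == pytest.approx(d1, abs=1e-3)
        assert abs(b1) < 1e-3 and abs(c1) < 1e-3

    def test_matches_quadrature_oracle_on_random_polygon(self):
        rng = np.random.default_rng(14)
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        r = 1 + 0.3 * rng.standard_normal(60).cumsum() / 20
        r = np.abs(r) + 0.3
        poly = OutlinePolygon(np.column_stack((r * np.cos(th), r * np.sin(th))))
        mine = eft_forward(poly, 6).harmonics
        oracle = quadrature_oracle(poly, 6)
        np.testing.assert_allclose(mine, oracle, atol=1e-6)

    def test_nyquist_bound_enforced(self, unit_square):
        poly = resample_equidistant(unit_square, 16)
        with pytest.raises(ValueError, match="Nyquist"):
            eft_forward(poly, 9)

    def test_dc_is_vertex_mean_for_equidistant_chain(self, circle_poly):
        poly = resample_equidistant(circle_poly, 256)
        coef = eft_forward(poly, 2)
        np.testing.assert_allclose(coef.dc, poly.vertices.mean(axis=0), atol=1e-6)


class TestInverse:
    def test_round_trip_ellipse(self, ellipse_poly):
        coef = eft_forward(ellipse_poly, 1)
        rec = eft_inverse(coef, 720)
        # every reconstructed vertex close to the true ellipse
        err = np.abs((rec.vertices[:, 0] / 2) ** 2 + rec.vertices[:, 1] ** 2 - 1)
        assert err.max() < 1e-2
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        truth = np.column_stack((2 * np.cos(t), np.sin(t)))
        assert np.abs(rec.vertices - truth).max() < 1e-3

    def test_degenerate_zero_harmonics_flagged(self):
        coef = EFTCoefficients(dc=(3.0, 4.0), harmonics=np.zeros((2, 4)))
        with pytest.raises(ValueError):
            eft_inverse(coef, 100)  # all points at (3,4): invalid polygon

    def test_reconstruction_error_non_increasing(self, wavy_template):
        poly = resample_equidistant(wavy_template.base_outline, 360)
        coef = eft_forward(poly, 32)
        errs = []
        for k in range(1, 33):
            rec = eft_inverse(coef, 360, n_harmonics=k)
            # root-mean-square reconstruction error (the L2 sense in which
            # Fourier truncation is guaranteed to improve with more terms)
            errs.append(np.sqrt(((rec.vertices - poly.vertices) ** 2).mean()))
        diffs = np.diff(errs)
        assert np.all(diffs <= 1e-9)

    def test_forward_inverse_is_projection(self, wavy_template):
        poly = resample_equidistant(wavy_template.base_outline, 360)
        coef = eft_forward(poly, 8)
        # dense reconstruction so the piecewise-linear re-expansion error
        # (O(h^2) in the sampling step) sits below the tolerance
        rec = eft_inverse(coef, 20_000)
        again = eft_forward(rec, 8)
        np.testing.assert_allclose(again.harmonics, coef.harmonics, atol=1e-6)


class TestPower:
    def test_ellipse_power(self, ellipse_poly):
        coef = eft_forward(ellipse_poly, 5)
        power, cum = harmonic_power(coef)
        assert power[0] == pytest.approx(2.5, abs=1e-3)  # (2^2 + 1^2) / 2
        assert cum[0] == pytest.approx(1.0, abs=1e-5)
        assert choose_n_harmonics(cum, 0.99) == 1

    def test_cumulative_fraction_arithmetic(self):
        coef = EFTCoefficients(dc=(0, 0), harmonics=np.array(
            [[np.sqrt(2 * 97), 0, 0, 0], [2, 0, 0, 0], [np.sqrt(2), 0, 0, 0]]))
        power, cum = harmonic_power(coef)
        np.testing.assert_allclose(power, [97, 2, 1], rtol=1e-12)
        np.testing.assert_allclose(cum, [0.97, 0.99, 1.00], atol=1e-12)
        assert choose_n_harmonics(cum, 0.99) == 2

    def test_powers_nonneg_cumulative_monotone(self, wavy_template):
        coef = eft_forward(resample_equidistant(wavy_template.base_outline, 360), 30)
        power, cum = harmonic_power(coef)
        assert (power >= 0).all()
        assert (np.diff(cum) >= -1e-15).all()
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)

    def test_dataset_rule_takes_maximum(self):
        fracs = [np.array([0.9, 0.95, 0.97, 0.992, 1.0]),          # needs 4
                 np.array([0.8, 0.9, 0.95, 0.96, 0.97, 0.99, 1.0]),  # needs 6
                 np.array([0.9, 0.95, 0.97, 0.98, 0.991, 1.0])]    # needs 5
        assert choose_n_harmonics(fracs, 0.99) == 6

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            choose_n_harmonics(np.array([0.5, 1.0]), 0.0)


class TestMatrix:
    def test_shape_contract(self, five_templates):
        coefs = [eft_forward(resample_equidistant(t.base_outline, 360), 8)
                 for t in five_templates.values()] * 2
        m = coefficient_matrix(coefs, 8)
        assert m.shape == (10, 32)

    def test_identical_outlines_identical_rows(self, wavy_template):
        coef = eft_forward(resample_equidistant(wavy_template.base_outline, 360), 6)
        m = coefficient_matrix([coef] * 5, 6)
        assert np.abs(m - m[0]).max() < 1e-9

    def test_column_means_match_recomputation(self, five_templates):
        coefs = [eft_forward(resample_equidistant(t.base_outline, 360), 5)
                 for t in five_templates.values()]
        m = coefficient_matrix(coefs, 5)
        manual = np.mean([c.harmonics[:5].ravel() for c in coefs], axis=0)
        np.testing.assert_allclose(m.mean(axis=0), manual, atol=1e-12)

    def test_mixed_counts_rejected(self, wavy_template):
        poly = resample_equidistant(wavy_template.base_outline, 360)
        with pytest.raises(ValueError):
            coefficient_matrix([eft_forward(poly, 3)], 5)


class TestInvariances:
    def test_scale_invariance_after_normalization(self, wavy_template):
        poly = wavy_template.base_outline
        a = eft_forward(normalize_outline(resample_equidistant(poly, 360)), 6)
        scaled = poly.transformed(scale=7.3)
        b = eft_forward(normalize_outline(resample_equidistant(scaled, 360)), 6)
        np.testing.assert_allclose(a.harmonics, b.harmonics, atol=1e-9)

    def test_shift_start_preserves_geometry_and_power(self, wavy_template):
        poly = resample_equidistant(wavy_template.base_outline, 360)
        coef = eft_forward(poly, 10)
        shifted = shift_start(coef, 0.83)
        p0, _ = harmonic_power(coef)
        p1, _ = harmonic_power(shifted)
        np.testing.assert_allclose(p0, p1, rtol=1e-9)

    def test_normalize_phase_removes_start_dependence(self, wavy_template):
        poly = wavy_template.base_outline
        # two nearby starting vertices (same major-axis end is the nearest one)
        a = normalize_phase(eft_forward(resample_equidistant(poly, 360, start_vertex=0), 10))
        b = normalize_phase(eft_forward(resample_equidistant(poly, 360, start_vertex=40), 10))
        np.testing.assert_allclose(a.harmonics, b.harmonics, atol=1e-4)
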