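"""Cubic coupling regression: exact identities, OLS oracle, diagnostics."""

import dataclasses

import numpy as np
import pytest

from slidegait import synthetic as syn
from slidegait.errors import DataError
from slidegait.regression import fit_all, fit_cubic, fits_frame, residual_diagnostics


@pytest.fixture(scope="module")
def hip_angle(noiseless_right):
    return noiseless_right[1].noiseless["hip_flex_deg"].to_numpy()


def normal_equations_fit(angle, pressure):
    """Independent brute-force OLS on the standardized cubic design."""
    z = (angle - angle.mean()) / angle.std(ddof=1)
    zy = (pressure - pressure.mean()) / pressure.std(ddof=1)
    X = np.column_stack([np.ones_like(z), z, z**2, z**3])
    return np.linalg.solve(X.T @ X, X.T @ zy)


class TestFitCubic:
    def test_identity_relation(self, hip_angle):
        fit = fit_cubic(hip_angle, hip_angle * 3.0 + 7.0)  # affine in the angle
        assert fit.terms["X1"].b == pytest.approx(1.0, abs=1e-10)
        assert fit.terms["X2"].b == pytest.approx(0.0, abs=1e-10)
        assert fit.terms["X3"].b == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_relation(self, hip_angle):
        rng = np.random.default_rng(0)
        fit = fit_cubic(hip_angle, rng.normal(0, 1, len(hip_angle)))
        assert fit.r2 < 0.05

    def test_b_equals_beta_for_first_order_term(self, hip_angle):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.normal(0, 1, len(hip_angle)) + 0.5 * hip_angle
            fit = fit_cubic(hip_angle, y)
            assert fit.terms["X1"].b == fit.terms["X1"].beta
            assert fit.terms["X2"].b != fit.terms["X2"].beta

    def test_matches_normal_equations_oracle(self, hip_angle):
        rng = np.random.default_rng(4)
        y = 1.2 * hip_angle + rng.normal(0, 5, len(hip_angle))
        fit = fit_cubic(hip_angle, y)
        beta = normal_equations_fit(hip_angle, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, term in enumerate(("X1", "X2", "X3")):
            assert fit.terms[term].b == pytest.approx(beta[j + 1], abs=1e-8)

    def test_adjusted_r2_formula(self, hip_angle):
        rng = np.random.default_rng(6)
        y = hip_angle + rng.normal(0, 8, len(hip_angle))
        fit = fit_cubic(hip_angle, y)
        n = fit.n
        assert fit.adj_r2 == pytest.approx(1 - (1 - fit.r2) * (n - 1) / (n - 4), abs=1e-12)
        assert fit.adj_r2 <= fit.r2 <= 1.0
        assert fit.r == pytest.approx(np.sqrt(fit.r2))

    def test_r2_invariant_to_affine_rescaling(self, hip_angle):
        rng = np.random.default_rng(7)
        y = hip_angle**2 + rng.normal(0, 50, len(hip_angle))
        a = fit_cubic(hip_angle, y)
        b = fit_cubic(2.5 * hip_angle - 40.0, 0.1 * y + 3.0)
        assert a.r2 == pytest.approx(b.r2, rel=1e-9)

    def test_standardized_residual_conventions(self, hip_angle):
        rng = np.random.default_rng(8)
        fit = fit_cubic(hip_angle, hip_angle + rng.normal(0, 5, len(hip_angle)))
        n = fit.n
        assert abs(fit.residual_summary["mean"]) < 1e-8
        # residuals scaled by sqrt(RSS/(n-4)): population SD is sqrt((n-4)/n)
        assert fit.residual_summary["sd"] * np.sqrt(n / (n - 4)) == pytest.approx(1.0, abs=1e-6)

    def test_ci_width_shrinks_with_n(self, hip_angle):
        rng = np.random.default_rng(9)
        widths = []
        for n in (50, 200, 800):
            idx = np.linspace(0, len(hip_angle) - 1, n).astype(int)
            a = hip_angle[idx]
            y = a + rng.normal(0, 5, n)
            fit = fit_cubic(a, y)
            lo, hi = fit.terms["X1"].ci90
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_inputs(self, hip_angle):
        with pytest.raises(DataError):
            fit_cubic(np.ones(50), np.arange(50.0))
        with pytest.raises(DataError):
            fit_cubic(hip_angle[:5], hip_angle[:5])


class TestResidualDiagnostics:
    def test_exact_fit_is_degenerate(self, hip_angle):
        fit = fit_cubic(hip_angle, hip_angle)
        assert residual_diagnostics(fit).degenerate

    def test_gaussian_noise_passes_normality_mostly(self, hip_angle):
        rng = np.random.default_rng(10)
        passed = 0
        for _ in range(10):
            fit = fit_cubic(hip_angle, hip_angle + rng.normal(0, 5, len(hip_angle)))
            if residual_diagnostics(fit).shapiro_p > 0.05:
                passed += 1
        assert passed >= 7

    def test_reports_lag1_autocorrelation(self, hip_angle):
        rng = np.random.default_rng(11)
        fit = fit_cubic(hip_angle, hip_angle + rng.normal(0, 5, len(hip_angle)))
        d = residual_diagnostics(fit)
        assert -1.0 <= d.lag1_autocorr <= 1.0
        assert d.hist_counts.sum() == fit.n


class TestFitAll:
    def test_eight_fits_table_shape(self, noiseless_left, noiseless_right):
        recs = {"left": noiseless_left[0].data, "right": noiseless_right[0].data}
        fits = fit_all(recs)
        assert len(fits) == 8
        frame = fits_frame(fits)
        assert len(frame) == 24  # 8 fits x 3 term rows
        assert set(frame["side"]) == {"left", "right"}

    def test_symmetric_config_gives_matching_fits(self, noiseless_cfg):
        mirrored = dataclasses.replace(noiseless_cfg, right_profiles=noiseless_cfg.left_profiles)
        left, _ = syn.generate_cycle(mirrored, "left")
        right, _ = syn.generate_cycle(mirrored, "right")
        fits = fit_all({"left": left.data, "right": right.data})
        by = {(f.side, f.joint_name): f for f in fits}
        for joint in syn.ANGLE_CHANNELS:
            assert by[("left", joint)].r2 == pytest.approx(by[("right", joint)].r2, abs=1e-9)
            assert by[("left", joint)].terms["X1"].b == pytest.approx(
                by[("right", joint)].terms["X1"].b, abs=1e-9
            )

    def test_recovers_side_specific_coupling(self, noiseless_cfg):
        """Distinct generative coefficients per side are recovered by the
        respective fits (generator oracle)."""
        truths = {"left": (1.15, 0.33, 0.0), "right": (0.6, -0.4, 0.1)}
        recs = {}
        for side, coeffs in truths.items():
            cfg = dataclasses.replace(
                noiseless_cfg,
                coupling=syn.CouplingSpec("hip_flex_deg", coeffs, 0.2),
                seed=21,
            )
            rec, gt = syn.generate_cycle(cfg, side)
            recs[side] = (rec, gt)
        for side, (rec, gt) in recs.items():
            fit = fit_cubic(rec.channel("hip_flex_deg"), rec.pressure)
            sdy = rec.pressure.std(ddof=1)
            for j, term in enumerate(("X1", "X2", "X3")):
                lo, hi = fit.terms[term].ci90
                assert lo * sdy - 0.05 <= gt.coefficients[j] <= hi * sdy + 0.05
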