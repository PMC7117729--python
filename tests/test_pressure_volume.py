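import numpy as np
import pytest
from scipy import stats

from hydrophys import (
    OsmoticLine,
    PVDrydown,
    PVSimSpec,
    ValidationError,
    analyze_pv_curve,
    fit_osmotic_line,
    max_osmotic_potential,
    modulus_of_elasticity,
    relative_water_content,
    saturated_weight,
    simulate_pv,
    trim_oversaturated,
    turgor_loss_point,
)
from hydrophys.pressure_volume import MIN_PRE_INFLECTION, _window_start


def brute_force_window_start(curve, ws):
    """Oracle: exhaustively score every dry-anchored window on (RWD, 1/psi).

    Same candidate set as the greedy search (>= 3 points, at least
    MIN_PRE_INFLECTION points left on the wet side); max R^2 wins, ties to
    the widest window.
    """
    masses = np.asarray(curve.fresh_masses)
    psis = np.asarray(curve.psis)
    rwd = 1.0 - relative_water_content(masses, curve.dry_mass, ws)
    n = len(masses)
    best = (-np.inf, None)
    for start in range(MIN_PRE_INFLECTION, n - 2):
        if np.any(psis[start:] >= 0):
            continue
        r = stats.linregress(rwd[start:], 1.0 / psis[start:])
        r2 = r.rvalue**2
        if r2 > best[0] + 1e-12 or (abs(r2 - best[0]) <= 1e-12 and start < best[1]):
            best = (r2, start)
    return best[1]


class TestRelativeWaterContent:
    def test_saturation(self):
        assert relative_water_content(1.0, 0.5, 1.0) == 1.0

    def test_fully_dry(self):
        assert relative_water_content(0.5, 0.5, 1.0) == 0.0

    def test_formula_arithmetic(self):
        assert relative_water_content(0.95, 0.50, 1.00) == pytest.approx(0.90)

    def test_oversaturated_allowed(self):
        assert relative_water_content(1.05, 0.5, 1.0) > 1.0

    def test_ws_below_wd_rejected(self):
        with pytest.raises(ValidationError):
            relative_water_content(0.9, 1.0, 0.8)


class TestTrimOversaturated:
    @pytest.mark.parametrize("n_over", [0, 1, 2, 3])
    def test_generator_truth_recovered(self, n_over):
        curve = simulate_pv(
            PVSimSpec(pi0=-2.15, epsilon=30.58, psi_noise_sd=0.0,
                      n_oversaturated=n_over)
        )
        trimmed, count = trim_oversaturated(curve)
        assert count == n_over
        assert len(trimmed) == len(curve) - n_over

    def test_idempotent(self):
        curve = simulate_pv(
            PVSimSpec(pi0=-2.15, epsilon=30.58, psi_noise_sd=0.0,
                      n_oversaturated=2)
        )
        once, n1 = trim_oversaturated(curve)
        twice, n2 = trim_oversaturated(once)
        assert n1 == 2 and n2 == 0
        assert twice == once

    def test_noisy_curves_rarely_mistrimmed(self):
        spurious = sum(
            trim_oversaturated(
                simulate_pv(PVSimSpec(pi0=-2.15, epsilon=30.58,
                                      psi_noise_sd=0.05, seed=400 + i))
            )[1]
            for i in range(20)
        )
        assert spurious <= 4


class TestSaturatedWeight:
    def test_noise_free_recovery(self, clean_pv_curve):
        ws = saturated_weight(clean_pv_curve)
        assert ws == pytest.approx(1.0, rel=1e-3)

    def test_first_point_at_psi_zero_anchors_intercept(self, clean_pv_curve):
        # the generated curve starts at (Ws, 0), so Ws is essentially read off
        assert saturated_weight(clean_pv_curve) == pytest.approx(
            clean_pv_curve.fresh_masses[0], rel=1e-3
        )

    def test_affine_equivariance(self, clean_pv_curve):
        from dataclasses import replace

        shift = 0.25
        shifted = replace(
            clean_pv_curve,
            fresh_masses=tuple(m + shift for m in clean_pv_curve.fresh_masses),
            dry_mass=clean_pv_curve.dry_mass + shift,
        )
        assert saturated_weight(shifted) == pytest.approx(
            saturated_weight(clean_pv_curve) + shift, abs=1e-9
        )


class TestOsmoticLine:
    def test_noise_free_intercept_is_reciprocal_pi0(self, clean_pv_curve):
        # with the true Ws, tail points satisfy 1/psi = (1 - RWD)/pi0 exactly
        line = fit_osmotic_line(clean_pv_curve, ws=1.0)
        assert line.intercept == pytest.approx(1.0 / -2.15, abs=1e-6)
        assert line.slope == pytest.approx(-1.0 / -2.15, abs=1e-6)
        assert line.r_squared == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "pi0,eps", [(-2.15, 30.58), (-1.26, 15.14), (-3.0, 12.0), (-1.0, 28.0)]
    )
    def test_greedy_agrees_with_brute_force_on_clean_data(self, pi0, eps):
        curve = simulate_pv(PVSimSpec(pi0=pi0, epsilon=eps, psi_noise_sd=0.0))
        greedy = _window_start(
            np.asarray(curve.fresh_masses), np.asarray(curve.psis)
        )
        assert greedy == brute_force_window_start(curve, ws=1.0)

    def test_duplicate_tail_point_does_not_change_line(self, clean_pv_curve):
        line = fit_osmotic_line(clean_pv_curve, ws=1.0)
        masses = list(clean_pv_curve.fresh_masses)
        psis = list(clean_pv_curve.psis)
        # duplicate the driest point (offset mass by an epsilon to keep
        # strict monotonicity; psi identical)
        masses.append(masses[-1] - 1e-9)
        psis.append(psis[-1])
        dup = PVDrydown(
            leaf_id="dup", species=clean_pv_curve.species,
            fresh_masses=tuple(masses), psis=tuple(psis),
            dry_mass=clean_pv_curve.dry_mass,
        )
        line2 = fit_osmotic_line(dup, ws=1.0)
        assert line2.slope == pytest.approx(line.slope, abs=1e-6)
        assert line2.intercept == pytest.approx(line.intercept, abs=1e-6)

    def test_window_excludes_turgid_points(self, clean_pv_curve):
        line = fit_osmotic_line(clean_pv_curve, ws=1.0)
        psis = np.asarray(clean_pv_curve.psis)[line.window_start:]
        rwc = relative_water_content(
            np.asarray(clean_pv_curve.fresh_masses)[line.window_start:],
            clean_pv_curve.dry_mass, 1.0,
        )
        turgor = psis - (-2.15) / rwc
        assert np.all(turgor <= 0.02)


class TestMaxOsmoticPotential:
    def test_reciprocal(self):
        line = OsmoticLine(slope=0.5, intercept=-0.5, n_points=5,
                           r_squared=1.0, window_start=8)
        assert max_osmotic_potential(line) == pytest.approx(-2.0)

    def test_recovery_at_reference_pi0_with_noise(self):
        # truth set to the reference full-turgor osmotic potential
        estimates = []
        for i in range(20):
            curve = simulate_pv(
                PVSimSpec(pi0=-2.15, epsilon=30.58, psi_noise_sd=0.05,
                          seed=600 + i)
            )
            estimates.append(analyze_pv_curve(curve).pi0)
        assert abs(np.median(estimates) - (-2.15)) < 0.1

    def test_noise_free_bias_over_replicates(self):
        # replicates differ only by seed, which is inert at zero noise; the
        # residual bias is pure model curvature and must stay tiny
        estimates = [
            analyze_pv_curve(
                simulate_pv(PVSimSpec(pi0=-2.15, epsilon=30.58,
                                      psi_noise_sd=0.0, seed=i))
            ).pi0
            for i in range(10)
        ]
        assert abs(np.mean(estimates) - (-2.15)) < 0.02

    def test_non_negative_intercept_rejected(self):
        line = OsmoticLine(slope=0.5, intercept=0.1, n_points=5,
                           r_squared=1.0, window_start=8)
        with pytest.raises(ValidationError):
            max_osmotic_potential(line)


class TestTurgorLossPoint:
    def test_noise_free_closed_form(self, clean_pv_curve):
        params = analyze_pv_curve(clean_pv_curve)
        assert params.tlp == pytest.approx(-2.313, rel=0.01)
        assert params.rwc_tlp == pytest.approx(0.9297, rel=0.01)

    def test_recovery_at_reference_tlp_with_noise(self):
        # pi0 solved so the closed-form TLP equals the reference value
        eps = 30.58
        tlp_target = -2.58
        pi0 = tlp_target * eps / (eps - tlp_target)
        estimates = []
        for i in range(20):
            curve = simulate_pv(
                PVSimSpec(pi0=pi0, epsilon=eps, psi_noise_sd=0.05, seed=700 + i)
            )
            estimates.append(analyze_pv_curve(curve).tlp)
        assert abs(np.median(estimates) - tlp_target) < 0.15

    def test_tlp_not_above_pi0(self):
        for i in range(10):
            curve = simulate_pv(
                PVSimSpec(pi0=-1.8, epsilon=22.0, psi_noise_sd=0.05, seed=i)
            )
            params = analyze_pv_curve(curve)
            assert params.tlp <= params.pi0

    def test_never_crossing_errors(self, clean_pv_curve):
        # a line predicting far more negative osmotic potential than any
        # observation keeps computed turgor positive everywhere
        line = OsmoticLine(slope=0.0, intercept=-0.05, n_points=3,
                           r_squared=1.0, window_start=10)
        with pytest.raises(ValidationError, match="never crosses"):
            turgor_loss_point(clean_pv_curve, 1.0, line)


class TestModulusOfElasticity:
    @pytest.mark.parametrize("eps", [30.58, 15.14])
    def test_noise_free_recovery(self, eps):
        pi0 = -2.15 if eps > 20 else -1.26
        curve = simulate_pv(PVSimSpec(pi0=pi0, epsilon=eps, psi_noise_sd=0.0))
        params = analyze_pv_curve(curve)
        assert params.epsilon == pytest.approx(eps, rel=0.02)

    def test_doubling_epsilon_doubles_estimate(self):
        est = []
        for eps in (14.0, 28.0):
            curve = simulate_pv(PVSimSpec(pi0=-1.8, epsilon=eps, psi_noise_sd=0.0))
            est.append(analyze_pv_curve(curve).epsilon)
        assert est[1] / est[0] == pytest.approx(2.0, rel=0.02)

    def test_too_few_turgid_points_errors(self, clean_pv_curve):
        line = fit_osmotic_line(clean_pv_curve, 1.0)
        with pytest.raises(ValidationError, match="turgid"):
            modulus_of_elasticity(clean_pv_curve, 1.0, line, rwc_tlp=1.5)


class TestPipeline:
    def test_full_recovery_grid(self):
        # median |TLP error| < 0.1 MPa across the plausible parameter box
        for pi0 in (-3.0, -2.0, -1.0):
            for eps in (10.0, 22.0, 35.0):
                errors = []
                for i in range(15):
                    curve = simulate_pv(
                        PVSimSpec(pi0=pi0, epsilon=eps, psi_noise_sd=0.05,
                                  seed=2000 + i)
                    )
                    params = analyze_pv_curve(curve)
                    errors.append(abs(params.tlp - curve.truth.tlp))
                assert np.median(errors) < 0.1, (pi0, eps)

    def test_rwc_tlp_range_and_closed_form(self):
        for pi0 in (-2.5, -1.5):
            for eps in (18.0, 32.0):
                curve = simulate_pv(PVSimSpec(pi0=pi0, epsilon=eps,
                                              psi_noise_sd=0.0))
                params = analyze_pv_curve(curve)
                closed = 1.0 + pi0 / eps
                assert 0.85 < params.rwc_tlp < 0.99
                assert params.rwc_tlp == pytest.approx(closed, rel=0.005)

    def test_validation_needs_eight_points(self):
        with pytest.raises(ValidationError, match="points"):
            PVDrydown("l", "x", (1.0, 0.9, 0.8), (-0.1, -0.5, -1.0), 0.5)
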