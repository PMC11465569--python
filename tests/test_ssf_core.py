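"""Movement-kernel MLEs, random steps, covariates, and the conditional logit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from temposelect.ssf_core import (
    DegenerateSampleError,
    GammaParams,
    VonMisesParams,
    clogit_fit,
    clogit_loglik,
    draw_random_step,
    draw_random_steps,
    extract_covariates,
    fit_from_differences,
    fit_gamma,
    fit_vonmises,
    standardize_distances,
)


def pairs_from_values(obs, rand):
    """Long pairs table for one covariate named x."""
    n = len(obs)
    return pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n), 2),
            "case": np.tile([1, 0], n),
            "x": np.column_stack([obs, rand]).ravel(),
        }
    )


class TestGammaFit:
    def test_mle_identity_shape_times_scale_is_mean(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(3.0, 50.0, size=500)
        params, _ = fit_gamma(x)
        assert params.mean == pytest.approx(x.mean(), rel=1e-8)

    def test_recovers_truth_at_large_n(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(2.0, 150.0, size=20_000)
        params, _ = fit_gamma(x)
        assert params.shape == pytest.approx(2.0, rel=0.05)
        assert params.scale == pytest.approx(150.0, rel=0.05)

    def test_matches_scipy_mle(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.gamma(1.7, 90.0, size=2_000)
        params, _ = fit_gamma(x)
        shape_ref, _, scale_ref = stats.gamma.fit(x, floc=0)
        assert params.shape == pytest.approx(shape_ref, rel=1e-3)
        assert params.scale == pytest.approx(scale_ref, rel=1e-3)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            fit_gamma(np.ones(20))

    def test_zeros_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.gamma(2.0, 10.0, size=50), np.zeros(5)])
        _, n_zero = fit_gamma(x)
        assert n_zero == 5


class TestVonMisesFit:
    def test_uniform_angles_give_zero_kappa(self):
        angles = np.linspace(-np.pi, np.pi, 24, endpoint=False)
        params = fit_vonmises(angles)
        assert params.kappa == pytest.approx(0.0, abs=1e-6)

    def test_identical_angles_hit_kappa_cap(self):
        params = fit_vonmises(np.full(20, 0.7), kappa_max=1e6)
        assert params.kappa == 1e6
        assert params.mu == pytest.approx(0.7)

    def test_recovers_truth_at_large_n(self):
        rng = np.random.default_rng(42)
        a = rng.vonmises(0.0, 2.0, size=20_000)
        params = fit_vonmises(a)
        assert params.kappa == pytest.approx(2.0, rel=0.05)
        assert abs(params.mu) < 0.05

    def test_empty_input_raises(self):
        with pytest.raises(DegenerateSampleError):
            fit_vonmises([])


class TestRandomSteps:
    def test_concentrated_kernel_follows_previous_bearing(self):
        gamma = GammaParams(2.0, 100.0)
        vm = VonMisesParams(0.0, 1e6)
        rng = np.random.default_rng(0)
        x, y, _ = draw_random_step(0.0, 0.0, 0.3, gamma, vm, rng)
        assert np.arctan2(y, x) == pytest.approx(0.3, abs=1e-2)

    def test_deterministic_given_rng_state(self):
        gamma = GammaParams(2.0, 100.0)
        vm = VonMisesParams(0.0, 1.0)
        a = draw_random_step(0, 0, 0.0, gamma, vm, np.random.default_rng(5))
        b = draw_random_step(0, 0, 0.0, gamma, vm, np.random.default_rng(5))
        assert a == b

    def test_mean_length_matches_kernel(self):
        gamma = GammaParams(2.0, 150.0)
        vm = VonMisesParams(0.0, 1.0)
        n = 100_000
        steps = pd.DataFrame(
            {
                "stratum_id": np.arange(n),
                "t_end": pd.Timestamp("2016-01-01", tz="UTC"),
                "x_start": 0.0,
                "y_start": 0.0,
                "prev_bearing": 0.0,
                "turn": 0.0,
            }
        )
        out = draw_random_steps(steps, gamma, vm, np.random.default_rng(8))
        lengths = np.hypot(out["x_rand"], out["y_rand"])
        se = gamma.scale * np.sqrt(gamma.shape / n)
        assert abs(lengths.mean() - gamma.mean) < 3 * se

    def test_landscape_bounds_respected(self, landscape):
        gamma = GammaParams(2.0, 400.0)
        vm = VonMisesParams(0.0, 0.5)
        n = 2_000
        steps = pd.DataFrame(
            {
                "stratum_id": np.arange(n),
                "t_end": pd.Timestamp("2016-01-01", tz="UTC"),
                "x_start": 30.0,  # near the western edge
                "y_start": 500.0,
                "prev_bearing": np.pi,  # pointing out of the landscape
                "turn": 0.0,
            }
        )
        out = draw_random_steps(steps, gamma, vm, np.random.default_rng(2), landscape)
        inside = landscape.in_bounds(out["x_rand"], out["y_rand"])
        assert (inside | out["oob_flag"]).all()
        assert inside.mean() > 0.95


class TestCovariates:
    def test_dummy_coding_matches_habitat_class(self, landscape):
        from temposelect.synthetic_data import HABITAT_CLASSES, MODELED_HABITATS

        cs = landscape.cell_size
        xs = landscape.origin_x + cs * (np.arange(50) + 0.5)
        ys = landscape.origin_y + cs * (np.arange(50) + 0.5)
        cov = extract_covariates(xs, ys, landscape)
        codes = landscape.habitat_grid[np.arange(50), np.arange(50)]
        for name in MODELED_HABITATS:
            expected = (codes == HABITAT_CLASSES.index(name)).astype(int)
            assert np.array_equal(cov[name].to_numpy(), expected)

    def test_distance_zero_on_road_cell(self, landscape):
        r, c = np.argwhere(landscape.dist_road_grid == 0.0)[0]
        cs = landscape.cell_size
        x = landscape.origin_x + (c + 0.5) * cs
        y = landscape.origin_y + (r + 0.5) * cs
        cov = extract_covariates(x, y, landscape)
        assert cov["dist_road"].iloc[0] == 0.0

    def test_edge_point_uses_half_open_rule(self, landscape):
        # a point exactly on the shared edge of cells (2,4)/(2,5) belongs to
        # column 5; brute-force containment under [edge, edge+cs)
        cs = landscape.cell_size
        x = landscape.origin_x + 5 * cs
        y = landscape.origin_y + 2.5 * cs
        cov = extract_covariates(x, y, landscape)
        expected = landscape.habitat_grid[2, 5]
        from temposelect.synthetic_data import HABITAT_CLASSES, MODELED_HABITATS

        name = HABITAT_CLASSES[expected]
        if name in MODELED_HABITATS:
            assert cov[name].iloc[0] == 1

    def test_outside_point_raises(self, landscape):
        with pytest.raises(ValueError):
            extract_covariates(-10.0, 5.0, landscape)


class TestStandardizeDistances:
    def test_sample_sd_convention(self):
        pairs = pairs_from_values([0.0, 20.0], [10.0, 10.0]).rename(
            columns={"x": "dist_road"}
        )
        pairs["dist_settlement"] = [1.0, 2.0, 3.0, 4.0]
        out = standardize_distances(pairs)
        # raw {0, 10, 20, 10}: the 0 and 20 map symmetrically
        z = out["dist_road_z"].to_numpy()
        assert z[0] == pytest.approx(-z[2])
        assert out["dist_road_z"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["dist_road_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_three_values(self):
        pairs = pd.DataFrame(
            {
                "stratum_id": [0, 0, 1],
                "case": [1, 0, 1],
                "dist_road": [0.0, 10.0, 20.0],
                "dist_settlement": [1.0, 2.0, 3.0],
            }
        )
        out = standardize_distances(pairs)
        assert out["dist_road_z"].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_raises(self):
        pairs = pd.DataFrame(
            {"dist_road": [5.0, 5.0], "dist_settlement": [1.0, 2.0]}
        )
        with pytest.raises(DegenerateSampleError):
            standardize_distances(pairs)


class TestClogit:
    def test_binary_closed_form(self):
        # 6 discordant pairs with obs exposed, 3 the other way, 5 concordant
        obs = [1] * 6 + [0] * 3 + [1] * 3 + [0] * 2
        rand = [0] * 6 + [1] * 3 + [1] * 3 + [0] * 2
        fit = clogit_fit(pairs_from_values(obs, rand), "x")
        assert fit.beta == pytest.approx(np.log(6 / 3), abs=1e-6)
        assert fit.n_pairs == 14
        assert fit.n_informative == 9

    def test_symmetric_discordance_gives_zero(self):
        fit = clogit_fit(pairs_from_values([1, 0], [0, 1]), "x")
        assert fit.beta == pytest.approx(0.0, abs=1e-8)

    def test_all_concordant_is_non_estimable(self):
        fit = clogit_fit(pairs_from_values([1, 0, 1], [1, 0, 1]), "x")
        assert not fit.estimable
        assert np.isnan(fit.beta)

    def test_complete_separation_flagged_and_capped(self):
        fit = clogit_fit(pairs_from_values([1, 1, 1], [0, 0, 0]), "x")
        assert fit.separation
        assert fit.beta == 10.0
        assert not fit.usable

    def test_continuous_matches_golden_section(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, size=60)
            fit = fit_from_differences(d)
            ref = optimize.minimize_scalar(
                lambda b: -clogit_loglik(b, d),
                bracket=(-10.0, 0.0, 10.0),
                method="golden",
                options={"xtol": 1e-10},
            ).x
            assert fit.beta == pytest.approx(ref, abs=1e-4)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(12)
        obs = rng.normal(0.5, 1.0, size=200)
        rand = rng.normal(0.0, 1.0, size=200)
        pairs = pairs_from_values(obs, rand)
        fit = clogit_fit(pairs, "x")
        ref = ConditionalLogit(
            pairs["case"], pairs[["x"]], groups=pairs["stratum_id"]
        ).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params.iloc[0], abs=1e-5)
        assert fit.se == pytest.approx(ref.bse.iloc[0], rel=1e-3)

    @given(st.floats(-100, 100))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_likelihood_invariant_to_shared_covariate_shift(self, shift):
        obs = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        rand = np.array([0.0, 2.5, 1.0, 1.0, 1.5])
        base = clogit_fit(pairs_from_values(obs, rand), "x")
        shifted = clogit_fit(pairs_from_values(obs + shift, rand + shift), "x")
        assert shifted.beta == pytest.approx(base.beta, abs=1e-8)

    def test_estimator_consistency_under_choice_kernel(self):
        # pairs simulated from the matched choice model with known beta
        beta_true = 0.8
        rng = np.random.default_rng(99)
        n = 5_000
        xa = rng.normal(size=n)
        xb = rng.normal(size=n)
        p_a = 1.0 / (1.0 + np.exp(-beta_true * (xa - xb)))
        a_is_obs = rng.random(n) < p_a
        obs = np.where(a_is_obs, xa, xb)
        rand = np.where(a_is_obs, xb, xa)
        fit = clogit_fit(pairs_from_values(obs, rand), "x")
        assert abs(fit.beta - beta_true) < 3 * fit.se
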