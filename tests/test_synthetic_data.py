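"""Landscape generator, harmonic truth surfaces, and the movement simulator."""

import numpy as np
import pandas as pd
import pytest

from temposelect.synthetic_data import (
    HABITAT_CLASSES,
    HarmonicBeta,
    InvalidConfigError,
    Landscape,
    SimConfig,
    TrueBetaSpec,
    make_landscape,
    make_synthetic_pairs,
    simulate_tracks,
    true_beta,
)


class TestLandscape:
    def test_all_classes_present(self, landscape):
        assert len(np.unique(landscape.habitat_grid)) >= 7

    def test_distance_grids_touch_zero_and_are_nonnegative(self, landscape):
        for grid in (landscape.dist_road_grid, landscape.dist_settlement_grid):
            assert grid.min() == 0.0
            assert (grid >= 0).all()

    def test_deterministic_given_seed(self):
        a = make_landscape(seed=3, n_rows=60, n_cols=60)
        b = make_landscape(seed=3, n_rows=60, n_cols=60)
        assert np.array_equal(a.habitat_grid, b.habitat_grid)
        assert np.array_equal(a.dist_road_grid, b.dist_road_grid)

    def test_too_small_raises(self):
        with pytest.raises(InvalidConfigError):
            make_landscape(seed=1, n_rows=20, n_cols=20)

    def test_half_open_cell_convention(self, landscape):
        # a point exactly on an interior shared edge belongs to the
        # higher-index cell; brute-force check of both candidate cells
        cs = landscape.cell_size
        x_edge = landscape.origin_x + 5 * cs
        y_mid = landscape.origin_y + 2.5 * cs
        row, col = landscape.cell_index(x_edge, y_mid)
        assert col == 5 and row == 2
        assert x_edge - (landscape.origin_x + col * cs) < cs  # inside [edge, edge+cs)

    def test_ascii_round_trip(self, landscape, tmp_path):
        path = tmp_path / "land.txt"
        landscape.write_ascii(path)
        back = Landscape.read_ascii(path)
        assert np.array_equal(back.habitat_grid, landscape.habitat_grid)
        assert np.allclose(back.dist_road_grid, landscape.dist_road_grid)
        assert back.cell_size == landscape.cell_size


class TestTrueBeta:
    def test_constant_surface(self):
        spec = TrueBetaSpec({"wetland": HarmonicBeta(a0=0.5)})
        for day, hour in [(1, 0), (180, 12), (365, 23.5)]:
            assert true_beta(spec, "wetland", day, hour) == pytest.approx(0.5)

    def test_diel_harmonic_extremes(self):
        spec = TrueBetaSpec({"arable": HarmonicBeta(a_hour=1.0, phi_hour=0.0)})
        assert true_beta(spec, "arable", 100, 0) == pytest.approx(1.0)
        assert true_beta(spec, "arable", 100, 12) == pytest.approx(-1.0)

    def test_grid_mean_equals_a0_with_interaction(self):
        # brute-force average of all harmonic terms over one full period is 0
        spec = TrueBetaSpec(
            {"grassland": HarmonicBeta(a0=0.7, a_hour=0.9, a_year=0.4, a_int=1.3)}
        )
        surf = spec.surface("grassland")
        assert surf.shape == (365, 24)
        assert surf.mean() == pytest.approx(0.7, abs=1e-6)

    def test_unknown_covariate_raises(self):
        spec = TrueBetaSpec({})
        with pytest.raises(KeyError):
            true_beta(spec, "lava_field", 1, 0)

    def test_domain_validation(self):
        spec = TrueBetaSpec({})
        with pytest.raises(ValueError):
            true_beta(spec, "wetland", 0, 5)
        with pytest.raises(ValueError):
            true_beta(spec, "wetland", 10, 24.0)


class TestSimulateTracks:
    def test_deterministic_given_seed(self, landscape):
        spec = TrueBetaSpec({"deciduous_forest": HarmonicBeta(a0=1.0)})
        cfg = SimConfig(n_individuals=2, end="2016-01-05T00:00:00", seed=9)
        a = simulate_tracks(landscape, cfg, spec)
        b = simulate_tracks(landscape, cfg, spec)
        assert a.equals(b)

    def test_neutral_choice_matches_availability(self, landscape):
        # with beta == 0 the chosen endpoint is a uniform pick among the
        # candidates, so chosen class shares match pooled candidate shares
        # (the availability under the movement kernel) within 3 SE
        cfg = SimConfig(n_individuals=7, seed=21)
        _, cand, chosen = simulate_tracks(
            landscape, cfg, TrueBetaSpec({}), collect_stats=True
        )
        n_steps = chosen.sum()
        assert n_steps >= 50_000
        avail = cand / cand.sum()
        share = chosen / n_steps
        se = np.sqrt(avail * (1 - avail) / n_steps)
        assert (np.abs(share - avail) <= 3 * se + 1e-12).all()

    def test_positive_selection_enriches_habitat(self, landscape):
        spec = TrueBetaSpec({"deciduous_forest": HarmonicBeta(a0=2.0)})
        cfg = SimConfig(n_individuals=3, end="2016-03-01T00:00:00", seed=4)
        _, cand, chosen = simulate_tracks(landscape, cfg, spec, collect_stats=True)
        code = HABITAT_CLASSES.index("deciduous_forest")
        assert chosen[code] / chosen.sum() > cand[code] / cand.sum()

    def test_endpoints_stay_inside_landscape(self, landscape):
        cfg = SimConfig(n_individuals=2, end="2016-02-01T00:00:00", seed=1)
        tracks = simulate_tracks(landscape, cfg, TrueBetaSpec({}))
        assert landscape.in_bounds(tracks["x"], tracks["y"]).all()

    def test_start_outside_raises(self, landscape):
        cfg = SimConfig(n_individuals=1, seed=1)
        with pytest.raises(InvalidConfigError):
            simulate_tracks(
                landscape, cfg, TrueBetaSpec({}), start_xy=[(-50.0, -50.0)]
            )

    def test_config_validation(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(gamma_shape=-1.0)
        with pytest.raises(InvalidConfigError):
            SimConfig(n_candidates=1)


class TestSyntheticPairs:
    def test_covers_all_cells_with_exact_counts(self, small_pairs):
        assert len(small_pairs) == 26 * 24 * 40 * 2
        per_stratum = small_pairs.groupby("stratum_id")["case"].agg(["size", "sum"])
        assert (per_stratum["size"] == 2).all()
        assert (per_stratum["sum"] == 1).all()

    def test_deterministic(self, harmonic_spec):
        a = make_synthetic_pairs(1, harmonic_spec, n_pairs_per_cell=5)
        b = make_synthetic_pairs(1, harmonic_spec, n_pairs_per_cell=5)
        assert a.equals(b)

    def test_exactly_one_habitat_dummy_per_row(self, small_pairs):
        dummies = small_pairs[
            ["deciduous_forest", "coniferous_forest", "wetland", "grassland", "arable"]
        ]
        assert dummies.sum(axis=1).isin([0, 1]).all()
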