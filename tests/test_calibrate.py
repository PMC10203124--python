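import numpy as np
import pytest

import gridheat as gh
from gridheat import (
    CensoredValue,
    GridSpec,
    HoleyFilmPattern,
    MissingDataError,
    ParameterError,
    ThermalParams,
    comparison_report,
    fit_alpha,
    predict_threshold,
    rank_grids,
    scaling_law_check,
)


class TestFitAlpha:
    def test_single_row_inversion_is_exact(self, catalogue, thermal):
        row = catalogue[catalogue.grid_id == "cf312_300cu"]
        calib = fit_alpha(row, thermal)
        spec = gh.spec_from_row(row.iloc[0])
        assert predict_threshold(spec, calib) == pytest.approx(64.0, rel=1e-12)

    def test_noiseless_synthetic_data_recovers_alpha_exactly(self):
        study = gh.default_study(seed=7, noise_cv=0.0)
        data = gh.simulate_threshold_dataset(study)
        calib = fit_alpha(data, study.thermal)
        for material, alpha in study.true_alpha.items():
            assert calib.materials[material].alpha == pytest.approx(alpha, rel=1e-10)

    def test_unreachable_materials_give_alpha_upper_bound_only(self, calibration, thermal):
        # formvar thresholds exceed the 690 W/cm² instrument ceiling
        fit = calibration.materials["formvar"]
        assert fit.alpha is None and fit.n_uncensored == 0
        expected = 8 * (thermal.Tmax - thermal.T0) / (690.0 * 1.0 * 90.0**2)
        assert fit.alpha_upper_bound == pytest.approx(expected, rel=1e-12)

    def test_censored_rows_never_enter_the_point_fit(self, catalogue, thermal):
        # dropping the "< 50" ultrathin-carbon row must not change the CFlat α
        without = catalogue[catalogue.grid_id != "cf200cu_ul"]
        a_with = fit_alpha(catalogue, thermal).materials["carbon_cflat"].alpha
        a_without = fit_alpha(without, thermal).materials["carbon_cflat"].alpha
        assert a_with == a_without

    def test_censored_rows_checked_for_consistency(self, calibration):
        assert calibration.materials["carbon_cflat"].censored_consistent["cf200cu_ul"] is True

    def test_duplicated_catalogue_rows_do_not_double_count(self, catalogue, thermal):
        deduped = catalogue.drop_duplicates(subset="grid_id")
        a1 = fit_alpha(catalogue, thermal).materials["carbon_quantifoil"].alpha
        a2 = fit_alpha(deduped, thermal).materials["carbon_quantifoil"].alpha
        assert a1 == a2

    def test_residuals_reproduce_measurements(self, catalogue, thermal, calibration):
        fit = calibration.materials["carbon_cflat"]
        deduped = catalogue.drop_duplicates(subset="grid_id").set_index("grid_id")
        for grid_id, log_res in fit.log_residuals.items():
            row = deduped.loc[grid_id]
            pred = gh.max_power_density(
                fit.alpha, float(row["square_size_um"]), thermal.T0, thermal.Tmax,
                gh.carbon_area_fraction(
                    HoleyFilmPattern(float(row["hole_diameter_um"]), float(row["hole_spacing_um"]))
                    if not np.isnan(row["hole_diameter_um"])
                    else HoleyFilmPattern.continuous()
                ),
            )
            assert pred * np.exp(log_res) == pytest.approx(
                float(row["measured_pmax_W_cm2"]), rel=1e-10
            )


class TestScalingLawCheck:
    def test_identical_pairs_give_zero(self):
        assert scaling_law_check((0.65, 64.0), (0.65, 64.0)) == 0.0

    def test_symmetric_in_arguments(self):
        a = scaling_law_check((0.651, 64.0), (0.819, 50.0))
        b = scaling_law_check((0.819, 50.0), (0.651, 64.0))
        assert a == b

    def test_cflat_pair_within_two_percent(self, catalogue):
        eta_21 = gh.carbon_area_fraction(HoleyFilmPattern(2, 1))
        eta_1213 = gh.carbon_area_fraction(HoleyFilmPattern(1.2, 1.3))
        diff = scaling_law_check((eta_21, 64.0), (eta_1213, 50.0))
        assert diff == pytest.approx(1.70, abs=0.01)

    def test_quantifoil_pair_about_three_percent(self):
        eta_21 = gh.carbon_area_fraction(HoleyFilmPattern(2, 1))
        eta_14 = gh.carbon_area_fraction(HoleyFilmPattern(1, 4))
        diff = scaling_law_check((eta_21, 23.0), (eta_14, 16.0))
        assert diff == pytest.approx(3.39, abs=0.01)

    def test_censored_threshold_rejected(self):
        with pytest.raises(ParameterError):
            scaling_law_check((0.65, CensoredValue(690.0, "lower")), (0.8, 50.0))


class TestComparisonReport:
    def test_manufacturing_ratio_rounds_to_53_percent(self, catalogue):
        rep = comparison_report(catalogue)
        assert rep["manufacturing"]["ratio_pct_rounded"] == 53

    def test_bar_metals_are_equivalent_heat_sinks(self, catalogue):
        assert comparison_report(catalogue)["bar_metal"]["ratio"] == pytest.approx(1.0)

    def test_mesh_series_model_adequacy_deviation(self, catalogue):
        rep = comparison_report(catalogue)
        pair_300_400 = rep["mesh_series"]["pairs"][1]
        assert pair_300_400["measured_ratio"] == pytest.approx(96 / 64)
        assert pair_300_400["model_ratio_L2"] == pytest.approx((58 / 37) ** 2)
        assert pair_300_400["deviation_pct"] == pytest.approx(39.0, abs=0.1)

    def test_film_geometry_products_reported_for_both_pairs(self, catalogue):
        pairs = comparison_report(catalogue)["film_geometry"]
        assert {p["material"] for p in pairs} == {"carbon_cflat", "carbon_quantifoil"}

    def test_missing_row_raises_named_error(self, catalogue):
        broken = catalogue[catalogue.grid_id != "cf412_400cu"]
        with pytest.raises(MissingDataError, match="400"):
            comparison_report(broken)


class TestPredictThreshold:
    def test_bar_metal_does_not_enter_the_model(self, catalogue, thermal):
        # calibrate on the copper-bar grid, predict the identical film on gold
        calib = fit_alpha(catalogue[catalogue.grid_id == "cf313_300cu"], thermal)
        gold = GridSpec("au", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300,
                        bar_metal="gold")
        copper = GridSpec("cu", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300,
                          bar_metal="copper")
        assert predict_threshold(gold, calib) == pytest.approx(50.0, rel=1e-12)
        assert predict_threshold(gold, calib) == predict_threshold(copper, calib)

    def test_mesh_change_scales_by_inverse_square_size(self, catalogue, thermal):
        calib = fit_alpha(catalogue[catalogue.grid_id == "cf313_300cu"], thermal)
        p300 = predict_threshold(
            GridSpec("a", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300), calib
        )
        p400 = predict_threshold(
            GridSpec("b", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=400), calib
        )
        assert p400 / p300 == pytest.approx((58 / 37) ** 2, rel=1e-12)

    def test_censored_material_propagates_to_lower_bound(self, calibration):
        spec = GridSpec("sf", "silicon_monoxide", HoleyFilmPattern.continuous(), mesh=200)
        pred = predict_threshold(spec, calibration)
        assert isinstance(pred, CensoredValue) and pred.kind == "lower"
        assert pred.bound == pytest.approx(690.0, rel=1e-12)

    def test_unknown_material_error_lists_calibrated_ones(self, calibration):
        spec = GridSpec("x", "graphene", HoleyFilmPattern.continuous(), mesh=200)
        with pytest.raises(MissingDataError, match="carbon_cflat"):
            predict_threshold(spec, calibration)


class TestRankGrids:
    def test_gold_film_ranks_above_carbon_at_equal_geometry(self, calibration):
        specs = [
            GridSpec("au_film", "gold_film", HoleyFilmPattern(1.2, 1.3), mesh=300),
            GridSpec("cf", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300),
            GridSpec("qf", "carbon_quantifoil", HoleyFilmPattern(1.2, 1.3), mesh=300),
        ]
        ranking = rank_grids(specs, calibration, required_P=10.0)
        assert ranking.iloc[0]["grid_id"] == "au_film"

    def test_empty_catalogue_gives_empty_ranking(self, calibration):
        assert rank_grids([], calibration, 10.0).empty

    def test_tie_break_is_deterministic(self, calibration):
        a = GridSpec("b_grid", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300)
        b = GridSpec("a_grid", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300)
        r1 = rank_grids([a, b], calibration, 1.0)
        r2 = rank_grids([b, a], calibration, 1.0)
        assert list(r1.grid_id) == list(r2.grid_id) == ["a_grid", "b_grid"]

    def test_usable_flag_applies_seventy_percent_rule(self, calibration, thermal):
        spec = GridSpec("cf", "carbon_cflat", HoleyFilmPattern(1.2, 1.3), mesh=300)
        pred = predict_threshold(spec, calibration, thermal)
        ranking = rank_grids([spec], calibration, required_P=0.71 * pred)
        assert not ranking.iloc[0]["usable"]
        ranking = rank_grids([spec], calibration, required_P=0.69 * pred)
        assert ranking.iloc[0]["usable"]
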