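"""Synthetic-data generators: determinism, closure, truth round trips."""
import numpy as np
import pandas as pd
import pytest

from landsink import SyntheticConfig, TransportParams, generate_all, invert_two_box
from landsink.synth import (
    gen_biomass_maps,
    gen_budget_series,
    gen_cmip_ensemble,
    gen_hemispheric_split,
    gen_o2_records,
    gen_station_records,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="span"):
            SyntheticConfig(years=(2000, 2000))
        with pytest.raises(ValueError, match="noise"):
            SyntheticConfig(noise_sd={"fossil": -1, "growth": 0, "ocean": 0, "land": 0})
        with pytest.raises(ValueError, match="model"):
            SyntheticConfig(n_models=0)
        with pytest.raises(ValueError, match="grid"):
            SyntheticConfig(grid_shape=(0, 10))

    def test_child_seeds_are_distinct_and_deterministic(self):
        config = SyntheticConfig(seed=13)
        a = config.child_seed("budget").generate_state(1)[0]
        b = config.child_seed("station").generate_state(1)[0]
        assert a != b
        assert a == SyntheticConfig(seed=13).child_seed("budget").generate_state(1)[0]


class TestBudget:
    def test_closure_holds_exactly_for_any_seed(self):
        for seed in (0, 1, 99):
            budget, _ = gen_budget_series(SyntheticConfig(seed=seed))
            s = budget.series
            residual = s["fossil"] - s["growth"] - s["ocean"] - s["land"]
            assert np.abs(residual).max() < 1e-12

    def test_noise_free_flat_configuration_gives_constant_series(self):
        config = SyntheticConfig(
            ff_growth=0.0,
            ff_start=8.0,
            noise_sd={"fossil": 0.0, "growth": 0.0, "ocean": 0.0, "land": 0.0},
        )
        budget, _ = gen_budget_series(config)
        assert np.allclose(budget.series["fossil"], 8.0)
        assert np.allclose(budget.series["ocean"], 8.0 * config.ocean_fraction_of_ff)
        assert np.allclose(budget.series["land"], 1.6)

    def test_same_seed_reproduces_identical_tables(self):
        a, _ = gen_budget_series(SyntheticConfig(seed=21))
        b, _ = gen_budget_series(SyntheticConfig(seed=21))
        pd.testing.assert_frame_equal(a.series, b.series)

    def test_land_truth_equals_stored_land_term(self):
        budget, truth = gen_budget_series(SyntheticConfig(seed=3))
        combined = truth.land_north + truth.land_south
        assert np.allclose(budget.series["land"], combined)


class TestHemisphericSplit:
    def test_components_sum_to_global_terms_exactly(self, clean_data):
        hemi = clean_data["hemi"]
        budget = clean_data["budget"]
        assert np.allclose(
            hemi.global_term("fossil"), budget.series["fossil"], atol=0
        )
        assert np.allclose(hemi.global_term("ocean"), budget.series["ocean"], atol=0)

    @pytest.mark.parametrize("fraction,nh,sh", [(1.0, 8.0, 0.0), (0.5, 4.0, 4.0), (0.94, 7.52, 0.48)])
    def test_split_arithmetic(self, fraction, nh, sh):
        config = SyntheticConfig(
            ff_start=8.0,
            ff_growth=0.0,
            noise_sd={"fossil": 0.0, "growth": 0.0, "ocean": 0.0, "land": 0.0},
        )
        budget, _ = gen_budget_series(config)
        hemi = gen_hemispheric_split(budget, fraction, 0.5)
        assert hemi.data["fossil_n"].iloc[0] == pytest.approx(nh)
        assert hemi.data["fossil_s"].iloc[0] == pytest.approx(sh)

    def test_fraction_outside_unit_interval_rejected(self, clean_data):
        with pytest.raises(ValueError, match="fractions"):
            gen_hemispheric_split(clean_data["budget"], 1.2, 0.5)


class TestStationRecords:
    def test_noise_free_inversion_recovers_land_truth(self, clean_data):
        result = invert_two_box(
            clean_data["north"], clean_data["south"], clean_data["hemi"]
        )
        assert np.max(np.abs(result.bn - clean_data["truth"].land_north)) < 1e-9

    def test_doubling_northern_fossil_steepens_mean_gradient(self, clean_config):
        data = generate_all(clean_config)
        hemi = data["hemi"]
        doubled = type(hemi)(
            data=hemi.data.assign(fossil_n=2 * hemi.data["fossil_n"]), sigma=hemi.sigma
        )
        truth = data["truth"]
        base_n, base_s, _ = gen_station_records(hemi, truth.land_north, truth.land_south)
        dbl_n, dbl_s, _ = gen_station_records(doubled, truth.land_north, truth.land_south)
        assert (dbl_n.data - dbl_s.data).mean() > (base_n.data - base_s.data).mean()

    def test_zero_fluxes_give_flat_records(self):
        config = SyntheticConfig(
            ff_start=0.0,
            ff_growth=0.0,
            land_sink_true=0.0,
            noise_sd={"fossil": 0.0, "growth": 0.0, "ocean": 0.0, "land": 0.0},
        )
        budget, truth = gen_budget_series(config)
        hemi = gen_hemispheric_split(budget, 0.94, 0.45)
        north, south, _ = gen_station_records(
            hemi, truth.land_north, truth.land_south, init_north=370.0, init_south=370.0
        )
        assert np.allclose(north.data, 370.0)
        assert np.allclose(south.data, 370.0)

    def test_observation_noise_is_seeded(self, clean_data):
        hemi = clean_data["hemi"]
        truth = clean_data["truth"]
        a = gen_station_records(hemi, truth.land_north, truth.land_south, obs_noise_sd=0.1, seed=5)
        b = gen_station_records(hemi, truth.land_north, truth.land_south, obs_noise_sd=0.1, seed=5)
        pd.testing.assert_series_equal(a[0].data, b[0].data)

    def test_mismatched_land_years_rejected(self, clean_data):
        truth = clean_data["truth"]
        with pytest.raises(ValueError, match="land truth"):
            gen_station_records(
                clean_data["hemi"], truth.land_north.iloc[:-2], truth.land_south
            )


class TestOxygenRecords:
    def test_fossil_only_decline_rate(self):
        from landsink import Stoichiometry
        from landsink.oxygen import mean_rate, per_meg_conversion

        config = SyntheticConfig(
            ff_start=8.0,
            ff_growth=0.0,
            land_sink_true=0.0,
            ocean_fraction_of_ff=0.0,
            noise_sd={"fossil": 0.0, "growth": 0.0, "ocean": 0.0, "land": 0.0},
        )
        budget, _ = gen_budget_series(config)
        stoich = Stoichiometry(z_ocean=0.0)
        o2, _ = gen_o2_records(budget, budget.series["land"], stoich)
        rate_pgc = per_meg_conversion(mean_rate(o2), stoich)[1]
        assert rate_pgc == pytest.approx(-1.38 * 8.0, rel=1e-9)

    def test_noise_free_partition_recovers_truth_exactly(self, clean_data):
        from landsink import Stoichiometry, partition_sinks
        from landsink.oxygen import mean_rate, per_meg_conversion

        budget = clean_data["budget"]
        truth = clean_data["truth"]
        stoich = Stoichiometry()
        d_o2 = per_meg_conversion(mean_rate(clean_data["o2"]), stoich)[1]
        part = partition_sinks(
            float(budget.series["growth"].mean()),
            d_o2,
            float(budget.series["fossil"].mean()),
            stoich,
        )
        assert part.land.value == pytest.approx(float(truth.b_true.mean()), abs=1e-10)
        assert part.ocean.value == pytest.approx(float(truth.o_true.mean()), abs=1e-10)

    def test_same_seed_identical_series(self, clean_data):
        budget = clean_data["budget"]
        a, _ = gen_o2_records(budget, budget.series["land"], noise_sd=0.5, seed=7)
        b, _ = gen_o2_records(budget, budget.series["land"], noise_sd=0.5, seed=7)
        pd.testing.assert_series_equal(a.data, b.data)


class TestEnsembleGeneration:
    def test_unit_scale_truth_gives_unit_scale_factor(self):
        from landsink import compute_scale_factor

        config = SyntheticConfig(seed=1, n_models=4, s_true=np.ones(4))
        members, truth = gen_cmip_ensemble(config)
        s = compute_scale_factor(members, window=config.years)
        assert s.mean == pytest.approx(1.0, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_prescribed_spread_recovered(self):
        from landsink import compute_scale_factor

        config = SyntheticConfig(seed=1, n_models=3, s_true=np.array([1.0, 1.6, 2.2]))
        members, _ = gen_cmip_ensemble(config)
        s = compute_scale_factor(members, window=config.years)
        assert s.mean == pytest.approx(1.6, abs=1e-12)
        assert s.sd == pytest.approx(0.6, abs=1e-12)

    def test_wrong_truth_length_rejected(self):
        with pytest.raises(ValueError, match="per model"):
            gen_cmip_ensemble(SyntheticConfig(n_models=3, s_true=np.ones(2)))

    def test_same_seed_identical_members(self):
        a, _ = gen_cmip_ensemble(SyntheticConfig(seed=17))
        b, _ = gen_cmip_ensemble(SyntheticConfig(seed=17))
        for ma, mb in zip(a, b):
            pd.testing.assert_frame_equal(ma.data, mb.data)


class TestBiomassMaps:
    def test_global_change_is_conserved_exactly(self):
        from landsink import grid_total_change

        config = SyntheticConfig(seed=23, delta_cveg_true=10.1)
        early, late, truth = gen_biomass_maps(config)
        assert grid_total_change(early, late) == pytest.approx(10.1, rel=1e-9)
        assert truth.delta_cveg == 10.1

    def test_sparse_fraction_controls_zero_change_cells(self):
        config = SyntheticConfig(seed=23, sparse_fraction=0.9, grid_shape=(30, 60))
        early, late, _ = gen_biomass_maps(config)
        change = late["cveg"].values - early["cveg"].values
        assert (change == 0).mean() >= 0.85

    def test_densities_remain_nonnegative(self):
        early, late, _ = gen_biomass_maps(SyntheticConfig(seed=4))
        assert (early["cveg"].values >= 0).all()
        assert (late["cveg"].values >= 0).all()

    def test_same_seed_identical_grids(self):
        a_early, a_late, _ = gen_biomass_maps(SyntheticConfig(seed=31))
        b_early, b_late, _ = gen_biomass_maps(SyntheticConfig(seed=31))
        assert np.array_equal(a_early["cveg"].values, b_early["cveg"].values)
        assert np.array_equal(a_late["cveg"].values, b_late["cveg"].values)


def test_generate_all_is_bit_reproducible():
    a = generate_all(SyntheticConfig(seed=77, obs_noise_sd=0.1, o2_noise_sd=0.3))
    b = generate_all(SyntheticConfig(seed=77, obs_noise_sd=0.1, o2_noise_sd=0.3))
    pd.testing.assert_frame_equal(a["budget"].series, b["budget"].series)
    pd.testing.assert_series_equal(a["north"].data, b["north"].data)
    pd.testing.assert_series_equal(a["o2"].data, b["o2"].data)
    assert np.array_equal(a["grid_late"]["cveg"].values, b["grid_late"]["cveg"].values)
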