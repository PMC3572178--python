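"""Redistribution methods, growth projection, national-total adjustment."""

import numpy as np
import pandas as pd
import pytest

import popweave as pw
from conftest import cat, make_grid


def census(rows, year=2008, country="x"):
    return pw.CensusTable(pd.DataFrame(
        [{"unit_id": uid, "population": p, "reference_year": year, "country": country}
         for uid, p in rows.items()]
    ))


class TestClassifyUnitsUrbanRural:
    def test_empty_extent_all_rural(self):
        grid = make_grid(2, 2)
        zones = cat(grid, [[1, 1], [2, 2]], {1: "a", 2: "b"})
        urban = cat(grid, np.zeros((2, 2), dtype=int))
        assert pw.classify_units_urban_rural(zones, urban) == {"a": False, "b": False}

    def test_single_coinciding_cell_makes_unit_urban(self):
        grid = make_grid(2, 2)
        zones = cat(grid, [[1, 1], [2, 2]], {1: "a", 2: "b"})
        urban = cat(grid, [[0, 1], [0, 0]])
        assert pw.classify_units_urban_rural(zones, urban) == {"a": True, "b": False}

    def test_extent_outside_all_units(self):
        grid = make_grid(2, 2)
        zones = cat(grid, [[1, grid.nodata_code], [1, grid.nodata_code]], {1: "a"})
        urban = cat(grid, [[0, 1], [0, 1]])
        assert pw.classify_units_urban_rural(zones, urban) == {"a": False}


class TestProjectPopulation:
    def _flagged(self, pop, urban, year=2005):
        c = census({"u": pop}, year=year)
        return c.with_urban_flags({"u": urban})

    def test_compound_growth_closed_form(self):
        c = self._flagged(1000.0, True, year=2005)
        g = pw.GrowthSpec("x", r_urban=0.02, r_rural=0.0, target_year=2010)
        out = pw.project_population(c, g)
        assert out.frame.population.iloc[0] == pytest.approx(1104.0808, abs=1e-4)

    def test_zero_t_and_zero_r_are_identities(self):
        g0 = pw.GrowthSpec("x", 0.05, 0.03, target_year=2005)
        out = pw.project_population(self._flagged(777.0, False, year=2005), g0)
        assert out.frame.population.iloc[0] == 777.0
        gr0 = pw.GrowthSpec("x", 0.0, 0.0, target_year=2050)
        out = pw.project_population(self._flagged(777.0, True, year=2005), gr0)
        assert out.frame.population.iloc[0] == 777.0

    def test_rural_flag_selects_rural_rate(self):
        g = pw.GrowthSpec("x", r_urban=0.10, r_rural=0.01, target_year=2006)
        out = pw.project_population(self._flagged(100.0, False, year=2005), g)
        assert out.frame.population.iloc[0] == pytest.approx(101.0)

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            pw.GrowthSpec("x", r_urban=-1.5, r_rural=0.0, target_year=2010)

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError, match="urban"):
            pw.project_population(census({"u": 1.0}), pw.GrowthSpec("x", 0, 0, 2010))


class TestDasymetric:
    def test_hand_example_three_a_one_b(self):
        grid = make_grid(1, 4)
        zones = cat(grid, [[1, 1, 1, 1]], {1: "u"})
        lc = cat(grid, [[1, 1, 1, 2]])
        climate = cat(grid, np.ones((1, 4), dtype=int))
        wt = pw.WeightTable.from_dict({(1, 1): 1.0, (1, 2): 7.0})
        pop = pw.dasymetric_redistribute(census({"u": 100.0}), zones, lc, climate, wt)
        assert pop.values.tolist() == [[10.0, 10.0, 10.0, 70.0]]

    def test_constant_weights_reduce_to_areal(self, bundle):
        const = pw.WeightTable.from_dict(
            {k: 3.0 for k in bundle.true_weights.as_dict()}
        )
        dasy = pw.dasymetric_redistribute(
            bundle.census, bundle.fine_zones, bundle.lc, bundle.climate, const
        )
        areal = pw.areal_redistribute(bundle.census, bundle.fine_zones)
        assert np.allclose(dasy.values, areal.values, atol=1e-12, rtol=0)

    def test_degenerate_support_all_mass_on_urban(self):
        grid = make_grid(1, 4)
        zones = cat(grid, [[1, 1, 1, 1]], {1: "u"})
        lc = cat(grid, [[pw.URBAN, 1, 1, pw.URBAN]])
        climate = cat(grid, np.ones((1, 4), dtype=int))
        wt = pw.WeightTable.from_dict({(1, pw.URBAN): 5.0, (1, 1): 0.0})
        pop = pw.dasymetric_redistribute(census({"u": 50.0}), zones, lc, climate, wt)
        assert pop.values.tolist() == [[25.0, 0.0, 0.0, 25.0]]

    def test_zero_weight_unit_falls_back_to_uniform(self, caplog):
        grid = make_grid(1, 2)
        zones = cat(grid, [[1, 1]], {1: "u"})
        lc = cat(grid, [[1, 1]])
        climate = cat(grid, np.ones((1, 2), dtype=int))
        wt = pw.WeightTable.from_dict({(1, 1): 0.0})
        with caplog.at_level("WARNING", logger="popweave"):
            pop = pw.dasymetric_redistribute(census({"u": 10.0}), zones, lc, climate, wt)
        assert pop.values.tolist() == [[5.0, 5.0]]
        assert "uniform" in caplog.text

    def test_outside_cells_nodata(self):
        grid = make_grid(1, 3)
        zones = cat(grid, [[1, grid.nodata_code, grid.nodata_code]], {1: "u"})
        lc = cat(grid, [[1, 1, 1]])
        climate = cat(grid, np.ones((1, 3), dtype=int))
        wt = pw.WeightTable.from_dict({(1, 1): 1.0})
        pop = pw.dasymetric_redistribute(census({"u": 9.0}), zones, lc, climate, wt)
        assert pop.values[0, 1] == pop.nodata and pop.values[0, 2] == pop.nodata


class TestAreal:
    def test_uniform_spread(self):
        grid = make_grid(2, 2)
        zones = cat(grid, [[1, 1], [1, 1]], {1: "u"})
        pop = pw.areal_redistribute(census({"u": 100.0}), zones)
        assert (pop.values == 25.0).all()

    def test_two_units_direct_division(self):
        grid = make_grid(1, 4)
        zones = cat(grid, [[1, 2, 2, 2]], {1: "a", 2: "b"})
        pop = pw.areal_redistribute(census({"a": 10.0, "b": 30.0}), zones)
        assert pop.values.tolist() == [[10.0, 10.0, 10.0, 10.0]]

    def test_zero_population_gives_zero_cells(self):
        grid = make_grid(1, 2)
        zones = cat(grid, [[1, 1]], {1: "u"})
        assert (pw.areal_redistribute(census({"u": 0.0}), zones).values == 0).all()

    def test_within_unit_max_minus_min_is_exactly_zero(self, bundle):
        pop = pw.areal_redistribute(bundle.census, bundle.fine_zones)
        for code in bundle.fine_zones.codes_present():
            vals = pop.values[bundle.fine_zones.values == code]
            assert vals.max() - vals.min() == 0.0

    def test_missing_unit_raises(self):
        grid = make_grid(1, 2)
        zones = cat(grid, [[1, 1]], {1: "u"})
        with pytest.raises(ValueError):
            pw.areal_redistribute(census({"u": 1.0, "ghost": 2.0}), zones)


class TestGrump:
    def _setup(self):
        grid = make_grid(1, 10)
        zones = cat(grid, [[1] * 10], {1: "u"})
        urban = cat(grid, [[1, 1] + [0] * 8])
        return grid, zones, urban

    def test_share_rule_arithmetic(self):
        _, zones, urban = self._setup()
        pop = pw.grump_redistribute(census({"u": 100.0}), zones, urban, urban_share=0.6)
        assert pop.values[0, :2].tolist() == [30.0, 30.0]
        assert np.allclose(pop.values[0, 2:], 5.0)

    def test_no_urban_cells_is_areal(self):
        grid = make_grid(1, 4)
        zones = cat(grid, [[1] * 4], {1: "u"})
        urban = cat(grid, [[0] * 4])
        pop = pw.grump_redistribute(census({"u": 40.0}), zones, urban, urban_share=0.9)
        assert (pop.values == 10.0).all()

    def test_share_one_concentrates_everything(self):
        grid = make_grid(1, 4)
        zones = cat(grid, [[1] * 4], {1: "u"})
        urban = cat(grid, [[0, 1, 0, 0]])
        pop = pw.grump_redistribute(census({"u": 40.0}), zones, urban, urban_share=1.0)
        assert pop.values.tolist() == [[0.0, 40.0, 0.0, 0.0]]

    def test_all_urban_unit_gets_everything_on_urban_cells(self):
        grid = make_grid(1, 2)
        zones = cat(grid, [[1, 1]], {1: "u"})
        urban = cat(grid, [[1, 1]])
        pop = pw.grump_redistribute(census({"u": 10.0}), zones, urban, urban_share=0.3)
        assert pop.values.tolist() == [[5.0, 5.0]]

    def test_share_out_of_range_rejected(self):
        _, zones, urban = self._setup()
        with pytest.raises(ValueError):
            pw.grump_redistribute(census({"u": 1.0}), zones, urban, urban_share=1.5)


class TestAdjustAndIntegerize:
    def test_uniform_scaling(self):
        grid = make_grid(1, 3)
        pop = pw.ValueRaster(grid, np.array([[10.0, 20.0, 30.0]]))
        out = pw.adjust_to_national_total(pop, 120.0)
        assert out.values.tolist() == [[20.0, 40.0, 60.0]]

    def test_identity_when_total_matches(self):
        grid = make_grid(1, 2)
        pop = pw.ValueRaster(grid, np.array([[45.0, 45.0]]))
        out = pw.adjust_to_national_total(pop, 90.0)
        assert np.allclose(out.values, pop.values, rtol=1e-12)

    def test_sum_matches_target_to_1e9_relative(self, bundle):
        pop = pw.areal_redistribute(bundle.census, bundle.fine_zones)
        out = pw.adjust_to_national_total(pop, 123456.0)
        assert abs(out.total() - 123456.0) / 123456.0 <= 1e-9

    def test_zero_sum_input_rejected(self):
        grid = make_grid(1, 2)
        with pytest.raises(ValueError):
            pw.adjust_to_national_total(pw.ValueRaster(grid, np.zeros((1, 2))), 10.0)

    def test_largest_remainder_integerization(self):
        grid = make_grid(1, 3)
        pop = pw.ValueRaster(grid, np.array([[1.2, 2.5, 6.3]]))
        out = pw.integerize_largest_remainder(pop)
        assert out.values.sum() == 10
        assert np.array_equal(out.values, np.array([[1.0, 3.0, 6.0]]))


class TestConservationAndOrderInvariance:
    def per_unit_sums(self, pop, zones):
        return {
            zones.legend[c]: float(pop.values[zones.values == c].sum())
            for c in zones.codes_present()
        }

    def test_mass_conservation_all_methods(self, bundle):
        wt = pw.estimate_weights(bundle.census, bundle.fine_zones, bundle.lc, bundle.climate)
        rasters = {
            "asiapop": pw.dasymetric_redistribute(
                bundle.census, bundle.fine_zones, bundle.lc, bundle.climate, wt
            ),
            "gpw": pw.areal_redistribute(bundle.census, bundle.fine_zones),
            "grump": pw.grump_redistribute(
                bundle.census, bundle.fine_zones, bundle.urban_extent, 0.5
            ),
        }
        pops = bundle.census.populations()
        for name, raster in rasters.items():
            assert (raster.valid_values() >= 0).all()
            sums = self.per_unit_sums(raster, bundle.fine_zones)
            for uid, total in sums.items():
                assert abs(total - pops[uid]) <= 1e-9 * max(pops[uid], 1.0), (name, uid)

    def test_project_then_grid_equals_grid_then_scale(self, bundle):
        flags = pw.classify_units_urban_rural(bundle.fine_zones, bundle.urban_extent)
        c = bundle.census.with_urban_flags(flags)
        spec = pw.GrowthSpec("synthland", r_urban=0.03, r_rural=0.01, target_year=2015)
        projected = pw.project_population(c, spec)
        a = pw.areal_redistribute(projected, bundle.fine_zones)
        b = pw.areal_redistribute(c, bundle.fine_zones)
        scaled = b.values.copy()
        t = 2015 - 2008
        for code in bundle.fine_zones.codes_present():
            uid = bundle.fine_zones.legend[code]
            r = 0.03 if flags[uid] else 0.01
            scaled[bundle.fine_zones.values == code] *= (1 + r) ** t
        valid = ~a.nodata_mask()
        assert np.allclose(a.values[valid], scaled[valid], rtol=1e-12)
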