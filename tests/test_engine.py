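"""Per-source emission operations and inventory assembly.

Expected values are hand evaluations of the linear factor formulas (IPCC
constants 55.65 MJ/kg CH4, 0.67 kg CH4/m3, 44/28 N2O-N conversion).
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beefcarbon import (
    AnimalCategory,
    EmissionInventory,
    Gas,
    ManureSystem,
    Source,
    build_inventory,
    sequestration,
)
from beefcarbon import engine
from beefcarbon.errors import DomainError, FactorLookupError

from conftest import make_cohort, make_farm

APPROX = dict(rel=1e-4)


class TestEntericTier2:
    @pytest.mark.parametrize(
        "gei, ym, head, expected",
        [
            (200.0, 6.5, 1, 85.27),  # 200*0.065*365/55.65
            (200.0, 0.0, 1, 0.0),
            (200.0, 5.0, 10, 655.89),  # 10 * 200*0.05*365/55.65
        ],
    )
    def test_hand_evaluated_masses(self, gei, ym, head, expected):
        cohort = make_cohort(gei=gei, headcount=head)
        result = engine.enteric_ch4_tier2(cohort, ym)
        assert result.mass == pytest.approx(expected, abs=0.01)
        assert result.source is Source.ENTERIC and result.gas is Gas.CH4

    def test_out_of_domain_ym_rejected(self):
        with pytest.raises(DomainError, match="ym"):
            engine.enteric_ch4_tier2(make_cohort(), 15.0)

    @settings(deadline=None, derandomize=True)
    @given(
        gei=st.floats(1.0, 400.0),
        ym=st.floats(0.1, 14.9),
        head=st.floats(0.0, 500.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_homogeneous_in_headcount_and_gei(self, gei, ym, head, scale):
        base = engine.enteric_ch4_tier2(make_cohort(gei=gei, headcount=head), ym).mass
        scaled = engine.enteric_ch4_tier2(
            make_cohort(gei=gei, headcount=head * scale), ym
        ).mass
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)


class TestEntericPerHead:
    def test_table_lookup_scales_with_headcount(self):
        table = {AnimalCategory.SUCKLER_COW: 90.0}
        one = engine.enteric_ch4_per_head(make_cohort(headcount=1), table)
        ten = engine.enteric_ch4_per_head(make_cohort(headcount=10), table)
        assert one.mass == pytest.approx(90.0)
        assert ten.mass == pytest.approx(900.0)

    def test_missing_category_names_it(self):
        with pytest.raises(FactorLookupError, match="suckler_cow"):
            engine.enteric_ch4_per_head(make_cohort(), {AnimalCategory.STORE: 50.0})


class TestManureCH4:
    def test_fully_housed_slurry_hand_value(self, ie_set):
        # 2.5 * 365 * 0.17 * 0.67 * 0.17 = 17.67 kg
        cohort = make_cohort(vs=2.5, days_grazing=0.0)
        result = engine.manure_ch4(cohort, {ManureSystem.SLURRY_TANK: 1.0}, ie_set)
        assert result.mass == pytest.approx(17.67, abs=0.01)

    def test_zero_mcf_gives_zero(self, ie_set):
        efs = ie_set.model_copy(
            update={"mcf": {s: 0.0 for s in ManureSystem}}
        )
        cohort = make_cohort(vs=2.5, days_grazing=100.0)
        assert engine.manure_ch4(cohort, {ManureSystem.SLURRY_TANK: 1.0}, efs).mass == 0.0

    def test_system_mix_is_share_weighted_mean(self, ie_set):
        # 50/50 split of two housed systems equals the mean of the pure systems
        efs = ie_set.model_copy(
            update={"mcf": {ManureSystem.SLURRY_TANK: 17.0,
                            ManureSystem.SOLID_STORAGE: 1.0,
                            ManureSystem.PASTURE_DEPOSITION: 1.0}}
        )
        cohort = make_cohort(vs=2.5, days_grazing=0.0)
        pure_a = engine.manure_ch4(cohort, {ManureSystem.SLURRY_TANK: 1.0}, efs).mass
        pure_b = engine.manure_ch4(cohort, {ManureSystem.SOLID_STORAGE: 1.0}, efs).mass
        mixed = engine.manure_ch4(
            cohort, {ManureSystem.SLURRY_TANK: 0.5, ManureSystem.SOLID_STORAGE: 0.5}, efs
        ).mass
        assert mixed == pytest.approx((pure_a + pure_b) / 2, **APPROX)


class TestManureN2O:
    def test_fully_housed_storage_hand_value(self, ie_set):
        # 80 * 0.005 * 44/28 = 0.6286 kg N2O
        cohort = make_cohort(nex=80.0, days_grazing=0.0)
        storage, _ = engine.manure_n2o(cohort, {ManureSystem.SLURRY_TANK: 1.0}, ie_set)
        assert storage.mass == pytest.approx(0.6286, abs=1e-3)

    def test_zero_ef3_gives_zero(self, ie_set):
        efs = ie_set.model_copy(update={"ef3_storage": {s: 0.0 for s in ManureSystem}})
        cohort = make_cohort(nex=80.0, days_grazing=0.0)
        storage, _ = engine.manure_n2o(cohort, {ManureSystem.SLURRY_TANK: 1.0}, efs)
        assert storage.mass == 0.0

    def test_half_year_housed_halves_the_mass(self, ie_set):
        housed = make_cohort(nex=80.0, days_grazing=0.0)
        half = make_cohort(nex=80.0, days_grazing=182.5)
        shares = {ManureSystem.SLURRY_TANK: 1.0}
        full_storage, full_spread = engine.manure_n2o(housed, shares, ie_set)
        half_storage, half_spread = engine.manure_n2o(half, shares, ie_set)
        assert half_storage.mass == pytest.approx(full_storage.mass / 2, **APPROX)
        assert half_spread.mass == pytest.approx(full_spread.mass / 2, **APPROX)


class TestGrazingReturns:
    def test_half_year_grazing_hand_value(self, ie_set):
        # 80 * 0.5 * 0.02 * 44/28 = 1.2571 kg N2O
        cohort = make_cohort(nex=80.0, days_grazing=182.5)
        assert engine.grazing_n2o(cohort, ie_set).mass == pytest.approx(1.2571, abs=1e-3)

    def test_linear_in_grazing_days(self, ie_set):
        half = engine.grazing_n2o(make_cohort(nex=80.0, days_grazing=182.5), ie_set).mass
        full = engine.grazing_n2o(make_cohort(nex=80.0, days_grazing=365.0), ie_set).mass
        assert full == pytest.approx(2 * half, **APPROX)
        assert engine.grazing_n2o(make_cohort(nex=80.0, days_grazing=0.0), ie_set).mass == 0.0


class TestSoilAndIndirectN2O:
    def test_direct_fertilizer_hand_value(self, ie_set):
        # 100 * 0.01 * 44/28 = 1.571 kg N2O
        assert engine.soil_n2o_fertilizer(100.0, 0.0, ie_set).mass == pytest.approx(
            1.571, abs=1e-3
        )
        assert engine.soil_n2o_fertilizer(0.0, 0.0, ie_set).mass == 0.0

    def test_spread_manure_n_is_additive(self, ie_set):
        fert_only = engine.soil_n2o_fertilizer(100.0, 0.0, ie_set).mass
        both = engine.soil_n2o_fertilizer(100.0, 50.0, ie_set).mass
        assert both == pytest.approx(1.5 * fert_only, **APPROX)

    def test_volatilization_pathway_hand_value(self, ie_set):
        # 100 * 0.10 * 0.01 * 44/28 = 0.1571 kg
        efs = ie_set.model_copy(update={"frac_leach": 0.0})
        res = engine.indirect_n2o({"fertilizer_n": 100.0}, efs)
        assert res.mass == pytest.approx(0.1571, abs=1e-3)

    def test_leaching_pathway_hand_value(self, ie_set):
        # 100 * 0.30 * 0.0075 * 44/28 = 0.3536 kg
        efs = ie_set.model_copy(update={"frac_gas_fert": 0.0, "frac_gas_manure": 0.0})
        res = engine.indirect_n2o({"fertilizer_n": 100.0}, efs)
        assert res.mass == pytest.approx(0.3536, abs=1e-3)

    def test_zero_fractions_give_zero(self, ie_set):
        efs = ie_set.model_copy(
            update={"frac_gas_fert": 0.0, "frac_gas_manure": 0.0, "frac_leach": 0.0}
        )
        assert engine.indirect_n2o({"fertilizer_n": 100.0, "manure_n": 500.0}, efs).mass == 0.0


class TestCO2AndOffFarm:
    def test_liming_and_diesel_hand_values(self, ie_set):
        lime, fuel = engine.liming_and_fuel_co2(1000.0, 500.0, ie_set)
        assert lime.mass == pytest.approx(1000.0 * ie_set.ef_lime)
        assert lime.mass == pytest.approx(440.0)
        assert fuel.mass == pytest.approx(500.0 * 2.67)

    def test_concentrate_embedded_emissions(self, ie_set):
        efs = ie_set.model_copy(update={"ef_concentrate": {"compound_ration": 0.8}})
        farm = make_farm(concentrate_fed={"compound_ration": 10000.0})
        results = {r.source: r for r in engine.offfarm_co2e(farm, efs)}
        assert results[Source.CONCENTRATE].mass == pytest.approx(8000.0)
        assert results[Source.CONCENTRATE].preaggregated

    def test_fertilizer_manufacture(self, ie_set):
        farm = make_farm(fert_n_applied=1000.0)
        results = {r.source: r for r in engine.offfarm_co2e(farm, ie_set)}
        assert results[Source.FERT_MANUFACTURE].mass == pytest.approx(6000.0)

    def test_unknown_concentrate_type_named(self, ie_set):
        farm = make_farm(concentrate_fed={"mystery_meal": 100.0})
        with pytest.raises(FactorLookupError, match="mystery_meal"):
            engine.offfarm_co2e(farm, ie_set)

    def test_no_inputs_all_zero(self, ie_set):
        results = engine.offfarm_co2e(make_farm(), ie_set)
        assert all(r.mass == 0.0 for r in results)


class TestSequestration:
    def test_grassland_product(self, ie_set):
        efs = ie_set.model_copy(update={"seq_rate_grassland": 700.0})
        assert sequestration(make_farm(grassland_area=50.0), efs) == pytest.approx(35000.0)

    def test_hedgerow_adds_linearly(self, ie_set):
        efs = ie_set.model_copy(update={"seq_rate_hedgerow": 1.0})
        base = sequestration(make_farm(grassland_area=10.0), efs)
        with_hedge = sequestration(
            make_farm(grassland_area=10.0, hedgerow_length=1000.0), efs
        )
        assert with_hedge - base == pytest.approx(1000.0)
        assert sequestration(make_farm(), ie_set.model_copy(
            update={"seq_rate_grassland": 0.0, "seq_rate_hedgerow": 0.0})) == 0.0


class TestBuildInventory:
    def test_zero_farm_gives_zero_inventory(self, ie_set):
        inv = build_inventory(make_farm(), ie_set)
        assert all(m == 0.0 for m in inv.entries.values())

    def test_totals_equal_sum_of_component_operations(self, suite, ie_set, fr_set):
        for efs in (ie_set, fr_set):
            for farm in suite[:6]:
                inv = build_inventory(farm, efs)
                expected = EmissionInventory()
                for cohort in farm.cohorts:
                    if efs.enteric_mode == "tier2":
                        ent = engine.enteric_ch4_tier2(cohort, efs.ym)
                    else:
                        ent = engine.enteric_ch4_per_head(cohort, efs.per_head_enteric)
                    expected.add(ent.source, ent.gas, ent.mass)
                    m = engine.manure_ch4(cohort, farm.manure_system_shares, efs)
                    expected.add(m.source, m.gas, m.mass)
                    sto, spr = engine.manure_n2o(cohort, farm.manure_system_shares, efs)
                    expected.add(sto.source, sto.gas, sto.mass)
                    expected.add(spr.source, spr.gas, spr.mass)
                    g = engine.grazing_n2o(cohort, efs)
                    expected.add(g.source, g.gas, g.mass)
                soil = engine.soil_n2o_fertilizer(farm.fert_n_applied, 0.0, efs)
                expected.add(soil.source, soil.gas, soil.mass)
                nex_total = sum(c.n_excretion * c.headcount for c in farm.cohorts)
                ind = engine.indirect_n2o(
                    {"fertilizer_n": farm.fert_n_applied, "manure_n": nex_total}, efs
                )
                expected.add(ind.source, ind.gas, ind.mass)
                lime, fuel = engine.liming_and_fuel_co2(
                    farm.lime_applied, farm.diesel_used, efs
                )
                expected.add(lime.source, lime.gas, lime.mass)
                expected.add(fuel.source, fuel.gas, fuel.mass)
                for r in engine.offfarm_co2e(farm, efs):
                    expected.add(r.source, r.gas, r.mass, preaggregated=r.preaggregated)
                assert inv == expected

    def test_doubling_headcount_doubles_livestock_masses(self, suite, ie_set):
        farm = suite[0]
        doubled = farm.model_copy(
            update={
                "cohorts": [
                    c.model_copy(update={"headcount": 2 * c.headcount})
                    for c in farm.cohorts
                ]
            }
        )
        inv, inv2 = build_inventory(farm, ie_set), build_inventory(doubled, ie_set)
        for source in (Source.ENTERIC, Source.MANURE_STORAGE, Source.GRAZING_RETURNS):
            for gas in Gas:
                assert inv2.get(source, gas) == pytest.approx(
                    2 * inv.get(source, gas), rel=1e-9
                )

    def test_fr_style_enteric_exceeds_ie_style_on_grass_farms(self, suite, ie_set, fr_set):
        grass = [f for f in suite if f.farm_id in ("IE1", "IE2", "FR1", "FR2", "FR5")]
        assert grass
        for farm in grass:
            ie_ent = build_inventory(farm, ie_set).get(Source.ENTERIC, Gas.CH4)
            fr_ent = build_inventory(farm, fr_set).get(Source.ENTERIC, Gas.CH4)
            assert fr_ent > ie_ent

    def test_n2o_n_never_exceeds_n_entering_system(self, suite, all_sets):
        for efs in all_sets:
            for farm in suite:
                inv = build_inventory(farm, efs)
                n_in = farm.fert_n_applied + sum(
                    c.n_excretion * c.headcount for c in farm.cohorts
                )
                assert engine.total_n2o_n(inv) <= n_in + 1e-9
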