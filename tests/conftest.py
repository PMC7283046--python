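import pytest

from beefcarbon import (
    AnimalCategory,
    AnimalCohort,
    FarmRecord,
    FarmSystem,
    ManureSystem,
    generate_suite,
    load_ef_set,
    load_gwp_set,
    load_measure_catalogue,
)

SUITE_SEED = 42


@pytest.fixture(scope="session")
def gwp():
    return load_gwp_set()


@pytest.fixture(scope="session")
def ie_set():
    return load_ef_set("IE_style")


@pytest.fixture(scope="session")
def fr_set():
    return load_ef_set("FR_style")


@pytest.fixture(scope="session")
def es_set():
    return load_ef_set("ES_style")


@pytest.fixture(scope="session")
def all_sets(ie_set, fr_set, es_set):
    return [ie_set, fr_set, es_set]


@pytest.fixture(scope="session")
def suite():
    return generate_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def catalogue():
    return load_measure_catalogue()


def make_cohort(
    category=AnimalCategory.SUCKLER_COW,
    headcount=1.0,
    gei=200.0,
    nex=80.0,
    vs=2.5,
    days_grazing=0.0,
    **kwargs,
):
    return AnimalCohort(
        category=category,
        headcount=headcount,
        avg_live_weight=kwargs.get("avg_live_weight", 600.0),
        daily_gain=kwargs.get("daily_gain", 0.0),
        gross_energy_intake=gei,
        n_excretion=nex,
        volatile_solids=vs,
        days_grazing=days_grazing,
        days_housed=365.0 - days_grazing,
    )


def make_farm(
    cohorts=None,
    shares=None,
    system=FarmSystem.SUCKLER_TO_BEEF,
    **kwargs,
):
    if shares is None:
        shares = {ManureSystem.SLURRY_TANK: 1.0}
    defaults = dict(
        farm_id="TEST",
        system=system,
        grassland_area=0.0,
        cohorts=cohorts or [],
        manure_system_shares=shares if (cohorts or shares) else {},
        lw_sold=10000.0,
        lw_opening=0.0,
        lw_closing=0.0,
    )
    defaults.update(kwargs)
    return FarmRecord(**defaults)
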