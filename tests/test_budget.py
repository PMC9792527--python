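"""Unit and property tests for the N & P mass-balance ledger."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrimpn import budget as bd
from shrimpn.budget import (
    Checkpoint,
    NutrientFractions,
    ScenarioSpec,
    biomass_per_ha,
    build_budget_table,
    excreted_nutrient,
    feed_nutrient,
    inorganic_load,
    removal_efficiency,
    retained_nutrient,
    site_total,
    unconsumed_feed,
)

masses = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


@pytest.mark.parametrize(
    "survivors, weight_g, expected",
    [
        (185000, 15.48, 2.8638),  # final 2018 checkpoint, rounds to the ledger's 2.87
        (0, 15.48, 0.0),
        (77000, 15.5, 1.1935),
    ],
)
def test_biomass_per_ha(survivors, weight_g, expected):
    assert biomass_per_ha(survivors, weight_g) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "func, args, expected",
    [
        (feed_nutrient, (4.162, 0.065), 0.27053),  # N in season feed, prints 0.271
        (feed_nutrient, (4.162, 0.014), 0.058268),
        (feed_nutrient, (0.0, 0.065), 0.0),
        (unconsumed_feed, (4.162, 0.30), 1.2486),
        (unconsumed_feed, (1.615, 0.10), 0.1615),
        (unconsumed_feed, (7.7, 0.0), 0.0),
        (retained_nutrient, (2.87, 0.03), 0.0861),
        (retained_nutrient, (2.87, 0.01), 0.0287),
        (retained_nutrient, (0.0, 0.03), 0.0),
        (inorganic_load, (0.081185, 0.18443), 0.265615),  # prints 0.266
        (inorganic_load, (0.0105, 0.069), 0.0795),
        (inorganic_load, (0.0, 0.0), 0.0),
        (site_total, (0.047, 830), 39.01),  # site P total, prints 39
        (site_total, (0.123, 1), 0.123),
    ],
)
def test_linear_ledger_ops(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "feed_n, retained, unconsumed, convention, expected",
    [
        (0.27053, 0.0861, 0.0, "table1", 0.18443),  # prints 0.184
        (0.105, 0.036, 0.0, "table1", 0.069),
        (0.27053, 0.0861, 0.081185, "strict", 0.27053 - 0.0861 - 0.081185),
        (0.1, 0.1, 0.0, "table1", 0.0),
    ],
)
def test_excreted_nutrient(feed_n, retained, unconsumed, convention, expected):
    assert excreted_nutrient(feed_n, retained, unconsumed, convention) == pytest.approx(
        expected, abs=1e-9
    )


def test_excretion_clamps_negative_balance_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        assert excreted_nutrient(0.1, 0.2, 0.0, "table1") == 0.0


@pytest.mark.parametrize(
    "func, args",
    [
        (biomass_per_ha, (-1, 10)),
        (feed_nutrient, (1.0, 1.5)),
        (feed_nutrient, (-1.0, 0.5)),
        (unconsumed_feed, (1.0, 1.0)),
        (retained_nutrient, (-1.0, 0.03)),
        (site_total, (1.0, 0.0)),
        (removal_efficiency, (0.0, 1.0)),
        (inorganic_load, (-0.1, 0.1)),
    ],
)
def test_domain_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


def test_excreted_rejects_unknown_convention():
    with pytest.raises(ValueError, match="convention"):
        excreted_nutrient(1.0, 0.1, 0.0, "bogus")


def test_removal_efficiency():
    # the published pairing: 220.157 t entering vs 121.8 t leaving the lagoon
    eff = removal_efficiency(220.157, 121.8)
    assert eff == pytest.approx(0.44677, abs=1e-4)
    assert round(eff * 100) == 45
    assert removal_efficiency(7.0, 7.0) == 0.0
    assert removal_efficiency(7.0, 0.0) == 1.0
    assert removal_efficiency(100.0, 150.0) < 0  # reported, not clamped


@given(mass=masses, factor=st.floats(min_value=0.0, max_value=10.0))
@settings(max_examples=50, deadline=None)
def test_ledger_ops_are_homogeneous_degree_one(mass, factor):
    """Doubling (scaling) the mass argument scales the output linearly."""
    for func, coeff in [
        (feed_nutrient, 0.065),
        (unconsumed_feed, 0.3),
        (retained_nutrient, 0.03),
    ]:
        assert func(mass * factor, coeff) == pytest.approx(factor * func(mass, coeff), rel=1e-12, abs=1e-12)
    assert site_total(mass * factor, 830.0) == pytest.approx(
        factor * site_total(mass, 830.0), rel=1e-12, abs=1e-12
    )


@given(
    a=st.floats(min_value=1e-6, max_value=1e6),
    b=st.floats(min_value=0.0, max_value=1e6),
)
@settings(max_examples=50, deadline=None)
def test_removal_efficiency_complements_transfer_ratio(a, b):
    assert removal_efficiency(a, b) + b / a == pytest.approx(1.0, rel=1e-12)


def test_scenario_validation():
    cp = Checkpoint(day=10, survivors_per_ha=1000, weight_g=1.0, cum_feed_t_per_ha=0.1)
    with pytest.raises(ValueError, match="increasing"):
        ScenarioSpec(area_ha=10, checkpoints=(cp, cp), loss_frac=0.3)
    cp2 = Checkpoint(day=20, survivors_per_ha=1000, weight_g=2.0, cum_feed_t_per_ha=0.05)
    with pytest.raises(ValueError, match="non-decreasing"):
        ScenarioSpec(area_ha=10, checkpoints=(cp, cp2), loss_frac=0.3)
    with pytest.raises(ValueError):
        NutrientFractions(n_feed=0.0)


def test_budget_table_zero_stocking_is_all_zero():
    cps = tuple(
        Checkpoint(day=d, survivors_per_ha=0, weight_g=1.0, cum_feed_t_per_ha=0.0)
        for d in (50, 80, 110)
    )
    table = build_budget_table(ScenarioSpec(area_ha=830, checkpoints=cps, loss_frac=0.3))
    frame = table.to_frame().drop(columns="day")
    assert (frame == 0).all().all()
    assert table.site_n_total_t == 0.0


def test_table1_convention_counts_unconsumed_twice():
    """Under the published bookkeeping, inorganic load = feed N - meat N + unconsumed N."""
    feed_n, meat_n, uncons_n = 0.27053, 0.0861, 0.081185
    excr = excreted_nutrient(feed_n, meat_n, uncons_n, "table1")
    assert inorganic_load(uncons_n, excr) == pytest.approx(feed_n - meat_n + uncons_n, rel=1e-12)


def test_strict_convention_conserves_mass():
    from shrimpn.synthdata import generate_scenario

    for density, fcr, loss in [(240000, 1.29, 0.30), (100000, 1.22, 0.10), (50000, 1.8, 0.0)]:
        scenario = generate_scenario(area_ha=830, density_per_ha=density, fcr=fcr, loss_frac=loss)
        table = build_budget_table(scenario, convention="strict")
        for row in table.rows:
            assert row.n_feed_t == pytest.approx(
                row.unconsumed_n_t + row.meat_n_t + row.excreted_n_t, rel=1e-12
            )
            assert row.p_feed_t == pytest.approx(
                row.unconsumed_p_t + row.meat_p_t + row.excreted_p_t, rel=1e-12
            )


def test_published_first_checkpoint_overdraws_p_under_strict(scenarios):
    """The monitored 2018 day-50 rows (biomass and unconsumed feed) imply
    more retained + wasted P than the feed contained, so the strict balance
    clamps excretion to zero there and warns; the published bookkeeping
    (``table1``) does not hit the clamp."""
    with pytest.warns(UserWarning, match="clamped"):
        table = build_budget_table(scenarios["2018"], convention="strict")
    assert table.rows[0].excreted_p_t == 0.0


def test_budget_roundtrip_csv(tmp_path, budget_tables):
    import pandas as pd

    table = budget_tables["2018"]
    path = tmp_path / "budget.csv"
    table.to_csv(path)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, table.to_frame())


def test_monitored_rows_override_derived_values():
    """Observed biomass / unconsumed feed on a checkpoint take precedence."""
    cp = Checkpoint(
        day=50,
        survivors_per_ha=195000,
        weight_g=0.6,
        cum_feed_t_per_ha=0.094,
        biomass_t_per_ha=0.117,
        unconsumed_feed_t_per_ha=0.037,
    )
    table = build_budget_table(ScenarioSpec(area_ha=830, checkpoints=(cp,), loss_frac=0.3))
    row = table.rows[0]
    assert row.biomass_t_per_ha == 0.117
    assert row.unconsumed_feed_t == 0.037
    # without overrides, the derived values apply
    cp_plain = Checkpoint(day=50, survivors_per_ha=195000, weight_g=0.6, cum_feed_t_per_ha=0.094)
    row_plain = build_budget_table(
        ScenarioSpec(area_ha=830, checkpoints=(cp_plain,), loss_frac=0.3)
    ).rows[0]
    assert row_plain.biomass_t_per_ha == pytest.approx(0.117, abs=1e-9)
    assert row_plain.unconsumed_feed_t == pytest.approx(0.094 * 0.3, rel=1e-12)
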