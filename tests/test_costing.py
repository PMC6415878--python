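"""Cost categories, micro-costing, capital equipment."""

import dataclasses

import numpy as np
import pytest

from besurv.costing import (
    ae_costs,
    capital_equipment_cost,
    histopathology_cost,
    procedure_costs,
    staff_cost_per_procedure,
)
from besurv.diagnostic_pathway import AEProfile, build_arms
from besurv.parameters import StaffTimes


def test_staff_micro_costs_per_endoscopy(params):
    # HD-WLE: 0.30x23 + 0.89x41 + 0.50x142 + 0.30x100 + 0.30x142
    assert staff_cost_per_procedure(params.costs, nbi_share=0.0) == pytest.approx(186.99)
    # NBI differs only in nurse non-contact time (0.42 h, proportional to biopsies)
    assert staff_cost_per_procedure(params.costs, nbi_share=1.0) == pytest.approx(167.72)
    blended = staff_cost_per_procedure(params.costs, nbi_share=0.84)
    assert blended == pytest.approx(0.84 * 167.72 + 0.16 * 186.99)


def test_zero_staff_times_cost_nothing(params):
    zero = StaffTimes(0, 0, 0, 0, 0)
    costs = dataclasses.replace(params.costs, staff_times_nbi=zero, staff_times_wle=zero)
    assert staff_cost_per_procedure(costs, 0.5) == 0.0


def test_per_patient_histology_cost(params):
    # the published derived cells: 82 x 3.6 and 82 x 7.6
    one = np.array([1.0])
    f = np.array([1.0])
    assert histopathology_cost(one * 3.6, 82, f) == pytest.approx(295.2)
    assert histopathology_cost(one * 7.6, 82, f) == pytest.approx(623.2)
    assert histopathology_cost(one * 4.24, 82, f) == pytest.approx(347.68)
    assert histopathology_cost(one * 0, 82, f) == 0.0


def test_histology_cost_discounts_and_scales(params):
    biopsies = np.array([100.0, 100.0])
    f = np.array([1.0, 0.5])
    assert histopathology_cost(biopsies, 82, f) == pytest.approx(100 * 82 * 1.5)
    assert histopathology_cost(biopsies, 82 * 1.1, f) == pytest.approx(
        1.1 * histopathology_cost(biopsies, 82, f)
    )


def _profile(stricture=0.0, perforation=0.0, bleeding=0.0):
    zero = {"stricture": 0.0, "perforation": 0.0, "bleeding": 0.0}
    return AEProfile(
        endoscopy={"stricture": stricture, "perforation": perforation, "bleeding": bleeding},
        treatment=dict(zero),
    )


def test_ae_costs_examples(params):
    unit = params.costs.ae_costs
    f = np.array([1.0])
    assert ae_costs([_profile(perforation=1.0)], unit, f) == pytest.approx(2852.0)
    assert ae_costs([_profile(stricture=1.0, bleeding=1.0)], unit, f) == pytest.approx(784.0)
    assert ae_costs([_profile()], unit, f) == 0.0


def test_capital_upgrade_quantities(params):
    nbi, wle = build_arms(params)
    plan = capital_equipment_cost(nbi, params.equipment, years=7)
    e = params.equipment
    systems_cost = 249 * 0.84 * (1 - 0.83) * 3.25 * 41_316  # 115.55 systems
    scopes_cost = 249 * 0.84 * 3.25 * 4 * (1 - 0.40) * 30_487
    training = 249 * 0.84 * 3.25 * 0.50 * 2 * 1136
    assert training == pytest.approx(0.772e6, rel=1e-3)
    assert plan.one_off_purchases == pytest.approx(systems_cost + scopes_cost + training)
    assert plan.amortized_per_year == pytest.approx(
        np.full(7, plan.one_off_purchases / 7)
    )
    # non-adopting arm has no purchases, full-estate replacement
    wle_plan = capital_equipment_cost(wle, params.equipment, years=7)
    assert wle_plan.one_off_purchases == 0.0
    assert wle_plan.replacement_per_year[0] == pytest.approx(
        249 * 3.25 * 4 * 0.029 * 30_487
    )
    # adopting arm replaces only its non-upgraded (non-Olympus) share
    assert plan.replacement_per_year[0] == pytest.approx(
        wle_plan.replacement_per_year[0] * (1 - 0.84)
    )


def test_fully_equipped_estate_needs_no_upgrade(params):
    fully = params.with_overrides(
        {
            "equipment.nbi_capable_share": 1.0,
            "equipment.hd_scope_share": 1.0,
            "equipment.trained_share": 0.0,
        }
    )
    nbi, _ = build_arms(fully)
    plan = capital_equipment_cost(nbi, fully.equipment, years=7)
    assert plan.one_off_purchases == 0.0


def test_capital_increment_positive(params):
    nbi, wle = build_arms(params)
    f = np.ones(7)
    plan_n = capital_equipment_cost(nbi, params.equipment, years=7)
    plan_w = capital_equipment_cost(wle, params.equipment, years=7)
    total_n = (plan_n.amortized_per_year + plan_n.replacement_per_year).sum()
    total_w = (plan_w.amortized_per_year + plan_w.replacement_per_year).sum()
    assert total_n > total_w


def test_procedure_costs_by_perspective(params):
    nbi, wle = build_arms(params)
    pop = np.array([1000.0])
    treated = np.array([50.0])
    f = np.array([1.0])
    nhs = procedure_costs(pop, treated, "nhs", wle, params.costs, f)
    assert nhs == (pytest.approx(1000 * 517), pytest.approx(50 * 2101))
    hosp_endo, hosp_treat = procedure_costs(pop, treated, "hospital", wle, params.costs, f)
    assert hosp_endo == pytest.approx(1000 * (186.99 + 21.0))  # staff + forceps
    assert hosp_treat == pytest.approx(50 * (186.99 + 12.0))  # staff + snare
    with pytest.raises(ValueError, match="perspective"):
        procedure_costs(pop, treated, "societal", wle, params.costs, f)


def test_identical_arms_produce_identical_breakdowns(params):
    """With no NBI uptake the mixed arm degenerates to pure HD-WLE."""
    from besurv.analyses import cost_consequence

    same = params.override("economics.market_share_nbi", 0.0)
    cc = cost_consequence(same)
    for cat, a in cc.nbi.cost.categories.items():
        if cat == "capital_equipment":
            continue  # the adopting arm still buys systems even at zero share
        assert a == pytest.approx(cc.hdwle.cost.categories[cat], rel=1e-12)


def test_biopsy_price_moves_only_histopathology(params, base_cc):
    from besurv.analyses import cost_consequence

    dearer = params.override("costs.cost_per_biopsy", 82 * 1.1)
    cc = cost_consequence(dearer)
    assert cc.nbi.cost.categories["histopathology"] == pytest.approx(
        base_cc.nbi.cost.categories["histopathology"] * 1.1, rel=1e-12
    )
    for cat in ("endoscopy_staff_overheads", "adverse_events", "capital_equipment"):
        assert cc.nbi.cost.categories[cat] == pytest.approx(
            base_cc.nbi.cost.categories[cat], rel=1e-12
        )


def test_histopathology_ratio_equals_biopsy_ratio(base_cc):
    """The arm ratio of histology spend is the biopsies-per-procedure ratio,
    independent of discounting."""
    ratio = (
        base_cc.nbi.cost.categories["histopathology"]
        / base_cc.hdwle.cost.categories["histopathology"]
    )
    assert ratio == pytest.approx(4.24 / 7.6, rel=1e-12)


def test_hospital_margin_identity(params):
    """Hospital perspective: margin = tariff income - micro-costs."""
    from besurv.analyses import cost_consequence

    cc = cost_consequence(params, perspective="hospital")
    for arm in (cc.nbi, cc.hdwle):
        assert arm.cost.income is not None
        assert arm.cost.margin == pytest.approx(arm.cost.income - arm.cost.grand_total)
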