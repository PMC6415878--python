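"""Parameter loading, defaults, validation and overrides."""

import pytest

from besurv.parameters import (
    ConfigurationError,
    ParameterSet,
    ParameterValidationError,
    UnknownParameterError,
    apply_override,
    default_parameters,
    load_parameters,
    valid_parameter_paths,
)

# every published default input, by dotted path (fractions, GBP)
EXPECTED_DEFAULTS = {
    "epidemiology.n_year1": 161_657,
    "epidemiology.annual_growth": 0.20,
    "epidemiology.horizon_years": 7,
    "epidemiology.hospital_cohort": 649,
    "epidemiology.parasa.total": 2696,
    "epidemiology.parasa.dysplastic": 905,
    "epidemiology.parasa.lg": 751,
    "epidemiology.parasa.hg": 106,
    "epidemiology.parasa.eac": 48,
    "accuracy.per_patient_sens": 0.942,
    "accuracy.per_patient_spec": 0.944,
    "accuracy.per_lesion_sens_nbi": 0.890,
    "accuracy.per_lesion_spec_nbi": 0.800,
    "accuracy.per_lesion_sens_wle": 0.791,
    "accuracy.per_lesion_spec_wle": 0.810,
    "accuracy.hist_sens": 1.0,
    "accuracy.hist_spec": 0.629,
    "procedure.biopsies_nbi": 3.6,
    "procedure.biopsies_wle": 7.6,
    "procedure.endo_ae_nbi.stricture": 0.0001,
    "procedure.endo_ae_nbi.perforation": 0.014,
    "procedure.endo_ae_nbi.bleeding": 0.002,
    "procedure.endo_ae_wle.stricture": 0.0001,
    "procedure.endo_ae_wle.perforation": 0.030,
    "procedure.endo_ae_wle.bleeding": 0.005,
    "procedure.treat_ae.stricture": 0.335,
    "procedure.treat_ae.perforation": 0.013,
    "procedure.treat_ae.bleeding": 0.075,
    "procedure.eradication_rate": 0.949,
    "economics.discount_rate": 0.035,
    "economics.market_share_nbi": 0.84,
    "costs.tariff_endoscopy": 517,
    "costs.tariff_emr_rfa": 2101,
    "costs.cost_per_biopsy": 82,
    "costs.ae_costs.stricture": 392,
    "costs.ae_costs.bleeding": 392,
    "costs.ae_costs.perforation": 2852,
    "costs.cancer_cost_per_year": 7647,
    "costs.staff_rates.admin": 23,
    "costs.staff_rates.nurse_noncontact": 41,
    "costs.staff_rates.consultant_ba": 142,
    "costs.staff_rates.nurse_contact": 100,
    "costs.staff_rates.consultant_during": 142,
    "costs.staff_times_nbi.nurse_noncontact": 0.42,
    "costs.staff_times_wle.nurse_noncontact": 0.89,
    "costs.snare_pack_cost": 240,
    "costs.forceps_pack_cost": 210,
    "equipment.hospitals": 249,
    "equipment.rooms_per_hospital": 3.25,
    "equipment.endoscopists_per_hospital": 3.25,
    "equipment.scopes_per_room": 4.0,
    "equipment.olympus_share": 0.84,
    "equipment.nbi_capable_share": 0.83,
    "equipment.hd_scope_share": 0.40,
    "equipment.trained_share": 0.50,
    "equipment.replacement_rate": 0.029,
    "equipment.unit_cost_system": 41_316,
    "equipment.unit_cost_scope": 30_487,
    "equipment.training_cost_per_day_nbi": 1136,
    "equipment.training_cost_per_day_wle": 795,
    "equipment.training_days_nbi": 2,
    "equipment.maintenance_system_nbi": 4590,
    "equipment.maintenance_system_wle": 4527,
    "equipment.maintenance_scope_nbi": 4285,
    "equipment.maintenance_scope_wle": 4089,
    "equipment.amortization_years": 7,
}


def _lookup(params: ParameterSet, path: str):
    node = params.to_dict()
    for part in path.split("."):
        node = node[part]
    return node


@pytest.mark.parametrize("path,expected", sorted(EXPECTED_DEFAULTS.items()))
def test_default_reproduces_published_inputs(params, path, expected):
    assert _lookup(params, path) == pytest.approx(expected)


def test_empty_config_yields_defaults(params):
    assert load_parameters({}) == params
    assert load_parameters(None) == params


def test_yaml_round_trip(params):
    assert ParameterSet.from_yaml(params.to_yaml()) == params


def test_override_returns_new_set_and_leaves_original(params):
    new = apply_override(params, "costs.cost_per_biopsy", 82 * 1.10)
    assert new.costs.cost_per_biopsy == pytest.approx(90.2)
    assert params.costs.cost_per_biopsy == 82
    assert new.epidemiology == params.epidemiology


def test_override_accepts_section_aliases(params):
    low = apply_override(params, "econ.discount_rate", 0.02)
    assert low.economics.discount_rate == 0.02
    assert apply_override(params, "cost.cost_per_biopsy", 90.2).costs.cost_per_biopsy == 90.2


def test_unknown_path_lists_valid_paths(params):
    with pytest.raises(UnknownParameterError, match="valid paths"):
        apply_override(params, "nonexistent.x", 1)
    assert "costs.cost_per_biopsy" in valid_parameter_paths()


@pytest.mark.parametrize(
    "path,value",
    [
        ("accuracy.per_patient_sens", 1.2),
        ("economics.discount_rate", -0.01),
        ("procedure.biopsies_nbi", 9.9),  # would exceed the Seattle-protocol count
        ("epidemiology.parasa.hg", 9999),  # breaks lg+hg+eac = dysplastic
        ("procedure.ae_exposure_basis", "per_lesion"),
        ("economics.perspective", "societal"),
    ],
)
def test_invariant_violations_rejected(params, path, value):
    with pytest.raises(ParameterValidationError):
        apply_override(params, path, value)


def test_unknown_config_field_rejected():
    with pytest.raises(ConfigurationError, match="unknown field"):
        load_parameters({"costs": {"tariff_endoscopy": 517, "typo_field": 1}})


def test_zero_discount_gives_unit_factors():
    from besurv.cohort import discount_factors

    zero = apply_override(default_parameters(), "economics.discount_rate", 0.0)
    assert (discount_factors(zero.economics.discount_rate, 7) == 1.0).all()
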