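"""Decision-tree layer: disease mix, classification, treatments, AEs."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from besurv.diagnostic_pathway import (
    ArmSpec,
    adverse_events,
    blended_biopsies_per_procedure,
    build_arms,
    classify_patients,
    disease_mix,
    treatment_counts,
)
from besurv.parameters import AERates, ParasaCounts

CUM_POP = 161_657 * (1.2**7 - 1) / 0.2  # exact 7-year cohort


def test_disease_mix_reproduces_published_proportions(params):
    mix = disease_mix(params.epidemiology.parasa)
    assert mix.nd == pytest.approx(0.664, abs=5e-4)  # printed 66.4%
    assert mix.lg / mix.dysplastic == pytest.approx(0.830, abs=5e-4)  # 83.0% of dysplastic
    assert mix.hg == pytest.approx(106 / 2696)
    assert sum(mix.as_tuple()) == pytest.approx(1.0, abs=1e-12)


def test_disease_mix_rejects_inconsistent_counts():
    with pytest.raises(Exception):
        disease_mix(ParasaCounts(total=100, dysplastic=150, lg=100, hg=40, eac=10))


@given(
    lg=st.integers(0, 500), hg=st.integers(0, 500), eac=st.integers(0, 500),
    nd=st.integers(0, 2000),
)
def test_disease_mix_normalizes(nd, lg, hg, eac):
    dys = lg + hg + eac
    if dys + nd == 0:
        return
    mix = disease_mix(ParasaCounts(total=nd + dys, dysplastic=dys, lg=lg, hg=hg, eac=eac))
    assert sum(mix.as_tuple()) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "share,expected", [(1.0, 3.6), (0.0, 7.6), (0.84, 4.24)]
)
def test_blended_biopsies(share, expected):
    assert blended_biopsies_per_procedure(share, 3.6, 7.6) == pytest.approx(expected)


def test_perfect_test_has_no_errors(params):
    mix = disease_mix(params.epidemiology.parasa)
    cls = classify_patients(1000.0, mix, sens=1.0, spec=1.0)
    assert cls.missed_dysplastic == 0
    assert cls.false_positives == 0
    assert cls.correctly_identified == pytest.approx(1000.0)


def test_detected_hg_matches_eradication_convention(params):
    """Detected HG over the 7-year cohort is the published eradication count."""
    mix = disease_mix(params.epidemiology.parasa)
    cls = classify_patients(CUM_POP, mix, sens=0.942, spec=0.944)
    assert cls.detected_hg == pytest.approx(CUM_POP * 106 / 2696 * 0.942)
    assert round(cls.detected_hg) == 77_331


def test_false_positive_count(params):
    mix = disease_mix(params.epidemiology.parasa)
    cls = classify_patients(CUM_POP, mix, sens=0.942, spec=0.944)
    assert cls.false_positives == pytest.approx(CUM_POP * 1791 / 2696 * 0.056, rel=1e-12)


@given(
    cohort=st.floats(0, 1e7),
    sens=st.floats(0, 1),
    spec=st.floats(0, 1),
)
def test_patient_conservation(params, cohort, sens, spec):
    mix = disease_mix(params.epidemiology.parasa)
    cls = classify_patients(cohort, mix, sens, spec)
    assert cls.total == pytest.approx(cohort, rel=1e-12, abs=1e-9)


def test_monotonic_in_accuracy(params):
    mix = disease_mix(params.epidemiology.parasa)
    lo = classify_patients(1000.0, mix, sens=0.6, spec=0.9)
    hi = classify_patients(1000.0, mix, sens=0.9, spec=0.9)
    assert hi.detected_dysplastic > lo.detected_dysplastic
    tighter = classify_patients(1000.0, mix, sens=0.9, spec=0.99)
    assert tighter.false_positives < hi.false_positives


def test_outputs_linear_in_cohort(params):
    mix = disease_mix(params.epidemiology.parasa)
    a = classify_patients(1.0, mix, 0.942, 0.944)
    b = classify_patients(2500.0, mix, 0.942, 0.944)
    assert b.detected_hg == pytest.approx(2500 * a.detected_hg, rel=1e-12)
    assert b.false_positives == pytest.approx(2500 * a.false_positives, rel=1e-12)


def test_histology_layer_filters_false_positives(params):
    mix = disease_mix(params.epidemiology.parasa)
    plain = classify_patients(1000.0, mix, 0.942, 0.944)
    confirmed = classify_patients(
        1000.0, mix, 0.942, 0.944, hist_sens=1.0, hist_spec=0.629, hist_layer_enabled=True
    )
    assert confirmed.false_positives == pytest.approx(plain.false_positives * (1 - 0.629))
    assert confirmed.detected_dysplastic == pytest.approx(plain.detected_dysplastic)
    assert confirmed.total == pytest.approx(1000.0)


def test_treatment_counts_conventions(params):
    mix = disease_mix(params.epidemiology.parasa)
    cls = classify_patients(CUM_POP, mix, 0.942, 0.944)
    trt = treatment_counts(cls, 0.949)
    assert trt.treated == pytest.approx(cls.detected_hg + cls.detected_eac)
    assert round(trt.reported_successful_eradications) == 77_331
    assert trt.strict_successes == pytest.approx(cls.detected_hg * 0.949)
    nothing = treatment_counts(classify_patients(1000.0, mix, 0.0, 0.944), 0.949)
    assert nothing.treated == 0


def _arm(endo: AERates, treat: AERates, bpp: float = 4.24) -> ArmSpec:
    return ArmSpec(
        name="x", nbi_share=0.84, sens=0.942, spec=0.944,
        biopsies_per_procedure=bpp, endo_ae=endo, treat_ae=treat, adopts_nbi=True,
    )


def test_blended_perforation_rate(params):
    nbi, _ = build_arms(params)
    assert nbi.endo_ae.perforation == pytest.approx(0.84 * 0.014 + 0.16 * 0.030)
    assert nbi.endo_ae.perforation == pytest.approx(0.01656)


def test_wle_per_procedure_perforations(params):
    _, wle = build_arms(params)
    aes = adverse_events(wle, 1000.0, 0.0, "per_procedure")
    assert aes.endoscopy["perforation"] == pytest.approx(30.0)


def test_zero_rates_give_empty_profile():
    zero = AERates(0.0, 0.0, 0.0)
    aes = adverse_events(_arm(zero, zero), 1000.0, 50.0, "per_procedure")
    assert all(v == 0 for v in aes.totals().values())


def test_exposure_bases(params):
    nbi, _ = build_arms(params)
    per_proc = adverse_events(nbi, 1000.0, 10.0, "per_procedure")
    per_biopsy = adverse_events(nbi, 1000.0, 10.0, "per_biopsy")
    per_treated = adverse_events(nbi, 1000.0, 10.0, "per_treated")
    assert per_biopsy.endoscopy["bleeding"] == pytest.approx(
        per_proc.endoscopy["bleeding"] * 4.24
    )
    assert per_treated.endoscopy["bleeding"] == pytest.approx(
        nbi.endo_ae.bleeding * 10.0
    )
    # treatment AEs are exposure-independent
    for profile in (per_proc, per_biopsy, per_treated):
        assert profile.treatment["stricture"] == pytest.approx(0.335 * 10.0)
    with pytest.raises(ValueError, match="exposure basis"):
        adverse_events(nbi, 1000.0, 10.0, "per_lesion")


def test_nbi_endoscopy_ae_burden_not_above_wle(params):
    """Blended rates cannot exceed the pure Seattle-protocol rates."""
    nbi, wle = build_arms(params)
    for t in ("stricture", "perforation", "bleeding"):
        assert getattr(nbi.endo_ae, t) <= getattr(wle.endo_ae, t)


def test_per_lesion_arms_are_technique_specific(params):
    nbi, wle = build_arms(params, accuracy_level="per_lesion")
    assert wle.sens == 0.791
    assert nbi.sens == pytest.approx(0.84 * 0.890 + 0.16 * 0.791)
    assert nbi.sens > wle.sens
    with pytest.raises(ValueError):
        build_arms(params, accuracy_level="per_slide")
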