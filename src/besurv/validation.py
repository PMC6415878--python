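"""Cohort-model expectations in per-patient units, for oracle comparison.

The microsimulation reports per-patient sample means; these helpers compute
the matching analytic expectations from the cohort engine so that
:func:`besurv.microsim.validate_against_cohort` can compare them statistic
by statistic.
"""

from __future__ import annotations

from .diagnostic_pathway import (
    AE_TYPES,
    ArmSpec,
    adverse_events,
    build_arms,
    classify_with_arm,
    disease_mix,
    treatment_counts,
)
from .parameters import ParameterSet
from .progression import SurveillancePlan, default_transition_matrix, long_term_trace

__all__ = ["cohort_expectations_per_patient", "cohort_expectations_long_term"]


def cohort_expectations_per_patient(
    params: ParameterSet, arm: ArmSpec | None = None
) -> dict[str, float]:
    """Expected per-patient diagnostic-phase statistics for one arm."""
    if arm is None:
        arm = build_arms(params)[0]
    cls = classify_with_arm(1.0, disease_mix(params.epidemiology.parasa), arm, params.accuracy)
    trt = treatment_counts(cls, params.procedure.eradication_rate)
    aes = adverse_events(
        arm, 1.0, trt.treated, params.procedure.ae_exposure_basis,
        total_biopsies=arm.biopsies_per_procedure,
    )
    costs = params.costs
    expected_cost = (
        costs.tariff_endoscopy
        + arm.biopsies_per_procedure * costs.cost_per_biopsy
        + trt.treated * costs.tariff_emr_rfa
        + sum(aes.total(t) * costs.ae_costs[t] for t in AE_TYPES)
    )
    out = {
        "biopsies": arm.biopsies_per_procedure,
        "detected_lg": cls.detected_lg,
        "detected_hg": cls.detected_hg,
        "detected_eac": cls.detected_eac,
        "false_positives": cls.false_positives,
        "true_negatives": cls.true_negatives,
        "missed_dysplastic": cls.missed_dysplastic,
        "treated": trt.treated,
        "eradicated": trt.strict_successes,
        "cost": expected_cost,
    }
    for t in AE_TYPES:
        out[f"endo_ae_{t}"] = aes.endoscopy[t]
        out[f"treat_ae_{t}"] = aes.treatment[t]
    return out


def cohort_expectations_long_term(
    params: ParameterSet, arm: ArmSpec | None = None, cycles: int = 14
) -> dict[str, float]:
    """Expected per-patient long-term statistics (Markov walk included)."""
    if arm is None:
        arm = build_arms(params)[0]
    cls = classify_with_arm(1.0, disease_mix(params.epidemiology.parasa), arm, params.accuracy)
    lt = long_term_trace(
        cls,
        SurveillancePlan(),
        default_transition_matrix(),
        arm.sens,
        params.procedure.eradication_rate,
        cycles=cycles,
    )
    return {
        "surveillance_endoscopies": lt.total_surveillance_endoscopies,
        "followup_treatments": float(lt.followup_treatments.sum()),
        "incident_eac": lt.cumulative_incident_eac,
    }
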