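"""Result products: cost-consequence, budget impact, ICER, scenario grid.

The engine runs each comparator arm through the same pipeline: project the
annual cohort, classify it at the index endoscopy, count biopsies,
treatments and adverse events, optionally follow each entry cohort through
the 6-month Markov model for the remaining horizon (long-term scenarios),
then cost every flow under the chosen perspective. The two arms always share
the cohort trace, so differences isolate the technology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import costing
from .cohort import CohortTrace, build_trace
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
from .progression import (
    SurveillancePlan,
    default_transition_matrix,
    long_term_trace,
)

__all__ = [
    "ConsequenceBreakdown",
    "ArmResult",
    "CostConsequenceResult",
    "ICERResult",
    "ScenarioSpec",
    "ScenarioResult",
    "SCENARIOS",
    "run_arm",
    "cost_consequence",
    "budget_impact",
    "icer",
    "run_scenario",
]


@dataclass(frozen=True)
class ConsequenceBreakdown:
    """Undiscounted clinical event counts for one arm over the horizon."""

    correctly_identified: float
    successful_eradications: float
    biopsies: float
    strictures: float
    bleedings: float
    perforations: float
    detected_lesions: float
    incident_eac: float | None = None  # long-term scenarios only
    incident_eac_year1_cohort: float | None = None

    _ROWS = (
        "correctly_identified",
        "successful_eradications",
        "biopsies",
        "strictures",
        "bleedings",
        "perforations",
    )

    def as_series(self) -> pd.Series:
        data = {name: getattr(self, name) for name in self._ROWS}
        if self.incident_eac is not None:
            data["incident_eac"] = self.incident_eac
        return pd.Series(data)


@dataclass(frozen=True)
class ArmResult:
    """Everything computed for one arm under one scenario."""

    arm: ArmSpec
    trace: CohortTrace
    cost: costing.CostBreakdown
    consequences: ConsequenceBreakdown


def run_arm(
    params: ParameterSet,
    arm: ArmSpec,
    *,
    perspective: str | None = None,
    long_term: bool | None = None,
) -> ArmResult:
    """Run the full pipeline for one arm."""
    econ = params.economics
    perspective = perspective if perspective is not None else econ.perspective
    long_term = long_term if long_term is not None else econ.long_term
    epi = params.epidemiology
    costs = params.costs

    n1 = epi.n_year1 if perspective == "nhs" else epi.hospital_cohort
    trace = build_trace(n1, epi.annual_growth, epi.horizon_years, econ.discount_rate)
    T = trace.years
    pop = trace.populations
    factors = trace.factors

    mix = disease_mix(epi.parasa)
    cls1 = classify_with_arm(1.0, mix, arm, params.accuracy)  # per-patient expected rates
    trt1 = treatment_counts(cls1, params.procedure.eradication_rate)

    procedures = pop.copy()  # index endoscopies per year
    treated = trt1.treated * pop
    biopsies = pop * arm.biopsies_per_procedure
    profiles = [
        adverse_events(
            arm,
            pop[t],
            treated[t],
            params.procedure.ae_exposure_basis,
            total_biopsies=biopsies[t],
        )
        for t in range(T)
    ]

    cancer_patient_cycles = np.zeros(T)
    incident_eac_total: float | None = None
    incident_eac_year1: float | None = None

    if long_term:
        plan = SurveillancePlan()
        matrix = default_transition_matrix()
        incident_eac_total = 0.0
        surv_endo = np.zeros(T)
        fu_treat = np.zeros(T)
        for t in range(T):  # entry year t (0-based) followed to end of horizon
            cycles = 2 * (T - t)
            lt = long_term_trace(
                cls1.scaled(pop[t]),
                plan,
                matrix,
                arm.sens,
                params.procedure.eradication_rate,
                cycles=cycles,
            )
            incident_eac_total += lt.cumulative_incident_eac
            if t == 0:
                incident_eac_year1 = lt.cumulative_incident_eac
            for c in range(1, cycles + 1):
                year = t + (c - 1) // 2
                surv_endo[year] += lt.surveillance_endoscopies[c - 1]
                fu_treat[year] += lt.followup_treatments[c - 1]
                cancer_patient_cycles[year] += lt.diagnosed_eac_prevalence[c - 1]
        procedures = procedures + surv_endo
        treated = treated + fu_treat
        biopsies = biopsies + surv_endo * arm.biopsies_per_procedure
        profiles = [
            profiles[t]
            + adverse_events(
                arm,
                surv_endo[t],
                fu_treat[t],
                params.procedure.ae_exposure_basis,
                total_biopsies=surv_endo[t] * arm.biopsies_per_procedure,
            )
            for t in range(T)
        ]

    # ---- money -----------------------------------------------------------
    endo_cost, treat_cost = costing.procedure_costs(
        procedures, treated, perspective, arm, costs, factors
    )
    histo = costing.histopathology_cost(biopsies, costs.cost_per_biopsy, factors)
    ae_total = costing.ae_costs(profiles, costs.ae_costs, factors)
    plan_cap = costing.capital_equipment_cost(
        arm,
        params.equipment,
        T,
        hospitals=1.0 if perspective == "hospital" else None,
    )
    capital_per_year = plan_cap.amortized_per_year + plan_cap.replacement_per_year
    if perspective == "hospital":
        capital_per_year = capital_per_year + plan_cap.maintenance_per_year
    cancer_per_year = cancer_patient_cycles * (costs.cancer_cost_per_year / 2.0)

    # per-year discounted split (pro-rata for the summed categories)
    endo_y = procedures * factors
    endo_y = endo_y / endo_y.sum() * endo_cost if endo_cost else np.zeros(T)
    treat_w = treated * factors
    treat_y = treat_w / treat_w.sum() * treat_cost if treat_cost else np.zeros(T)
    histo_w = biopsies * factors
    histo_y = histo_w / histo_w.sum() * histo if histo else np.zeros(T)
    ae_w = np.array(
        [sum(p.total(k) * costs.ae_costs[k] for k in AE_TYPES) for p in profiles]
    ) * factors
    ae_y = ae_w / ae_w.sum() * ae_total if ae_total else np.zeros(T)
    per_year = pd.DataFrame(
        {
            "endoscopy_staff_overheads": endo_y,
            "treatment_staff_overheads": treat_y,
            "histopathology": histo_y,
            "adverse_events": ae_y,
            "capital_equipment": capital_per_year * factors,
            "cancer_management": cancer_per_year * factors,
        },
        index=pd.RangeIndex(1, T + 1, name="year"),
    )
    income = None
    if perspective == "hospital":
        income = float(
            (
                (procedures * costs.tariff_endoscopy + treated * costs.tariff_emr_rfa)
                * factors
            ).sum()
        )
    cost = costing.CostBreakdown(per_year=per_year, income=income)

    # ---- counts (undiscounted) ------------------------------------------
    cum = trace.cumulative
    ae_counts = {t: sum(p.total(t) for p in profiles) for t in AE_TYPES}
    lam = params.accuracy.lesions_per_dysplastic
    consequences = ConsequenceBreakdown(
        correctly_identified=cls1.correctly_identified * cum,
        successful_eradications=trt1.reported_successful_eradications * cum,
        biopsies=float(biopsies.sum()),
        strictures=ae_counts["stricture"],
        bleedings=ae_counts["bleeding"],
        perforations=ae_counts["perforation"],
        detected_lesions=mix.dysplastic * arm.sens * lam * cum,
        incident_eac=incident_eac_total,
        incident_eac_year1_cohort=incident_eac_year1,
    )
    return ArmResult(arm=arm, trace=trace, cost=cost, consequences=consequences)


@dataclass(frozen=True)
class CostConsequenceResult:
    """Paired arm results with absolute and relative differences."""

    nbi: ArmResult
    hdwle: ArmResult

    @property
    def total_cost_difference(self) -> float:
        return self.nbi.cost.grand_total - self.hdwle.cost.grand_total

    def cost_table(self) -> pd.DataFrame:
        rows = {}
        for cat in costing.CATEGORIES:
            a = self.nbi.cost.categories[cat]
            b = self.hdwle.cost.categories[cat]
            rows[cat] = (a, b)
        rows["total_costs"] = (self.nbi.cost.grand_total, self.hdwle.cost.grand_total)
        return _diff_frame(rows)

    def consequence_table(self) -> pd.DataFrame:
        a = self.nbi.consequences.as_series()
        b = self.hdwle.consequences.as_series()
        return _diff_frame({k: (a[k], b[k]) for k in a.index})

    def table(self) -> pd.DataFrame:
        return pd.concat([self.cost_table(), self.consequence_table()])


def _diff_frame(rows: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["nbi", "hdwle"])
    out["abs_diff"] = out["nbi"] - out["hdwle"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(out["hdwle"] != 0, out["abs_diff"] / out["hdwle"], np.nan)
    out["rel_diff"] = rel
    out.index.name = "category"
    return out


def cost_consequence(
    params: ParameterSet,
    *,
    accuracy_level: str | None = None,
    perspective: str | None = None,
    long_term: bool | None = None,
) -> CostConsequenceResult:
    """Run both arms on the shared cohort trace and tabulate differences."""
    nbi_arm, wle_arm = build_arms(params, accuracy_level)
    kwargs = dict(perspective=perspective, long_term=long_term)
    return CostConsequenceResult(
        nbi=run_arm(params, nbi_arm, **kwargs),
        hdwle=run_arm(params, wle_arm, **kwargs),
    )


def budget_impact(
    params: ParameterSet, cc: CostConsequenceResult | None = None
) -> pd.DataFrame:
    """Year-by-year payer expenditure per arm, with the population column.

    The Total row equals the cost-consequence grand totals by construction.
    """
    if cc is None:
        cc = cost_consequence(params)
    trace = cc.nbi.trace
    nbi_y = cc.nbi.cost.yearly_totals
    wle_y = cc.hdwle.cost.yearly_totals
    table = pd.DataFrame(
        {
            "population": trace.populations_rounded,
            "nbi_cost": nbi_y,
            "hdwle_cost": wle_y,
            "difference": nbi_y - wle_y,
        },
        index=pd.RangeIndex(1, trace.years + 1, name="year"),
    )
    total = pd.DataFrame(
        {
            "population": [trace.cumulative_rounded],
            "nbi_cost": [nbi_y.sum()],
            "hdwle_cost": [wle_y.sum()],
            "difference": [nbi_y.sum() - wle_y.sum()],
        },
        index=pd.Index(["total"], name="year"),
    )
    return pd.concat([table, total])


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness statement."""

    delta_cost: float
    delta_effect: float
    ratio: float | None
    label: str

    def ratio_thousands(self, sig: int = 3) -> float | None:
        """The ratio in thousands of GBP, rounded to ``sig`` significant figures."""
        if self.ratio is None:
            return None
        k = self.ratio / 1000.0
        if k == 0:
            return 0.0
        exp = sig - 1 - math.floor(math.log10(abs(k)))
        return round(k, exp)


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost per incremental unit of effect, with dominance labels."""
    if delta_effect == 0:
        if delta_cost == 0:
            label = "equivalent"
        elif delta_cost < 0:
            label = "cost-saving-equal-effect"
        else:
            label = "cost-increasing-equal-effect"
        return ICERResult(delta_cost, delta_effect, None, label)
    ratio = delta_cost / delta_effect
    if delta_cost < 0 and delta_effect > 0:
        label = "dominant"
    elif delta_cost > 0 and delta_effect < 0:
        label = "dominated"
    else:
        label = "icer"
    return ICERResult(delta_cost, delta_effect, ratio, label)


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario grid."""

    id: int
    accuracy_level: str  # per_patient | per_lesion
    perspective: str  # nhs | hospital
    long_term: bool

    def __post_init__(self) -> None:
        if self.perspective == "hospital" and self.long_term:
            raise ValueError(
                "long-term follow-up is defined for the NHS perspective only"
            )

    @property
    def description(self) -> str:
        fu = "long-term consequences considered" if self.long_term else "long-term consequences not considered"
        return f"{self.perspective.upper()} perspective; {self.accuracy_level} accuracy; {fu}"


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, "per_patient", "nhs", False),
    2: ScenarioSpec(2, "per_patient", "nhs", True),
    3: ScenarioSpec(3, "per_lesion", "nhs", False),
    4: ScenarioSpec(4, "per_lesion", "nhs", True),
    5: ScenarioSpec(5, "per_patient", "hospital", False),
    6: ScenarioSpec(6, "per_lesion", "hospital", False),
}


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    cc: CostConsequenceResult
    delta_cost: float
    effect_name: str
    delta_effect: float
    icer: ICERResult
    margin_difference: float | None  # hospital perspective only

    def summary(self) -> dict[str, object]:
        out = {
            "scenario": self.spec.id,
            "description": self.spec.description,
            "nbi_cost": self.cc.nbi.cost.grand_total,
            "hdwle_cost": self.cc.hdwle.cost.grand_total,
            "cost_difference": self.delta_cost,
            "effect_name": self.effect_name,
            "effect_difference": self.delta_effect,
            "icer_label": self.icer.label,
            "icer": self.icer.ratio,
        }
        if self.margin_difference is not None:
            out["margin_difference"] = self.margin_difference
        return out


def run_scenario(spec: ScenarioSpec | int, params: ParameterSet) -> ScenarioResult:
    """Run one scenario of the grid and derive its ICER statement."""
    if isinstance(spec, int):
        if spec not in SCENARIOS:
            raise ValueError(f"unknown scenario id {spec}; defined scenarios: 1..6")
        spec = SCENARIOS[spec]
    spec.__post_init__()  # re-check consistency for hand-built specs
    cc = cost_consequence(
        params,
        accuracy_level=spec.accuracy_level,
        perspective=spec.perspective,
        long_term=spec.long_term,
    )
    delta_cost = cc.total_cost_difference
    if spec.accuracy_level == "per_patient":
        effect_name, delta_effect = "equal_effect", 0.0
    elif spec.long_term:
        effect_name = "avoided_cancer_cases"
        delta_effect = (
            cc.hdwle.consequences.incident_eac - cc.nbi.consequences.incident_eac
        )
    else:
        effect_name = "incremental_detected_lesions"
        delta_effect = (
            cc.nbi.consequences.detected_lesions - cc.hdwle.consequences.detected_lesions
        )
    margin_diff = None
    if spec.perspective == "hospital":
        margin_diff = cc.nbi.cost.margin - cc.hdwle.cost.margin
    return ScenarioResult(
        spec=spec,
        cc=cc,
        delta_cost=delta_cost,
        effect_name=effect_name,
        delta_effect=delta_effect,
        icer=icer(delta_cost, delta_effect),
        margin_difference=margin_diff,
    )
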