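"""Individual-patient microsimulation: the verification oracle.

The cohort engine computes expected values analytically; this module draws
individual patients with exactly the same probabilistic structure — true
state from the entry distribution, technique by market share within the
mixed arm, detection as a Bernoulli trial on the arm's sensitivity or
specificity, biopsies by technique, adverse events as Bernoulli trials, and
(in long-term mode) a 6-month Markov walk with surveillance re-detection.
Sample means scaled to the cohort size must agree with every cohort
expectation within sampling error; :func:`validate_against_cohort` flags any
statistic outside mean ± 3 standard errors.

Draws are fully vectorized from a single numpy Generator seeded by the
caller, so results are reproducible given (n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostic_pathway import AE_TYPES, ArmSpec, disease_mix
from .parameters import ParameterSet
from .progression import SurveillancePlan, default_transition_matrix

__all__ = [
    "PatientRecords",
    "simulate_patients",
    "aggregate",
    "validate_against_cohort",
]

_ND, _LG, _HG, _EAC = range(4)
_POOL_BELIEVED_ND, _POOL_DX_LG, _POOL_DX_HG, _POOL_DX_EAC = range(4)


@dataclass(frozen=True)
class PatientRecords:
    """Column-wise records of simulated patients."""

    n: int
    seed: int
    mode: str
    arm_name: str
    true_state: np.ndarray  # entry state, 0..3
    uses_nbi: np.ndarray  # bool, technique at index endoscopy
    diagnosed_dysplastic: np.ndarray  # bool, index test positive
    biopsies: np.ndarray  # float, technique-specific count at index
    endo_ae: dict[str, np.ndarray]  # bool per type
    treat_ae: dict[str, np.ndarray]
    treated: np.ndarray  # bool (index treatment: detected HG or EAC)
    eradicated: np.ndarray  # bool (treated HG with successful eradication)
    cost: np.ndarray  # GBP accrued per patient (undiscounted, NHS unit costs)
    # long-term mode only (zeros otherwise)
    surveillance_endoscopies: np.ndarray
    followup_treatments: np.ndarray
    incident_eac: np.ndarray  # bool, entered EAC during follow-up
    trajectory_final_state: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {
            "true_state": self.true_state,
            "uses_nbi": self.uses_nbi,
            "diagnosed_dysplastic": self.diagnosed_dysplastic,
            "biopsies": self.biopsies,
            "treated": self.treated,
            "eradicated": self.eradicated,
            "cost": self.cost,
            "surveillance_endoscopies": self.surveillance_endoscopies,
            "followup_treatments": self.followup_treatments,
            "incident_eac": self.incident_eac,
            "final_state": self.trajectory_final_state,
        }
        for t in AE_TYPES:
            data[f"endo_ae_{t}"] = self.endo_ae[t]
            data[f"treat_ae_{t}"] = self.treat_ae[t]
        return pd.DataFrame(data)


def simulate_patients(
    n: int,
    seed: int,
    params: ParameterSet,
    mode: str = "diagnostic_only",
    *,
    arm: ArmSpec | None = None,
    cycles: int = 14,
) -> PatientRecords:
    """Simulate ``n`` i.i.d. patients through one arm's pathway.

    ``arm`` defaults to the NBI-adopting mixed arm under the parameter set's
    accuracy level. ``mode`` is ``diagnostic_only`` (index endoscopy only)
    or ``long_term`` (adds the Markov walk with surveillance re-detection
    over ``cycles`` 6-month cycles).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mode not in ("diagnostic_only", "long_term"):
        raise ValueError(f"unknown mode {mode!r}")
    if arm is None:
        from .diagnostic_pathway import build_arms

        arm = build_arms(params)[0]

    rng = np.random.default_rng(seed)
    mix = disease_mix(params.epidemiology.parasa)
    proc = params.procedure
    costs = params.costs

    state = rng.choice(4, size=n, p=mix.as_tuple())
    uses_nbi = rng.random(n) < arm.nbi_share

    # detection at the index endoscopy: binary dysplastic-vs-not accuracy
    dysplastic = state > _ND
    u = rng.random(n)
    diagnosed = np.where(dysplastic, u < arm.sens, u < (1.0 - arm.spec))

    biopsies = np.where(uses_nbi, proc.biopsies_nbi, proc.biopsies_wle).astype(float)

    endo_ae: dict[str, np.ndarray] = {}
    for t in AE_TYPES:
        rate = np.where(
            uses_nbi, getattr(proc.endo_ae_nbi, t), getattr(proc.endo_ae_wle, t)
        )
        endo_ae[t] = rng.random(n) < rate

    treated = diagnosed & ((state == _HG) | (state == _EAC))
    treat_ae = {t: treated & (rng.random(n) < getattr(proc.treat_ae, t)) for t in AE_TYPES}
    eradicated = treated & (state == _HG) & (rng.random(n) < proc.eradication_rate)

    surv_endo = np.zeros(n)
    fu_treat = np.zeros(n)
    incident = np.zeros(n, dtype=bool)
    final_state = state.copy()
    cancer_cycles = np.zeros(n)

    if mode == "long_term":
        final_state, surv_endo, fu_treat, incident, cancer_cycles = _walk_long_term(
            rng, state, diagnosed, eradicated, treated, arm, params, cycles
        )

    cost = (
        costs.tariff_endoscopy
        + biopsies * costs.cost_per_biopsy
        + treated * costs.tariff_emr_rfa
        + surv_endo * (costs.tariff_endoscopy + biopsies * costs.cost_per_biopsy)
        + fu_treat * costs.tariff_emr_rfa
        + cancer_cycles * costs.cancer_cost_per_year / 2.0
    )
    for t in AE_TYPES:
        cost = cost + (endo_ae[t] + treat_ae[t]) * costs.ae_costs[t]

    return PatientRecords(
        n=n,
        seed=seed,
        mode=mode,
        arm_name=arm.name,
        true_state=state,
        uses_nbi=uses_nbi,
        diagnosed_dysplastic=diagnosed,
        biopsies=biopsies,
        endo_ae=endo_ae,
        treat_ae=treat_ae,
        treated=treated,
        eradicated=eradicated,
        cost=cost,
        surveillance_endoscopies=surv_endo,
        followup_treatments=fu_treat,
        incident_eac=incident,
        trajectory_final_state=final_state,
    )


def _walk_long_term(
    rng: np.random.Generator,
    state0: np.ndarray,
    diagnosed: np.ndarray,
    eradicated: np.ndarray,
    treated: np.ndarray,
    arm: ArmSpec,
    params: ParameterSet,
    cycles: int,
):
    """Vectorized Markov walk mirroring progression.long_term_trace."""
    n = len(state0)
    matrix = default_transition_matrix().probs
    cum = matrix.cumsum(axis=1)
    plan = SurveillancePlan()
    erad_rate = params.procedure.eradication_rate
    sens = arm.sens

    state = state0.copy()
    # initial pool assignment (mirrors progression._initial_pools)
    pool = np.full(n, _POOL_BELIEVED_ND)
    pool[diagnosed & (state0 == _LG)] = _POOL_DX_LG
    pool[~diagnosed & (state0 == _ND)] = _POOL_BELIEVED_ND
    fp = diagnosed & (state0 == _ND)
    pool[fp] = _POOL_DX_LG  # false positives are labelled LG
    treated_hg = treated & (state0 == _HG)
    pool[treated_hg & ~eradicated] = _POOL_DX_HG
    pool[treated_hg & eradicated] = _POOL_BELIEVED_ND
    state[treated_hg & eradicated] = _ND  # eradication resets the disease
    pool[diagnosed & (state0 == _EAC)] = _POOL_DX_EAC

    visit_every = {
        _POOL_BELIEVED_ND: plan.nd_months // 6,
        _POOL_DX_LG: plan.lg_months // 6,
        _POOL_DX_HG: plan.hg_post_months // 6,
        _POOL_DX_EAC: plan.eac_post_months // 6,
    }

    surv_endo = np.zeros(n)
    fu_treat = np.zeros(n)
    incident = np.zeros(n, dtype=bool)
    cancer_cycles = np.zeros(n)

    for c in range(1, cycles + 1):
        # progression draw
        u = rng.random(n)
        state = (u[:, None] > cum[state]).sum(axis=1)
        newly_eac = (state == _EAC) & ~incident & (state0 != _EAC)
        incident |= newly_eac

        # surveillance visits
        visits = np.zeros(n, dtype=bool)
        for p, k in visit_every.items():
            if c % k == 0:
                visits |= pool == p
        surv_endo += visits

        det = visits & (rng.random(n) < sens)
        # believed-ND: any dysplasia detectable; dx_lg: HG/EAC; dx_hg: EAC
        found_lg = det & (pool == _POOL_BELIEVED_ND) & (state == _LG)
        found_hg = det & (pool <= _POOL_DX_LG) & (state == _HG)
        found_eac = det & (pool <= _POOL_DX_HG) & (state == _EAC)

        pool[found_lg] = _POOL_DX_LG
        erad_now = found_hg & (rng.random(n) < erad_rate)
        pool[found_hg & ~erad_now] = _POOL_DX_HG
        pool[erad_now] = _POOL_BELIEVED_ND
        state[erad_now] = _ND
        pool[found_eac] = _POOL_DX_EAC
        fu_treat += found_hg + found_eac

        cancer_cycles += pool == _POOL_DX_EAC

    return state, surv_endo, fu_treat, incident, cancer_cycles


@dataclass(frozen=True)
class AggregateEstimates:
    """Microsim estimates scaled to a cohort, with standard errors."""

    estimates: pd.DataFrame  # index statistic, columns value/se
    cohort_size: float
    n: int

    def value(self, statistic: str) -> float:
        return float(self.estimates.loc[statistic, "value"])

    def se(self, statistic: str) -> float:
        return float(self.estimates.loc[statistic, "se"])


def aggregate(records: PatientRecords, cohort_size: float = 1.0) -> AggregateEstimates:
    """Scale per-patient sample means to a cohort, with standard errors."""
    if records.n < 1:
        raise ValueError("cannot aggregate an empty record collection")
    state = records.true_state
    det = records.diagnosed_dysplastic
    columns: dict[str, np.ndarray] = {
        "biopsies": records.biopsies,
        "detected_lg": (det & (state == _LG)).astype(float),
        "detected_hg": (det & (state == _HG)).astype(float),
        "detected_eac": (det & (state == _EAC)).astype(float),
        "false_positives": (det & (state == _ND)).astype(float),
        "true_negatives": (~det & (state == _ND)).astype(float),
        "missed_dysplastic": (~det & (state > _ND)).astype(float),
        "treated": records.treated.astype(float),
        "eradicated": records.eradicated.astype(float),
        "cost": records.cost,
    }
    for t in AE_TYPES:
        columns[f"endo_ae_{t}"] = records.endo_ae[t].astype(float)
        columns[f"treat_ae_{t}"] = records.treat_ae[t].astype(float)
    if records.mode == "long_term":
        columns["surveillance_endoscopies"] = records.surveillance_endoscopies
        columns["followup_treatments"] = records.followup_treatments
        columns["incident_eac"] = records.incident_eac.astype(float)
    rows = {}
    for name, col in columns.items():
        mean = float(col.mean())
        se = float(col.std(ddof=1) / np.sqrt(records.n)) if records.n > 1 else 0.0
        if se < 1e-12 * max(1.0, abs(mean)):  # constant column: numerical dust
            se = 0.0
        rows[name] = {"value": mean * cohort_size, "se": se * cohort_size}
    return AggregateEstimates(
        estimates=pd.DataFrame.from_dict(rows, orient="index"),
        cohort_size=cohort_size,
        n=records.n,
    )


def validate_against_cohort(
    estimates: AggregateEstimates,
    cohort_expectations: dict[str, float],
    tolerance_se: float = 3.0,
) -> pd.DataFrame:
    """Compare cohort expectations with microsim estimates statistic by statistic.

    A statistic passes when the cohort expectation lies within
    mean ± tolerance_se x SE; degenerate (zero-variance) statistics require
    exact equality. Unknown statistic names raise KeyError.
    """
    rows = []
    for name, expected in cohort_expectations.items():
        if name not in estimates.estimates.index:
            raise KeyError(f"microsim does not report statistic {name!r}")
        value = estimates.value(name)
        se = estimates.se(name)
        if se == 0.0:
            passed = bool(np.isclose(value, expected, rtol=1e-12, atol=1e-9))
            z = 0.0 if passed else np.inf
        else:
            z = (value - expected) / se
            passed = bool(abs(z) <= tolerance_se)
        rows.append(
            {
                "statistic": name,
                "cohort_expectation": expected,
                "microsim_value": value,
                "se": se,
                "z": z,
                "pass": passed,
            }
        )
    return pd.DataFrame(rows).set_index("statistic")
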