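"""Costing layer: convert pathway/progression flows into cost categories.

Two perspectives are supported:

* **NHS**: tariffs for endoscopy and EMR+RFA are booked as payer costs,
  alongside histopathology, adverse-event management and capital equipment
  (systems, scopes, training, replacement). Staff and consumable micro-costs
  are excluded — they are covered under tariff.
* **Hospital**: procedures are micro-costed (staff time x hourly rates plus
  consumables), maintenance is added, and the tariffs are booked as income;
  the margin (income minus cost) is reported alongside.

Capital purchases for the NBI-adopting arm (system upgrades for non-NBI-
capable Olympus rooms, HD scope upgrades, endoscopist training) are
amortized as equal annual charges over the equipment lifetime and then
discounted like any other cost. Both arms accrue annual scope replacement;
the adopting arm applies it only to its non-upgraded (non-Olympus) share.

Money is discounted from year 2 at the annual rate; event counts are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostic_pathway import AE_TYPES, AEProfile, ArmSpec
from .parameters import CostParams, EquipmentParams

__all__ = [
    "CostBreakdown",
    "staff_cost_per_procedure",
    "histopathology_cost",
    "ae_costs",
    "capital_equipment_cost",
    "procedure_costs",
]

CATEGORIES = (
    "endoscopy_staff_overheads",
    "treatment_staff_overheads",
    "histopathology",
    "adverse_events",
    "capital_equipment",
    "cancer_management",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted GBP totals per category, with the per-year split."""

    per_year: pd.DataFrame  # years x categories, discounted GBP
    income: float | None = None  # hospital perspective: tariff income
    categories: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", {c: float(self.per_year[c].sum()) for c in self.per_year.columns})

    @property
    def grand_total(self) -> float:
        return float(sum(self.categories.values()))

    @property
    def yearly_totals(self) -> np.ndarray:
        return self.per_year.sum(axis=1).to_numpy()

    @property
    def margin(self) -> float | None:
        """Income minus cost (hospital perspective only)."""
        if self.income is None:
            return None
        return self.income - self.grand_total


def staff_cost_per_procedure(costs: CostParams, nbi_share: float) -> float:
    """Micro-costed staff cost of one endoscopy, market-share blended.

    Nurse non-contact time is the only technique-dependent component (it is
    proportional to the number of biopsies taken).
    """
    r = costs.staff_rates

    def one(times) -> float:
        return (
            times.admin * r.admin
            + times.nurse_noncontact * r.nurse_noncontact
            + times.consultant_ba * r.consultant_ba
            + times.nurse_contact * r.nurse_contact
            + times.consultant_during * r.consultant_during
        )

    return nbi_share * one(costs.staff_times_nbi) + (1 - nbi_share) * one(costs.staff_times_wle)


def histopathology_cost(
    biopsies_per_year: np.ndarray, cost_per_biopsy: float, factors: np.ndarray
) -> float:
    """Discounted histology cost: sum_t biopsies[t] x unit cost x factor[t]."""
    biopsies = np.asarray(biopsies_per_year, dtype=float)
    if (biopsies < 0).any() or cost_per_biopsy < 0:
        raise ValueError("biopsy counts and unit cost must be non-negative")
    return float((biopsies * cost_per_biopsy * np.asarray(factors)).sum())


def ae_costs(
    profiles_per_year: list[AEProfile], unit_costs: dict[str, float], factors: np.ndarray
) -> float:
    """Discounted adverse-event management cost over the horizon."""
    total = 0.0
    for profile, f in zip(profiles_per_year, factors, strict=True):
        total += sum(profile.total(t) * unit_costs[t] for t in AE_TYPES) * f
    return float(total)


@dataclass(frozen=True)
class CapitalPlan:
    """One arm's capital flows, per year, undiscounted GBP."""

    one_off_purchases: float  # systems + scopes + training, before amortization
    amortized_per_year: np.ndarray
    replacement_per_year: np.ndarray
    maintenance_per_year: np.ndarray  # charged in the hospital perspective only


def capital_equipment_cost(
    arm: ArmSpec,
    equipment: EquipmentParams,
    years: int,
    *,
    hospitals: float | None = None,
) -> CapitalPlan:
    """Capital flows for one arm.

    The adopting arm upgrades every Olympus room lacking an NBI-capable
    system, replaces the non-HD share of scopes in Olympus rooms, and trains
    half its endoscopists; purchases are spread evenly over the amortization
    horizon. The non-adopting arm only replaces worn scopes. ``hospitals``
    rescales the installed base (one hospital for the hospital perspective).
    """
    e = equipment
    H = e.hospitals if hospitals is None else hospitals
    rooms = H * e.rooms_per_hospital
    scopes = rooms * e.scopes_per_room

    if arm.adopts_nbi:
        systems_upgrade = rooms * e.olympus_share * (1.0 - e.nbi_capable_share) * e.unit_cost_system
        scope_upgrade = scopes * e.olympus_share * (1.0 - e.hd_scope_share) * e.unit_cost_scope
        training = (
            H
            * e.olympus_share
            * e.endoscopists_per_hospital
            * e.trained_share
            * e.training_days_nbi
            * e.training_cost_per_day_nbi
        )
        replacement_share = 1.0 - e.olympus_share  # non-upgraded estate keeps wearing out
        maint_system, maint_scope = e.maintenance_system_nbi, e.maintenance_scope_nbi
    else:
        systems_upgrade = scope_upgrade = 0.0
        training = (
            H
            * e.endoscopists_per_hospital
            * e.trained_share
            * e.training_days_wle
            * e.training_cost_per_day_wle
        )
        replacement_share = 1.0
        maint_system, maint_scope = e.maintenance_system_wle, e.maintenance_scope_wle

    one_off = systems_upgrade + scope_upgrade + training
    amortized = np.zeros(years)
    charge_years = min(years, e.amortization_years)
    amortized[:charge_years] = one_off / e.amortization_years
    replacement = np.full(years, scopes * replacement_share * e.replacement_rate * e.unit_cost_scope)
    maintenance = np.full(years, rooms * maint_system + scopes * maint_scope)
    return CapitalPlan(
        one_off_purchases=float(one_off),
        amortized_per_year=amortized,
        replacement_per_year=replacement,
        maintenance_per_year=maintenance,
    )


def procedure_costs(
    populations: np.ndarray,
    treated: np.ndarray,
    perspective: str,
    arm: ArmSpec,
    costs: CostParams,
    factors: np.ndarray,
) -> tuple[float, float]:
    """Discounted (endoscopy, treatment) procedure costs for one arm.

    NHS perspective: tariff outlays. Hospital perspective: micro-costs
    (staff plus consumables: one forceps per endoscopy, one snare per
    treatment); the tariffs enter as income elsewhere.
    """
    pop = np.asarray(populations, dtype=float)
    trt = np.asarray(treated, dtype=float)
    f = np.asarray(factors, dtype=float)
    if perspective == "nhs":
        endo_unit = costs.tariff_endoscopy
        treat_unit = costs.tariff_emr_rfa
    elif perspective == "hospital":
        staff = staff_cost_per_procedure(costs, arm.nbi_share)
        endo_unit = staff + costs.forceps_unit_cost
        treat_unit = staff + costs.snare_unit_cost
    else:
        raise ValueError(f"unknown perspective {perspective!r}; expected 'nhs' or 'hospital'")
    return float((pop * endo_unit * f).sum()), float((trt * treat_unit * f).sum())
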