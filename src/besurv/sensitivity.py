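"""Deterministic one-way sensitivity analysis and the equal-AE-rate analysis.

Each OWSA item names one parameter by its dotted path and a (low, high)
bound pair; the full base-case pipeline is re-run at each bound and items
are ranked by the range they induce in the outcome (the discounted total
cost difference, NBI minus HD-WLE). Default bounds are relative ±10% on the
parameter's natural scale, except the discount rate (2.0% / 5.0%);
probabilities are clipped to [0, 1] after scaling, with a warning.
Diagnostic-accuracy confidence-interval bounds are not part of the default
grid and should be supplied by the caller when available; absent that, the
accuracy items fall back to ±10% (also warned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .analyses import cost_consequence
from .parameters import ParameterSet, apply_override, valid_parameter_paths

__all__ = ["OWSAItem", "default_owsa_items", "owsa", "equal_ae_analysis"]

# parameters whose scaled bounds must stay inside [0, 1]
_PROBABILITY_PATHS_PREFIXES = (
    "accuracy.",
    "procedure.endo_ae_",
    "procedure.treat_ae",
    "procedure.eradication_rate",
    "economics.market_share_nbi",
)


@dataclass(frozen=True)
class OWSAItem:
    """One tornado bar: a parameter with its tested bounds and outcomes."""

    path: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float
    base_outcome: float

    @property
    def range(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _is_probability(path: str) -> bool:
    return any(path.startswith(p) for p in _PROBABILITY_PATHS_PREFIXES)


def _relative_bounds(params: ParameterSet, path: str, rel: float = 0.10) -> tuple[float, float]:
    node: object = params.to_dict()
    for part in path.split("."):
        node = node[part]  # type: ignore[index]
    base = float(node)  # type: ignore[arg-type]
    low, high = base * (1 - rel), base * (1 + rel)
    if _is_probability(path) and (low < 0 or high > 1):
        warnings.warn(
            f"OWSA bounds for probability {path} clipped to [0, 1]", stacklevel=3
        )
        low, high = max(low, 0.0), min(high, 1.0)
    return low, high


_DEFAULT_RELATIVE_PATHS = (
    # demographics
    "epidemiology.n_year1",
    "epidemiology.annual_growth",
    # accuracy (±10% fallback when CI bounds are not supplied)
    "accuracy.per_patient_sens",
    "accuracy.per_patient_spec",
    # biopsies and adverse-event rates
    "procedure.biopsies_nbi",
    "procedure.biopsies_wle",
    "procedure.endo_ae_nbi.perforation",
    "procedure.endo_ae_nbi.bleeding",
    "procedure.endo_ae_wle.perforation",
    "procedure.endo_ae_wle.bleeding",
    "procedure.treat_ae.stricture",
    # unit costs
    "costs.tariff_endoscopy",
    "costs.tariff_emr_rfa",
    "costs.cost_per_biopsy",
    "costs.ae_costs.perforation",
    "equipment.unit_cost_system",
    "equipment.unit_cost_scope",
)


def default_owsa_items(
    params: ParameterSet, *, accuracy_ci: dict[str, tuple[float, float]] | None = None
) -> list[dict[str, float | str]]:
    """The default OWSA grid: ±10% everywhere, discount rate 2.0%–5.0%.

    ``accuracy_ci`` maps accuracy paths to explicit (low, high) confidence
    bounds and replaces the ±10% fallback for those items.
    """
    accuracy_ci = accuracy_ci or {}
    if not accuracy_ci:
        warnings.warn(
            "no confidence-interval bounds supplied for diagnostic accuracy; "
            "falling back to ±10% relative bounds",
            stacklevel=2,
        )
    items: list[dict[str, float | str]] = []
    for path in _DEFAULT_RELATIVE_PATHS:
        if path in accuracy_ci:
            low, high = accuracy_ci[path]
        else:
            low, high = _relative_bounds(params, path)
        items.append({"path": path, "low": low, "high": high})
    items.append({"path": "economics.discount_rate", "low": 0.02, "high": 0.05})
    return items


def _outcome(params: ParameterSet) -> float:
    """Discounted total cost difference, NBI minus HD-WLE (base pipeline)."""
    return cost_consequence(params).total_cost_difference


def owsa(
    params: ParameterSet,
    items: list[dict[str, float | str]] | None = None,
    *,
    accuracy_ci: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis, tornado-ranked.

    Returns one row per item — parameter path, tested bounds, outcome at
    each bound, base outcome and range — sorted by decreasing range. The
    input ParameterSet is never modified. All paths are validated before any
    model run.
    """
    if items is None:
        items = default_owsa_items(params, accuracy_ci=accuracy_ci)
    known = set(valid_parameter_paths())
    for item in items:
        if item["path"] not in known:
            raise KeyError(f"unknown OWSA parameter path {item['path']!r}")
        if float(item["low"]) > float(item["high"]):
            raise ValueError(
                f"OWSA item {item['path']}: low bound {item['low']} exceeds high bound {item['high']}"
            )
    base = _outcome(params)
    rows = []
    for item in items:
        path = str(item["path"])
        low, high = float(item["low"]), float(item["high"])
        out_low = _outcome(apply_override(params, path, low))
        out_high = _outcome(apply_override(params, path, high))
        rows.append(
            OWSAItem(
                path=path,
                low=low,
                high=high,
                outcome_low=out_low,
                outcome_high=out_high,
                base_outcome=base,
            )
        )
    frame = pd.DataFrame(
        {
            "parameter": [r.path for r in rows],
            "low": [r.low for r in rows],
            "high": [r.high for r in rows],
            "outcome_low": [r.outcome_low for r in rows],
            "outcome_high": [r.outcome_high for r in rows],
            "base_outcome": [r.base_outcome for r in rows],
            "range": [r.range for r in rows],
        }
    )
    frame = frame.sort_values(
        ["range", "parameter"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def equal_ae_analysis(params: ParameterSet) -> dict[str, float]:
    """Re-run the base case with NBI endoscopy AE rates set equal to HD-WLE.

    Removes the biopsy-count dependence of adverse events. The resulting
    total difference satisfies the identity

        equal_ae_diff = base_diff - base AE-category difference

    because, with the per-procedure exposure basis and equal treated counts,
    the AE category is the only one driven by the technique-specific rates.
    """
    base_cc = cost_consequence(params)
    base_diff = base_cc.total_cost_difference
    ae_component = (
        base_cc.nbi.cost.categories["adverse_events"]
        - base_cc.hdwle.cost.categories["adverse_events"]
    )
    wle = params.procedure.endo_ae_wle
    equalized = params.with_overrides(
        {
            "procedure.endo_ae_nbi.stricture": wle.stricture,
            "procedure.endo_ae_nbi.perforation": wle.perforation,
            "procedure.endo_ae_nbi.bleeding": wle.bleeding,
        }
    )
    equal_diff = cost_consequence(equalized).total_cost_difference
    return {
        "base_difference": base_diff,
        "ae_component_difference": ae_component,
        "equal_ae_difference": equal_diff,
        "identity_residual": equal_diff - (base_diff - ae_component),
    }
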