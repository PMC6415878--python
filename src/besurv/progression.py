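"""Six-month-cycle Markov model of disease progression and surveillance.

States are (ND, LG, HG, EAC) with a forward-only transition matrix per
6-month cycle; EAC is absorbing. Long-term scenarios follow a classified
entry cohort over the horizon: correctly diagnosed patients attend
surveillance at their state's interval, missed dysplastics progress silently
while surveyed at the non-dysplastic (36-month) interval and can be
re-detected with the arm's sensitivity at each attended visit, and
successfully eradicated patients restart from ND.

The engine tracks four diagnosis pools, each carrying a 4-vector of true
state mass:

* ``believed_nd`` — true negatives, missed dysplastics, and post-eradication
  patients; surveyed every 36 months.
* ``dx_lg`` — diagnosed LG (including false positives, whose true state is
  ND); surveyed every 6 months.
* ``dx_hg`` — diagnosed HG after failed eradication; surveyed every 6 months.
* ``dx_eac`` — diagnosed cancer; surveyed every 6 months and accruing cancer
  management cost while prevalent.

At an attended visit, true-state mass beyond the pool's diagnosis is
detected with probability Se: newly found LG moves to ``dx_lg``; newly found
HG is treated (eradication successes restart in ``believed_nd`` at ND,
failures move to ``dx_hg``); newly found EAC moves to ``dx_eac``. Detected
HG and EAC each bill one treatment. Between scheduled visits no detection
occurs. Probability mass is conserved at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostic_pathway import ClassificationResult

__all__ = [
    "STATES",
    "TransitionMatrix",
    "SurveillancePlan",
    "LongTermResult",
    "default_transition_matrix",
    "evolve",
    "long_term_trace",
]

STATES = ("nd", "lg", "hg", "eac")
_ND, _LG, _HG, _EAC = range(4)
CYCLE_MONTHS = 6


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 matrix of 6-month transition probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, 4):
            raise ValueError(f"transition matrix must be 4x4, got {p.shape}")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = p.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError(f"transition matrix rows must sum to 1, got {rows}")
        object.__setattr__(self, "probs", p)

    @property
    def eac_absorbing(self) -> bool:
        return bool(self.probs[_EAC, _EAC] == 1.0)


def default_transition_matrix() -> TransitionMatrix:
    """The 6-month progression matrix over (ND, LG, HG, EAC)."""
    return TransitionMatrix(
        np.array(
            [
                [0.9500, 0.0500, 0.0000, 0.0000],
                [0.0000, 0.9318, 0.0682, 0.0000],
                [0.0000, 0.0000, 0.9048, 0.0952],
                [0.0000, 0.0000, 0.0000, 1.0000],
            ]
        )
    )


def evolve(dist: np.ndarray, matrix: TransitionMatrix, cycles: int) -> np.ndarray:
    """Propagate a state-occupancy vector through ``cycles`` 6-month steps."""
    if cycles < 0:
        raise ValueError(f"cycles must be >= 0, got {cycles}")
    out = np.asarray(dist, dtype=float)
    return out @ np.linalg.matrix_power(matrix.probs, cycles)


@dataclass(frozen=True)
class SurveillancePlan:
    """Surveillance intervals in months per diagnosed state."""

    nd_months: int = 36
    lg_months: int = 6
    hg_post_months: int = 6
    eac_post_months: int = 6

    def __post_init__(self) -> None:
        for name in ("nd_months", "lg_months", "hg_post_months", "eac_post_months"):
            v = getattr(self, name)
            if v <= 0 or v % CYCLE_MONTHS != 0:
                raise ValueError(
                    f"{name} must be a positive multiple of {CYCLE_MONTHS} months, got {v}"
                )

    def cycles(self, pool: str) -> int:
        months = {
            "believed_nd": self.nd_months,
            "dx_lg": self.lg_months,
            "dx_hg": self.hg_post_months,
            "dx_eac": self.eac_post_months,
        }[pool]
        return months // CYCLE_MONTHS


POOLS = ("believed_nd", "dx_lg", "dx_hg", "dx_eac")


@dataclass
class LongTermResult:
    """Per-cycle accruals from following one entry cohort."""

    cycles: int
    occupancy: np.ndarray  # (cycles+1, 4) total true-state mass, all pools
    incident_eac: np.ndarray  # (cycles,) new entries into EAC per cycle
    surveillance_endoscopies: np.ndarray  # (cycles,) visits attended per cycle
    followup_treatments: np.ndarray  # (cycles,) HG/EAC treatments billed per cycle
    diagnosed_eac_prevalence: np.ndarray  # (cycles,) dx_eac mass after each cycle
    pools_final: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cumulative_incident_eac(self) -> float:
        return float(self.incident_eac.sum())

    @property
    def total_surveillance_endoscopies(self) -> float:
        return float(self.surveillance_endoscopies.sum())


def _initial_pools(cls: ClassificationResult, eradication_rate: float) -> dict[str, np.ndarray]:
    strict = cls.detected_hg * eradication_rate
    failed = cls.detected_hg - strict
    return {
        # eradication successes restart from ND under the ND interval
        "believed_nd": np.array(
            [cls.true_negatives + strict, cls.missed_lg, cls.missed_hg, cls.missed_eac]
        ),
        # false positives are labelled LG but their true state is ND
        "dx_lg": np.array([cls.false_positives, cls.detected_lg, 0.0, 0.0]),
        "dx_hg": np.array([0.0, 0.0, failed, 0.0]),
        "dx_eac": np.array([0.0, 0.0, 0.0, cls.detected_eac]),
    }


def long_term_trace(
    cls: ClassificationResult,
    plan: SurveillancePlan,
    matrix: TransitionMatrix,
    sens: float,
    eradication_rate: float,
    cycles: int = 14,
) -> LongTermResult:
    """Follow a classified entry cohort for ``cycles`` 6-month cycles.

    Each cycle the true state of every pool progresses under the matrix;
    pools whose surveillance interval divides the cycle index attend an
    endoscopy, where mass in states beyond the pool's diagnosis is detected
    with probability ``sens`` and routed (LG to surveillance, HG to
    eradication, EAC to cancer management).
    """
    if cycles < 0:
        raise ValueError(f"cycles must be >= 0, got {cycles}")
    if not 0.0 <= sens <= 1.0:
        raise ValueError(f"sens must be in [0, 1], got {sens}")
    if not 0.0 <= eradication_rate <= 1.0:
        raise ValueError(f"eradication_rate must be in [0, 1], got {eradication_rate}")

    pools = _initial_pools(cls, eradication_rate)
    visit_every = {pool: plan.cycles(pool) for pool in POOLS}

    occupancy = np.zeros((cycles + 1, 4))
    occupancy[0] = sum(pools.values())
    incident = np.zeros(cycles)
    endoscopies = np.zeros(cycles)
    treatments = np.zeros(cycles)
    eac_prev = np.zeros(cycles)

    M = matrix.probs
    for c in range(1, cycles + 1):
        # disease progression in every pool
        for pool in POOLS:
            before_eac = pools[pool][_EAC]
            pools[pool] = pools[pool] @ M
            incident[c - 1] += pools[pool][_EAC] - before_eac

        # surveillance visits and re-detection
        moved_to_lg = moved_to_hg = moved_to_eac = reset_to_nd = 0.0
        for pool in POOLS:
            if c % visit_every[pool] != 0:
                continue
            vec = pools[pool]
            endoscopies[c - 1] += vec.sum()
            if pool == "believed_nd":
                det_lg = vec[_LG] * sens
                det_hg = vec[_HG] * sens
                det_eac = vec[_EAC] * sens
                vec[_LG] -= det_lg
                vec[_HG] -= det_hg
                vec[_EAC] -= det_eac
                moved_to_lg += det_lg
                moved_to_hg += det_hg
                moved_to_eac += det_eac
            elif pool == "dx_lg":
                det_hg = vec[_HG] * sens
                det_eac = vec[_EAC] * sens
                vec[_HG] -= det_hg
                vec[_EAC] -= det_eac
                moved_to_hg += det_hg
                moved_to_eac += det_eac
            elif pool == "dx_hg":
                det_eac = vec[_EAC] * sens
                vec[_EAC] -= det_eac
                moved_to_eac += det_eac
            # dx_eac: visit only, nothing further to detect

        # newly found HG is treated: successes restart from ND, failures stay HG
        erad = moved_to_hg * eradication_rate
        reset_to_nd += erad
        pools["dx_lg"][_LG] += moved_to_lg
        pools["dx_hg"][_HG] += moved_to_hg - erad
        pools["dx_eac"][_EAC] += moved_to_eac
        pools["believed_nd"][_ND] += reset_to_nd
        treatments[c - 1] += moved_to_hg + moved_to_eac

        eac_prev[c - 1] = pools["dx_eac"].sum()
        occupancy[c] = sum(pools.values())

    return LongTermResult(
        cycles=cycles,
        occupancy=occupancy,
        incident_eac=incident,
        surveillance_endoscopies=endoscopies,
        followup_treatments=treatments,
        diagnosed_eac_prevalence=eac_prev,
        pools_final={k: v.copy() for k, v in pools.items()},
    )
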