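"""Decision-tree layer: disease mix, classification, biopsies, treatments, AEs.

Patients attending endoscopy carry one of four true states — non-dysplastic
Barrett's esophagus (ND), low-grade dysplasia (LG), high-grade dysplasia
(HG), or esophageal adenocarcinoma (EAC) — drawn from an observed cohort
distribution. The index test detects dysplasia with sensitivity Se and
clears non-dysplastic patients with specificity Sp; accuracy is binary
(dysplastic vs not) and grade assignment among detected dysplastics is taken
as correct. False positives are labelled LG (they enter 6-month surveillance
in long-term scenarios) and are not resected.

The "NBI" comparator arm is a mixed-technology arm: a market-share fraction
(default 84%) of procedures use NBI targeted biopsies, the remainder HD-WLE
with the Seattle protocol. Biopsies per procedure, endoscopy adverse-event
rates, staff times and (in per-lesion scenarios) accuracy are all blended
with that share. The comparator arm is 100% HD-WLE.

All counts are expected values (fractional) over a cohort; rounding happens
only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import AERates, AccuracyParams, ParameterSet, ParasaCounts

__all__ = [
    "StateDistribution",
    "ClassificationResult",
    "TreatmentCounts",
    "AEProfile",
    "ArmSpec",
    "disease_mix",
    "blended_biopsies_per_procedure",
    "classify_patients",
    "treatment_counts",
    "adverse_events",
    "build_arms",
]

AE_TYPES = ("stricture", "perforation", "bleeding")


@dataclass(frozen=True)
class StateDistribution:
    """Fraction of patients in each true state at entry; sums to one."""

    nd: float
    lg: float
    hg: float
    eac: float

    def __post_init__(self) -> None:
        vals = (self.nd, self.lg, self.hg, self.eac)
        if any(v < 0 for v in vals):
            raise ValueError(f"state fractions must be non-negative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1, got {sum(vals)!r}")

    @property
    def dysplastic(self) -> float:
        return self.lg + self.hg + self.eac

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.nd, self.lg, self.hg, self.eac)


def disease_mix(parasa: ParasaCounts) -> StateDistribution:
    """True-state distribution from the observed cohort counts."""
    parasa.validate()
    total = parasa.total
    return StateDistribution(
        nd=(total - parasa.dysplastic) / total,
        lg=parasa.lg / total,
        hg=parasa.hg / total,
        eac=parasa.eac / total,
    )


def blended_biopsies_per_procedure(market_share_nbi: float, b_nbi: float, b_wle: float) -> float:
    """Biopsies per procedure in a mixed arm: share x NBI + (1-share) x WLE."""
    if not 0.0 <= market_share_nbi <= 1.0:
        raise ValueError(f"market share must be in [0, 1], got {market_share_nbi}")
    return market_share_nbi * b_nbi + (1.0 - market_share_nbi) * b_wle


def _blend_ae(share: float, nbi: AERates, wle: AERates) -> AERates:
    return AERates(
        stricture=share * nbi.stricture + (1 - share) * wle.stricture,
        perforation=share * nbi.perforation + (1 - share) * wle.perforation,
        bleeding=share * nbi.bleeding + (1 - share) * wle.bleeding,
    )


@dataclass(frozen=True)
class ArmSpec:
    """One comparator arm with its blended operating characteristics."""

    name: str
    nbi_share: float  # fraction of procedures done with NBI (0 for the HD-WLE arm)
    sens: float
    spec: float
    biopsies_per_procedure: float
    endo_ae: AERates
    treat_ae: AERates
    adopts_nbi: bool  # drives the capital-equipment plan


def build_arms(params: ParameterSet, accuracy_level: str | None = None) -> tuple[ArmSpec, ArmSpec]:
    """The (NBI-adopting mixed arm, HD-WLE-only arm) pair for a scenario.

    Per-patient accuracy is meta-analytic and equal in both arms; per-lesion
    accuracy is technique-specific and market-share blended within the mixed
    arm, like every other technique-dependent input.
    """
    level = accuracy_level or params.economics.accuracy_level
    acc = params.accuracy
    proc = params.procedure
    share = params.economics.market_share_nbi
    if level == "per_patient":
        sens_nbi = sens_wle = acc.per_patient_sens
        spec_nbi = spec_wle = acc.per_patient_spec
    elif level == "per_lesion":
        sens_nbi = share * acc.per_lesion_sens_nbi + (1 - share) * acc.per_lesion_sens_wle
        spec_nbi = share * acc.per_lesion_spec_nbi + (1 - share) * acc.per_lesion_spec_wle
        sens_wle = acc.per_lesion_sens_wle
        spec_wle = acc.per_lesion_spec_wle
    else:
        raise ValueError(f"unknown accuracy level {level!r}")
    nbi = ArmSpec(
        name="nbi",
        nbi_share=share,
        sens=sens_nbi,
        spec=spec_nbi,
        biopsies_per_procedure=blended_biopsies_per_procedure(
            share, proc.biopsies_nbi, proc.biopsies_wle
        ),
        endo_ae=_blend_ae(share, proc.endo_ae_nbi, proc.endo_ae_wle),
        treat_ae=proc.treat_ae,
        adopts_nbi=True,
    )
    wle = ArmSpec(
        name="hdwle",
        nbi_share=0.0,
        sens=sens_wle,
        spec=spec_wle,
        biopsies_per_procedure=proc.biopsies_wle,
        endo_ae=proc.endo_ae_wle,
        treat_ae=proc.treat_ae,
        adopts_nbi=False,
    )
    return nbi, wle


@dataclass(frozen=True)
class ClassificationResult:
    """Expected classification counts for a cohort at the index endoscopy."""

    cohort: float
    detected_lg: float
    detected_hg: float
    detected_eac: float
    missed_lg: float
    missed_hg: float
    missed_eac: float
    true_negatives: float
    false_positives: float

    @property
    def detected_dysplastic(self) -> float:
        return self.detected_lg + self.detected_hg + self.detected_eac

    @property
    def missed_dysplastic(self) -> float:
        return self.missed_lg + self.missed_hg + self.missed_eac

    @property
    def correctly_identified(self) -> float:
        """True positives plus true negatives."""
        return self.detected_dysplastic + self.true_negatives

    @property
    def total(self) -> float:
        return (
            self.detected_dysplastic
            + self.missed_dysplastic
            + self.true_negatives
            + self.false_positives
        )

    def scaled(self, factor: float) -> "ClassificationResult":
        return ClassificationResult(
            *(getattr(self, f) * factor for f in (
                "cohort",
                "detected_lg",
                "detected_hg",
                "detected_eac",
                "missed_lg",
                "missed_hg",
                "missed_eac",
                "true_negatives",
                "false_positives",
            ))
        )


def classify_patients(
    cohort: float,
    mix: StateDistribution,
    sens: float,
    spec: float,
    *,
    hist_sens: float = 1.0,
    hist_spec: float = 0.629,
    hist_layer_enabled: bool = False,
) -> ClassificationResult:
    """Apply the index test to a cohort; expected counts by outcome.

    Dysplastic patients (LG/HG/EAC) are detected with probability ``sens``;
    non-dysplastic patients test negative with probability ``spec``, false
    positives being labelled LG. When the histopathology confirmation layer
    is enabled, endoscopy positives are re-tested: true positives are
    confirmed with ``hist_sens`` (rejections become misses) and false
    positives are cleared with ``hist_spec``.
    """
    if cohort < 0:
        raise ValueError(f"cohort must be >= 0, got {cohort}")
    for p, name in ((sens, "sens"), (spec, "spec")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    n_nd = cohort * mix.nd
    n_lg = cohort * mix.lg
    n_hg = cohort * mix.hg
    n_eac = cohort * mix.eac

    det_lg, det_hg, det_eac = n_lg * sens, n_hg * sens, n_eac * sens
    miss_lg, miss_hg, miss_eac = n_lg - det_lg, n_hg - det_hg, n_eac - det_eac
    tn = n_nd * spec
    fp = n_nd - tn

    if hist_layer_enabled:
        # Histology re-tests endoscopy positives: TP confirmed with hist_sens,
        # FP (truly non-dysplastic) cleared with hist_spec.
        miss_lg += det_lg * (1.0 - hist_sens)
        miss_hg += det_hg * (1.0 - hist_sens)
        miss_eac += det_eac * (1.0 - hist_sens)
        det_lg *= hist_sens
        det_hg *= hist_sens
        det_eac *= hist_sens
        tn += fp * hist_spec
        fp *= 1.0 - hist_spec

    return ClassificationResult(
        cohort=cohort,
        detected_lg=det_lg,
        detected_hg=det_hg,
        detected_eac=det_eac,
        missed_lg=miss_lg,
        missed_hg=miss_hg,
        missed_eac=miss_eac,
        true_negatives=tn,
        false_positives=fp,
    )


def classify_with_arm(cohort: float, mix: StateDistribution, arm: ArmSpec, acc: AccuracyParams) -> ClassificationResult:
    return classify_patients(
        cohort,
        mix,
        arm.sens,
        arm.spec,
        hist_sens=acc.hist_sens,
        hist_spec=acc.hist_spec,
        hist_layer_enabled=acc.hist_layer_enabled,
    )


@dataclass(frozen=True)
class TreatmentCounts:
    """Treatment throughput for detected high-grade dysplasia and cancer.

    ``treated`` covers detected HG and detected EAC (both billed at the
    EMR+RFA / cancer-treatment tariff). ``reported_successful_eradications``
    follows the reporting convention of the published outcome table (the
    count of detected HG patients sent to eradication); ``strict_successes``
    multiplies by the eradication rate and is what the progression module
    resets to the non-dysplastic state.
    """

    treated: float
    reported_successful_eradications: float
    strict_successes: float


def treatment_counts(cls: ClassificationResult, eradication_rate: float) -> TreatmentCounts:
    if not 0.0 <= eradication_rate <= 1.0:
        raise ValueError(f"eradication_rate must be in [0, 1], got {eradication_rate}")
    return TreatmentCounts(
        treated=cls.detected_hg + cls.detected_eac,
        reported_successful_eradications=cls.detected_hg,
        strict_successes=cls.detected_hg * eradication_rate,
    )


@dataclass(frozen=True)
class AEProfile:
    """Expected adverse-event counts split by source."""

    endoscopy: dict[str, float]
    treatment: dict[str, float]

    def total(self, ae_type: str) -> float:
        return self.endoscopy[ae_type] + self.treatment[ae_type]

    def totals(self) -> dict[str, float]:
        return {t: self.total(t) for t in AE_TYPES}

    def __add__(self, other: "AEProfile") -> "AEProfile":
        return AEProfile(
            endoscopy={t: self.endoscopy[t] + other.endoscopy[t] for t in AE_TYPES},
            treatment={t: self.treatment[t] + other.treatment[t] for t in AE_TYPES},
        )


def adverse_events(
    arm: ArmSpec,
    cohort: float,
    treated: float,
    basis: str = "per_procedure",
    *,
    total_biopsies: float | None = None,
) -> AEProfile:
    """Expected AE counts for one arm.

    Endoscopy AEs scale with an exposure chosen by ``basis``: the procedure
    count (default), the total biopsy count, or the treated count. Treatment
    AEs always scale with the treated count.
    """
    if basis == "per_procedure":
        exposure = cohort
    elif basis == "per_biopsy":
        exposure = (
            total_biopsies
            if total_biopsies is not None
            else cohort * arm.biopsies_per_procedure
        )
    elif basis == "per_treated":
        exposure = treated
    else:
        raise ValueError(
            f"unknown AE exposure basis {basis!r}; expected per_procedure, per_biopsy or per_treated"
        )
    endo = {t: getattr(arm.endo_ae, t) * exposure for t in AE_TYPES}
    treat = {t: getattr(arm.treat_ae, t) * treated for t in AE_TYPES}
    return AEProfile(endoscopy=endo, treatment=treat)
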