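"""Model input parameters: loading, validation and overrides.

Every number the engine consumes lives in a :class:`ParameterSet`, a frozen
tree of dataclasses mirroring the sections of the bundled ``defaults.yaml``
(epidemiology, accuracy, procedure, economics, costs, equipment). The default
set reproduces the published input table for the NHS England evaluation of
NBI-guided targeted biopsy versus HD-WLE with the Seattle protocol.

Probabilities and shares are stored as fractions (0.942, not 94.2%); money is
GBP 2017. The report layer is responsible for percent formatting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "ConfigurationError",
    "ParameterValidationError",
    "UnknownParameterError",
    "ParasaCounts",
    "EpidemiologyParams",
    "AccuracyParams",
    "AERates",
    "ProcedureParams",
    "EconomicSettings",
    "StaffRates",
    "StaffTimes",
    "CostParams",
    "EquipmentParams",
    "ParameterSet",
    "default_parameters",
    "load_parameters",
    "apply_override",
]


class ConfigurationError(ValueError):
    """A config document is missing a required field or has a bad shape."""


class ParameterValidationError(ValueError):
    """A parameter value violates a model invariant."""


class UnknownParameterError(KeyError):
    """A dotted override path does not name a known parameter."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterValidationError(message)


def _prob(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, f"{name} must be a probability in [0, 1], got {value!r}")


def _nonneg(value: float, name: str) -> None:
    _check(value >= 0, f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ParasaCounts:
    """Observed disease-state counts at index endoscopy (single cohort study).

    Integer counts are kept rather than the rounded percentages because the
    model's downstream outputs are only reproduced by the exact fractions
    (e.g. the HG share 106/2696, not 11.7% of 33.6%).
    """

    total: int = 2696
    dysplastic: int = 905
    lg: int = 751
    hg: int = 106
    eac: int = 48

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            _check(value >= 0, f"parasa.{f.name} must be >= 0")
        _check(
            self.lg + self.hg + self.eac == self.dysplastic,
            "parasa counts must satisfy lg + hg + eac = dysplastic "
            f"({self.lg} + {self.hg} + {self.eac} != {self.dysplastic})",
        )
        _check(
            self.dysplastic <= self.total,
            f"parasa.dysplastic ({self.dysplastic}) cannot exceed parasa.total ({self.total})",
        )


@dataclass(frozen=True)
class EpidemiologyParams:
    n_year1: int = 161_657
    annual_growth: float = 0.20
    horizon_years: int = 7
    hospital_cohort: int = 649
    parasa: ParasaCounts = field(default_factory=ParasaCounts)

    def validate(self) -> None:
        _check(self.n_year1 > 0, "epidemiology.n_year1 must be > 0")
        _check(self.annual_growth >= 0, "epidemiology.annual_growth must be >= 0")
        _check(self.horizon_years >= 1, "epidemiology.horizon_years must be >= 1")
        _check(self.hospital_cohort > 0, "epidemiology.hospital_cohort must be > 0")
        self.parasa.validate()


@dataclass(frozen=True)
class AccuracyParams:
    """Diagnostic accuracy of the index endoscopy.

    Per-patient values (meta-analytic, assumed equal for both techniques in
    the base case) and per-lesion values (technique-specific) are both
    carried; the scenario layer selects which level drives classification.
    The optional histopathology confirmation layer re-tests endoscopy
    positives and is off in the base case.
    """

    per_patient_sens: float = 0.942
    per_patient_spec: float = 0.944
    per_lesion_sens_nbi: float = 0.890
    per_lesion_spec_nbi: float = 0.800
    per_lesion_sens_wle: float = 0.791
    per_lesion_spec_wle: float = 0.810
    hist_sens: float = 1.0
    hist_spec: float = 0.629
    hist_layer_enabled: bool = False
    lesions_per_dysplastic: float = 1.0

    def validate(self) -> None:
        for f in fields(self):
            if f.name in ("hist_layer_enabled", "lesions_per_dysplastic"):
                continue
            _prob(getattr(self, f.name), f"accuracy.{f.name}")
        _check(self.lesions_per_dysplastic > 0, "accuracy.lesions_per_dysplastic must be > 0")


@dataclass(frozen=True)
class AERates:
    """Adverse-event probabilities: stricture / perforation / bleeding."""

    stricture: float
    perforation: float
    bleeding: float

    def validate(self, prefix: str) -> None:
        for f in fields(self):
            _prob(getattr(self, f.name), f"{prefix}.{f.name}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_AE_EXPOSURE_BASES = ("per_procedure", "per_biopsy", "per_treated")


@dataclass(frozen=True)
class ProcedureParams:
    biopsies_nbi: float = 3.6
    biopsies_wle: float = 7.6
    endo_ae_nbi: AERates = field(
        default_factory=lambda: AERates(stricture=0.0001, perforation=0.014, bleeding=0.002)
    )
    endo_ae_wle: AERates = field(
        default_factory=lambda: AERates(stricture=0.0001, perforation=0.030, bleeding=0.005)
    )
    treat_ae: AERates = field(
        default_factory=lambda: AERates(stricture=0.335, perforation=0.013, bleeding=0.075)
    )
    eradication_rate: float = 0.949
    ae_exposure_basis: str = "per_procedure"

    def validate(self) -> None:
        _nonneg(self.biopsies_nbi, "procedure.biopsies_nbi")
        _nonneg(self.biopsies_wle, "procedure.biopsies_wle")
        _check(
            self.biopsies_nbi <= self.biopsies_wle,
            "procedure.biopsies_nbi must not exceed procedure.biopsies_wle "
            "(targeted biopsy takes fewer specimens than the Seattle protocol)",
        )
        self.endo_ae_nbi.validate("procedure.endo_ae_nbi")
        self.endo_ae_wle.validate("procedure.endo_ae_wle")
        self.treat_ae.validate("procedure.treat_ae")
        _prob(self.eradication_rate, "procedure.eradication_rate")
        _check(
            self.ae_exposure_basis in _AE_EXPOSURE_BASES,
            f"procedure.ae_exposure_basis must be one of {_AE_EXPOSURE_BASES}, "
            f"got {self.ae_exposure_basis!r}",
        )


_PERSPECTIVES = ("nhs", "hospital")
_ACCURACY_LEVELS = ("per_patient", "per_lesion")


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate: float = 0.035
    perspective: str = "nhs"
    market_share_nbi: float = 0.84
    accuracy_level: str = "per_patient"
    long_term: bool = False

    def validate(self) -> None:
        _check(self.discount_rate >= 0, "economics.discount_rate must be >= 0")
        _check(
            self.perspective in _PERSPECTIVES,
            f"economics.perspective must be one of {_PERSPECTIVES}, got {self.perspective!r}",
        )
        _prob(self.market_share_nbi, "economics.market_share_nbi")
        _check(
            self.accuracy_level in _ACCURACY_LEVELS,
            f"economics.accuracy_level must be one of {_ACCURACY_LEVELS}, "
            f"got {self.accuracy_level!r}",
        )


@dataclass(frozen=True)
class StaffRates:
    """GBP per hour by staff activity."""

    admin: float = 23.0
    nurse_noncontact: float = 41.0
    consultant_ba: float = 142.0
    nurse_contact: float = 100.0
    consultant_during: float = 142.0

    def validate(self, prefix: str = "costs.staff_rates") -> None:
        for f in fields(self):
            _nonneg(getattr(self, f.name), f"{prefix}.{f.name}")


@dataclass(frozen=True)
class StaffTimes:
    """Hours per procedure by staff activity."""

    admin: float
    nurse_noncontact: float
    consultant_ba: float
    nurse_contact: float
    consultant_during: float

    def validate(self, prefix: str) -> None:
        for f in fields(self):
            _nonneg(getattr(self, f.name), f"{prefix}.{f.name}")


@dataclass(frozen=True)
class CostParams:
    tariff_endoscopy: float = 517.0
    tariff_emr_rfa: float = 2101.0
    cost_per_biopsy: float = 82.0
    ae_costs: dict[str, float] = field(
        default_factory=lambda: {"stricture": 392.0, "bleeding": 392.0, "perforation": 2852.0}
    )
    cancer_cost_per_year: float = 7647.0
    staff_rates: StaffRates = field(default_factory=StaffRates)
    staff_times_nbi: StaffTimes = field(
        default_factory=lambda: StaffTimes(0.30, 0.42, 0.50, 0.30, 0.30)
    )
    staff_times_wle: StaffTimes = field(
        default_factory=lambda: StaffTimes(0.30, 0.89, 0.50, 0.30, 0.30)
    )
    snare_pack_cost: float = 240.0
    snare_pack_size: int = 20
    forceps_pack_cost: float = 210.0
    forceps_pack_size: int = 10

    def validate(self) -> None:
        for name in (
            "tariff_endoscopy",
            "tariff_emr_rfa",
            "cost_per_biopsy",
            "cancer_cost_per_year",
            "snare_pack_cost",
            "forceps_pack_cost",
        ):
            _nonneg(getattr(self, name), f"costs.{name}")
        for key in ("stricture", "bleeding", "perforation"):
            _check(key in self.ae_costs, f"costs.ae_costs missing {key!r}")
            _nonneg(self.ae_costs[key], f"costs.ae_costs.{key}")
        self.staff_rates.validate()
        self.staff_times_nbi.validate("costs.staff_times_nbi")
        self.staff_times_wle.validate("costs.staff_times_wle")
        _check(self.snare_pack_size > 0, "costs.snare_pack_size must be > 0")
        _check(self.forceps_pack_size > 0, "costs.forceps_pack_size must be > 0")

    @property
    def snare_unit_cost(self) -> float:
        return self.snare_pack_cost / self.snare_pack_size

    @property
    def forceps_unit_cost(self) -> float:
        return self.forceps_pack_cost / self.forceps_pack_size


@dataclass(frozen=True)
class EquipmentParams:
    hospitals: int = 249
    rooms_per_hospital: float = 3.25
    endoscopists_per_hospital: float = 3.25
    scopes_per_room: float = 4.0
    olympus_share: float = 0.84
    nbi_capable_share: float = 0.83
    hd_scope_share: float = 0.40
    trained_share: float = 0.50
    replacement_rate: float = 0.029
    unit_cost_system: float = 41_316.0
    unit_cost_scope: float = 30_487.0
    training_cost_per_day_nbi: float = 1136.0
    training_cost_per_day_wle: float = 795.0
    training_days_nbi: float = 2.0
    training_days_wle: float = 0.0
    maintenance_system_nbi: float = 4590.0
    maintenance_system_wle: float = 4527.0
    maintenance_scope_nbi: float = 4285.0
    maintenance_scope_wle: float = 4089.0
    amortization_years: int = 7

    def validate(self) -> None:
        for name in ("hospitals", "rooms_per_hospital", "endoscopists_per_hospital", "scopes_per_room"):
            _check(getattr(self, name) > 0, f"equipment.{name} must be > 0")
        for name in ("olympus_share", "nbi_capable_share", "hd_scope_share", "trained_share", "replacement_rate"):
            _prob(getattr(self, name), f"equipment.{name}")
        for name in (
            "unit_cost_system",
            "unit_cost_scope",
            "training_cost_per_day_nbi",
            "training_cost_per_day_wle",
            "training_days_nbi",
            "training_days_wle",
            "maintenance_system_nbi",
            "maintenance_system_wle",
            "maintenance_scope_nbi",
            "maintenance_scope_wle",
        ):
            _nonneg(getattr(self, name), f"equipment.{name}")
        _check(self.amortization_years >= 1, "equipment.amortization_years must be >= 1")


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated model input set."""

    epidemiology: EpidemiologyParams = field(default_factory=EpidemiologyParams)
    accuracy: AccuracyParams = field(default_factory=AccuracyParams)
    procedure: ProcedureParams = field(default_factory=ProcedureParams)
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    costs: CostParams = field(default_factory=CostParams)
    equipment: EquipmentParams = field(default_factory=EquipmentParams)

    def validate(self) -> "ParameterSet":
        for f in fields(self):
            getattr(self, f.name).validate()
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        return _build_dataclass(cls, data, path="")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterSet":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError("config document must be a mapping of sections")
        return cls.from_dict(data)

    # -- overrides --------------------------------------------------------

    def override(self, path: str, value: Any) -> "ParameterSet":
        """Return a new set differing only in the field at dotted ``path``."""
        return apply_override(self, path, value)

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        """Apply several overrides atomically (invariants checked once at the
        end, so mutually dependent fields can change together)."""
        data = self.to_dict()
        for path, value in overrides.items():
            _set_path(data, path, value)
        return ParameterSet.from_dict(data)


_SECTION_ALIASES = {
    "epi": "epidemiology",
    "acc": "accuracy",
    "proc": "procedure",
    "econ": "economics",
    "cost": "costs",
    "equip": "equipment",
}


def _build_dataclass(cls: type, data: Mapping[str, Any], path: str) -> Any:
    """Build a (possibly nested) dataclass from a mapping, defaulting missing fields."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"section {path or cls.__name__!r} must be a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {sorted(unknown)} in section {path or '<root>'}; "
            f"known fields: {sorted(known)}"
        )
    kwargs: dict[str, Any] = {}
    for name, f in known.items():
        sub_path = f"{path}.{name}" if path else name
        if name in data:
            raw = data[name]
            if dataclasses.is_dataclass(f.type) or (isinstance(f.type, str) and f.type in _NESTED_TYPES):
                sub_cls = _resolve_field_type(f)
                kwargs[name] = _build_dataclass(sub_cls, raw, sub_path)
            else:
                kwargs[name] = raw
        else:
            if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
                raise ConfigurationError(f"missing required field {sub_path!r} with no default")
    try:
        obj = cls(**kwargs)
    except TypeError as exc:  # a required nested field absent
        raise ConfigurationError(str(exc)) from exc
    if isinstance(obj, ParameterSet):
        obj.validate()
    return obj


_NESTED_TYPES = {
    "ParasaCounts": ParasaCounts,
    "EpidemiologyParams": EpidemiologyParams,
    "AccuracyParams": AccuracyParams,
    "AERates": AERates,
    "ProcedureParams": ProcedureParams,
    "EconomicSettings": EconomicSettings,
    "StaffRates": StaffRates,
    "StaffTimes": StaffTimes,
    "CostParams": CostParams,
    "EquipmentParams": EquipmentParams,
}


def _resolve_field_type(f: dataclasses.Field) -> type:
    if isinstance(f.type, type):
        return f.type
    return _NESTED_TYPES[str(f.type)]


def _iter_paths(cls: type, prefix: str = "") -> Iterator[str]:
    for f in fields(cls):
        sub = f"{prefix}.{f.name}" if prefix else f.name
        ftype = f.type if isinstance(f.type, type) else _NESTED_TYPES.get(str(f.type))
        if ftype is not None and dataclasses.is_dataclass(ftype):
            yield from _iter_paths(ftype, sub)
        elif f.name == "ae_costs":
            for key in ("stricture", "bleeding", "perforation"):
                yield f"{sub}.{key}"
        else:
            yield sub


def valid_parameter_paths() -> list[str]:
    """All dotted paths accepted by :func:`apply_override`."""
    return sorted(_iter_paths(ParameterSet))


def default_parameters() -> ParameterSet:
    """The bundled default input set (NHS England base case)."""
    text = resources.files("besurv").joinpath("data/defaults.yaml").read_text()
    return ParameterSet.from_yaml(text)


def load_parameters(config: str | Path | Mapping[str, Any] | None = None) -> ParameterSet:
    """Load a validated :class:`ParameterSet`.

    ``config`` may be a path to a YAML/JSON document, a mapping, or None for
    the bundled defaults. Sections and fields not present in the document
    take their default values; an empty document therefore yields the
    default set exactly.
    """
    if config is None:
        return default_parameters()
    if isinstance(config, Mapping):
        return ParameterSet.from_dict(config)
    text = Path(config).read_text()
    return ParameterSet.from_yaml(text)


def _set_path(data: dict[str, Any], path: str, value: Any) -> None:
    parts = path.split(".")
    if parts:
        parts[0] = _SECTION_ALIASES.get(parts[0], parts[0])
    canonical = ".".join(parts)
    known = valid_parameter_paths()
    if canonical not in known:
        section = parts[0] if parts else ""
        nearby = [p for p in known if p.startswith(section + ".")] or known
        raise UnknownParameterError(
            f"unknown parameter path {path!r}; valid paths include: {', '.join(nearby[:12])} ..."
        )
    node: Any = data
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


def apply_override(params: ParameterSet, path: str, value: Any) -> ParameterSet:
    """Return a new ParameterSet with the field at dotted ``path`` replaced.

    Section aliases (``econ`` for ``economics``, ``cost`` for ``costs``, ...)
    are accepted. The original set is never modified; the new set is
    re-validated, so an override violating an invariant raises
    :class:`ParameterValidationError`.
    """
    data = params.to_dict()
    _set_path(data, path, value)
    return ParameterSet.from_dict(data)
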