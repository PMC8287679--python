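"""Model parameters for the NAC-vs-AC cost-effectiveness analysis.

This module is the single source of truth for every probability, cost,
utility weight, treatment time frame and overall-survival (OS) figure
used by the decision tree, the sensitivity analyses and the patient-level
microsimulation.

The built-in defaults describe the comparison of two strategies for
cT2-4N0-1 non-small cell lung cancer (NSCLC):

* **AC** (adjuvant chemotherapy): surgery followed by four cycles of
  platinum-doublet chemotherapy.
* **NAC** (neoadjuvant chemotherapy): two cycles of chemotherapy, then
  surgery, then two more cycles.

Event probabilities come from a 92 matched-pair propensity-score cohort;
costs are aggregate 2020 RMB estimates from payer fee schedules; utility
weights and treatment time frames (in months) come from the published
NSCLC quality-of-life literature.  All currency values are carried at
full printed precision; nothing is rounded before reporting.

Parameters are addressed throughout the package by flat, namespaced keys
such as ``nac.imaging``, ``ac.p_ae_ge3`` or ``utilities.u_surgery_chemo``
(the loader also accepts the longer ``nac.costs.imaging`` spelling).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ArmProbabilities",
    "ArmCosts",
    "Arm",
    "UtilitySchedule",
    "ParameterSet",
    "Finding",
    "ParameterError",
    "default_parameters",
    "validate_parameters",
    "load_parameters",
    "save_parameters",
    "to_flat_dict",
    "from_flat_dict",
    "get_value",
    "set_value",
    "flat_keys",
    "parameter_digest",
    "base_case_path",
]

PROB_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter file or override violates the model invariants."""


@dataclass(frozen=True)
class Finding:
    """One validation finding: the offending field, its value, the violated rule."""

    field: str
    value: float
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


@dataclass(frozen=True)
class ArmProbabilities:
    """Event probabilities of one treatment arm.

    ``p_no_complication``, ``p_complication_ge3`` and ``p_postop_death`` are
    the three mutually exclusive postoperative outcomes and must sum to 1.
    ``p_ae_ge3`` is the probability of a grade >=3 chemotherapy adverse
    event over the whole chemotherapy course (evaluated once per patient).
    """

    p_no_complication: float
    p_complication_ge3: float
    p_postop_death: float
    p_ae_ge3: float
    p_receive_surgery: float = 1.0
    p_receive_chemo: float = 1.0


@dataclass(frozen=True)
class ArmCosts:
    """Cost inputs of one treatment arm, in 2020 RMB.

    ``chemo_full_course`` covers the full four-cycle course; ``imaging`` is
    the arm-specific total over diagnosis, (pre-operative) staging and
    end-of-chemotherapy scans; ``ae_treatment`` is charged once per patient
    who experiences a grade >=3 adverse event.
    """

    surgery_base: float
    surgery_additional: float
    hosp_with_complication: float
    hosp_without_complication: float
    chemo_full_course: float
    imaging: float
    ae_treatment: float


@dataclass(frozen=True)
class Arm:
    """Probabilities plus costs of one strategy arm.

    Field access is delegated, so ``arm.imaging`` and ``arm.p_ae_ge3``
    resolve into the nested ``costs`` / ``probabilities`` records.
    """

    probabilities: ArmProbabilities
    costs: ArmCosts

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        probs = object.__getattribute__(self, "probabilities")
        costs = object.__getattribute__(self, "costs")
        for part in (probs, costs):
            if name in part.__dataclass_fields__:
                return getattr(part, name)
        raise AttributeError(name)


@dataclass(frozen=True)
class UtilitySchedule:
    """Utility weights (dimensionless, in [0, 1]) and time frames (months).

    ``t_ae`` and ``t_complication`` are *additional* months appended to the
    basic surgery+chemotherapy period when the corresponding event occurs.
    ``u_post_treatment`` applies from the end of the initial treatment
    phase to the overall-survival horizon; it is not printed in the source
    tables and defaults to 1.0 (see also :data:`nsclc_cea.model.CALIBRATED_U_POST`).
    """

    u_surgery_chemo: float = 0.81
    t_surgery_chemo: float = 4.87
    u_ae: float = 0.45
    t_ae: float = 0.73
    u_complication: float = 0.63
    t_complication: float = 0.50
    u_surgery_alone: float = 0.77
    t_surgery_alone: float = 0.53
    u_chemo_alone: float = 1.00
    t_chemo_alone: float = 0.21
    u_post_treatment: float = 1.00
    u_death: float = 0.0


@dataclass(frozen=True)
class ParameterSet:
    """The complete model input set for both arms.

    ``wtp_threshold`` is the willingness-to-pay threshold in RMB per QALY,
    ``cohort_size_source`` the size of the matched cohort behind the event
    probabilities (used for the beta/Dirichlet pseudo-counts in the PSA),
    and ``discount_rate`` an annual discount rate applied to post-treatment
    QALY accrual (0 by default: the model horizon is a single survival
    figure and the source analysis does not discount).
    """

    nac: Arm
    ac: Arm
    utilities: UtilitySchedule
    os_nac_years: float = 9.1
    os_ac_years: float = 9.1
    wtp_threshold: float = 35446.0
    cohort_size_source: int = 92
    discount_rate: float = 0.0
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False, repr=False)

    def arm(self, strategy: str) -> Arm:
        return self.nac if strategy.upper() == "NAC" else self.ac

    def os_years(self, strategy: str) -> float:
        return self.os_nac_years if strategy.upper() == "NAC" else self.os_ac_years


# --------------------------------------------------------------------------
# defaults (the published base case)

_DEFAULT_PROBS = {
    "NAC": ArmProbabilities(
        p_no_complication=0.82,
        p_complication_ge3=0.14,
        p_postop_death=0.04,
        p_ae_ge3=0.15,
    ),
    "AC": ArmProbabilities(
        p_no_complication=0.91,
        p_complication_ge3=0.07,
        p_postop_death=0.02,
        p_ae_ge3=0.38,
    ),
}

_DEFAULT_COSTS = {
    "NAC": ArmCosts(
        surgery_base=2351.96,
        surgery_additional=1854.46,
        hosp_with_complication=96462.0,
        hosp_without_complication=66800.0,
        chemo_full_course=30946.5,
        imaging=6036.0,
        ae_treatment=3679.8,
    ),
    "AC": ArmCosts(
        surgery_base=2367.82,
        surgery_additional=2513.65,
        hosp_with_complication=96462.0,
        hosp_without_complication=66800.0,
        chemo_full_course=30946.5,
        imaging=3568.0,
        ae_treatment=3679.8,
    ),
}


def default_parameters() -> ParameterSet:
    """Return the published base-case parameter set (both arms, OS 9.1 years)."""
    return ParameterSet(
        nac=Arm(_DEFAULT_PROBS["NAC"], _DEFAULT_COSTS["NAC"]),
        ac=Arm(_DEFAULT_PROBS["AC"], _DEFAULT_COSTS["AC"]),
        utilities=UtilitySchedule(),
    )


# --------------------------------------------------------------------------
# flat-key addressing

_TOP_SCALARS = (
    "os_nac_years",
    "os_ac_years",
    "wtp_threshold",
    "cohort_size_source",
    "discount_rate",
)


def flat_keys() -> tuple[str, ...]:
    """Canonical flat keys, one per scalar parameter."""
    keys: list[str] = []
    for arm in ("nac", "ac"):
        keys += [f"{arm}.{f.name}" for f in fields(ArmProbabilities)]
        keys += [f"{arm}.{f.name}" for f in fields(ArmCosts)]
    keys += [f"utilities.{f.name}" for f in fields(UtilitySchedule)]
    keys += list(_TOP_SCALARS)
    return tuple(keys)


def _normalize_key(key: str) -> str:
    parts = key.split(".")
    if len(parts) == 3 and parts[1] in ("costs", "probabilities", "probs"):
        parts = [parts[0], parts[2]]
    return ".".join(parts)


def get_value(p: ParameterSet, key: str) -> float:
    """Look up a scalar parameter by flat key (e.g. ``"nac.imaging"``)."""
    key = _normalize_key(key)
    parts = key.split(".")
    if len(parts) == 1:
        if parts[0] not in _TOP_SCALARS:
            raise KeyError(key)
        return getattr(p, parts[0])
    group, name = parts
    if group in ("nac", "ac"):
        arm = getattr(p, group)
        try:
            return getattr(arm, name)
        except AttributeError:
            raise KeyError(key) from None
    if group == "utilities":
        if name not in UtilitySchedule.__dataclass_fields__:
            raise KeyError(key)
        return getattr(p.utilities, name)
    raise KeyError(key)


def set_value(p: ParameterSet, key: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with one scalar parameter replaced."""
    key = _normalize_key(key)
    parts = key.split(".")
    if len(parts) == 1:
        if parts[0] not in _TOP_SCALARS:
            raise KeyError(key)
        value = int(value) if parts[0] == "cohort_size_source" else float(value)
        return replace(p, **{parts[0]: value})
    group, name = parts
    value = float(value)
    if group in ("nac", "ac"):
        arm: Arm = getattr(p, group)
        if name in ArmProbabilities.__dataclass_fields__:
            arm = replace(arm, probabilities=replace(arm.probabilities, **{name: value}))
        elif name in ArmCosts.__dataclass_fields__:
            arm = replace(arm, costs=replace(arm.costs, **{name: value}))
        else:
            raise KeyError(key)
        return replace(p, **{group: arm})
    if group == "utilities":
        if name not in UtilitySchedule.__dataclass_fields__:
            raise KeyError(key)
        return replace(p, utilities=replace(p.utilities, **{name: value}))
    raise KeyError(key)


def to_flat_dict(p: ParameterSet) -> dict[str, float]:
    return {k: get_value(p, k) for k in flat_keys()}


def from_flat_dict(
    values: Mapping[str, float], base: ParameterSet | None = None
) -> ParameterSet:
    """Build a ParameterSet from flat key-value overrides on top of ``base``.

    Unknown keys raise :class:`ParameterError`; provenance per field
    (``"default"`` vs ``"user"``) is recorded on the result.
    """
    p = base if base is not None else default_parameters()
    canonical = set(flat_keys())
    provenance = {k: "default" for k in canonical}
    for key, value in values.items():
        norm = _normalize_key(str(key))
        if norm not in canonical:
            raise ParameterError(f"unknown parameter key: {key!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"parameter {key!r} must be numeric, got {value!r}")
        p = set_value(p, norm, value)
        provenance[norm] = "user"
    return replace(p, provenance=provenance)


# --------------------------------------------------------------------------
# validation

def _prob_findings(prefix: str, a: ArmProbabilities) -> list[Finding]:
    out: list[Finding] = []
    for f in fields(a):
        v = getattr(a, f.name)
        if not 0.0 <= v <= 1.0:
            out.append(Finding(f"{prefix}.{f.name}", v, "probability must lie in [0, 1]"))
    s = a.p_no_complication + a.p_complication_ge3 + a.p_postop_death
    if abs(s - 1.0) > PROB_TOL:
        out.append(
            Finding(
                f"{prefix}.p_no_complication/p_complication_ge3/p_postop_death",
                s,
                f"branch probabilities sum {s:.10g}, must sum to 1",
            )
        )
    return out


def _cost_findings(prefix: str, c: ArmCosts) -> list[Finding]:
    out: list[Finding] = []
    for f in fields(c):
        v = getattr(c, f.name)
        if v < 0.0:
            out.append(Finding(f"{prefix}.{f.name}", v, "cost must be non-negative"))
    if c.hosp_with_complication < c.hosp_without_complication:
        out.append(
            Finding(
                f"{prefix}.hosp_with_complication",
                c.hosp_with_complication,
                "hospitalization with complication must cost at least as much as without",
            )
        )
    return out


def validate_parameters(p: ParameterSet) -> list[Finding]:
    """Check every model invariant; return findings (empty list iff valid)."""
    out: list[Finding] = []
    out += _prob_findings("nac", p.nac.probabilities)
    out += _prob_findings("ac", p.ac.probabilities)
    out += _cost_findings("nac", p.nac.costs)
    out += _cost_findings("ac", p.ac.costs)
    u = p.utilities
    for f in fields(u):
        v = getattr(u, f.name)
        if f.name.startswith("u_") and not 0.0 <= v <= 1.0:
            out.append(Finding(f"utilities.{f.name}", v, "utility must lie in [0, 1]"))
        if f.name.startswith("t_") and v < 0.0:
            out.append(Finding(f"utilities.{f.name}", v, "time frame must be non-negative"))
    if u.u_death != 0.0:
        out.append(Finding("utilities.u_death", u.u_death, "death utility is fixed at 0"))
    # OS must exceed the longest possible treatment phase of either arm
    t_max_years = (u.t_surgery_chemo + u.t_ae + u.t_complication) / 12.0
    for name in ("os_nac_years", "os_ac_years"):
        v = getattr(p, name)
        if v <= t_max_years:
            out.append(
                Finding(name, v, f"overall survival must exceed the treatment phase ({t_max_years:.3f} y)")
            )
    if p.wtp_threshold <= 0.0:
        out.append(Finding("wtp_threshold", p.wtp_threshold, "willingness-to-pay must be positive"))
    if p.cohort_size_source < 1:
        out.append(Finding("cohort_size_source", p.cohort_size_source, "cohort size must be >= 1"))
    if not 0.0 <= p.discount_rate < 1.0:
        out.append(Finding("discount_rate", p.discount_rate, "annual discount rate must lie in [0, 1)"))
    return out


# --------------------------------------------------------------------------
# serialization

def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write the full parameter set as a flat-key YAML mapping."""
    payload = {k: get_value(p, k) for k in flat_keys()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a flat-key YAML config; unspecified keys fall back to defaults.

    Raises :class:`ParameterError` (naming the offending field) when the
    file is missing, unparseable, or violates a model invariant.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ParameterError(f"parameter file must be a key-value mapping: {path}")
    p = from_flat_dict(raw)
    findings = validate_parameters(p)
    if findings:
        msg = "; ".join(str(f) for f in findings)
        raise ParameterError(f"invalid parameters in {path}: {msg}")
    return p


def parameter_digest(p: ParameterSet) -> str:
    """Stable hex digest of every scalar parameter value."""
    payload = json.dumps(to_flat_dict(p), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def base_case_path() -> Path:
    """Path of the shipped base-case parameter file."""
    return Path(__file__).parent / "data" / "base_case.yaml"
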