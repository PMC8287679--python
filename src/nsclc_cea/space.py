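"""The scalar parameter space shared by the sensitivity analyses.

One entry per *uncertain model parameter*.  Cost rows whose NAC and AC
values are one and the same published figure (hospitalization with and
without complication, the chemotherapy course, AE treatment) are single
parameters applied to both arms; arm-specific rows (surgery base and
additional procedures, imaging) and event probabilities are per-arm.
Utility weights and time frames are shared between arms by model
assumption.  One-way analysis and the probabilistic sensitivity analysis
both draw their variable lists from here so that "a parameter" means the
same thing in a tornado diagram and in a Monte Carlo draw.
"""
from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet, get_value, set_value

__all__ = ["ScalarParameter", "parameter_space", "find_parameter", "apply_value"]


@dataclass(frozen=True)
class ScalarParameter:
    """A named scalar with the flat keys it writes to and its kind.

    ``kind`` is one of ``cost | time | utility | probability | os`` and
    determines both the one-way clipping rule and the PSA distribution
    family.
    """

    name: str
    paths: tuple[str, ...]
    kind: str

    def value(self, p: ParameterSet) -> float:
        return get_value(p, self.paths[0])


def parameter_space() -> tuple[ScalarParameter, ...]:
    entries: list[ScalarParameter] = []
    # arm-specific costs
    for arm in ("nac", "ac"):
        for name in ("surgery_base", "surgery_additional", "imaging"):
            entries.append(ScalarParameter(f"{arm}.{name}", (f"{arm}.{name}",), "cost"))
    # shared costs (one published figure covering both arms)
    for name in (
        "hosp_with_complication",
        "hosp_without_complication",
        "chemo_full_course",
        "ae_treatment",
    ):
        entries.append(ScalarParameter(name, (f"nac.{name}", f"ac.{name}"), "cost"))
    # shared treatment time frames (months)
    for name in ("t_surgery_chemo", "t_ae", "t_complication", "t_surgery_alone", "t_chemo_alone"):
        entries.append(ScalarParameter(name, (f"utilities.{name}",), "time"))
    # shared utility weights
    for name in (
        "u_surgery_chemo",
        "u_ae",
        "u_complication",
        "u_surgery_alone",
        "u_chemo_alone",
        "u_post_treatment",
    ):
        entries.append(ScalarParameter(name, (f"utilities.{name}",), "utility"))
    # per-arm event probabilities
    for arm in ("nac", "ac"):
        for name in ("p_complication_ge3", "p_postop_death", "p_ae_ge3"):
            entries.append(ScalarParameter(f"{arm}.{name}", (f"{arm}.{name}",), "probability"))
    # overall survival per arm
    entries.append(ScalarParameter("os_nac_years", ("os_nac_years",), "os"))
    entries.append(ScalarParameter("os_ac_years", ("os_ac_years",), "os"))
    return tuple(entries)


def find_parameter(name: str) -> ScalarParameter:
    for entry in parameter_space():
        if entry.name == name:
            return entry
    raise KeyError(f"unknown model parameter: {name!r}")


def apply_value(p: ParameterSet, param: ScalarParameter, value: float) -> ParameterSet:
    """Set a scalar parameter, renormalizing sibling branch probabilities.

    Varying a complication-outcome probability (``p_complication_ge3`` or
    ``p_postop_death``) lets ``p_no_complication`` absorb the residual so
    the chance node stays a probability distribution.
    """
    for path in param.paths:
        p = set_value(p, path, value)
    if param.kind == "probability":
        arm, name = param.paths[0].split(".")
        if name in ("p_complication_ge3", "p_postop_death"):
            probs = p.arm(arm).probabilities
            residual = 1.0 - probs.p_complication_ge3 - probs.p_postop_death
            if residual < 0.0:
                raise ValueError(
                    f"{param.name}={value:g} leaves no probability for the "
                    "no-complication branch"
                )
            p = set_value(p, f"{arm}.p_no_complication", residual)
    return p
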