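"""One-way deterministic sensitivity analysis, tornado ordering, and the
overall-survival threshold analysis.

Each parameter is varied to 80% and 120% of its base value (probabilities
and utilities are clipped to [0, 1]; varying one complication-outcome
probability renormalizes the no-complication branch).  The tornado metric
is the swing of the *net-monetary-benefit difference* (NAC minus AC) at
the willingness-to-pay threshold rather than the raw ICER, which is
sign-unstable when the QALY increment crosses zero; the ICERs at the low
and high settings are reported alongside.

The threshold analysis finds the smallest overall-survival advantage of
NAC (holding the AC overall survival at base) at which NAC attains the
higher net monetary benefit, by bisection on a bracketing interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .metrics import CEAResult, compare
from .model import DEFAULT_CONVENTIONS, StructuralConventions, evaluate_arm, evaluate_base_case
from .params import ParameterSet, set_value
from .space import ScalarParameter, apply_value, find_parameter, parameter_space

__all__ = ["OneWayResult", "one_way", "tornado", "tornado_frame", "os_threshold"]


@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    base_value: float
    low_value: float
    high_value: float
    icer_low: float | None
    icer_high: float | None
    metric_low: float  # NMB difference (NAC - AC) at the low setting
    metric_high: float
    swing: float


def _evaluate(p: ParameterSet, wtp: float, conventions: StructuralConventions) -> CEAResult:
    nac, ac = evaluate_base_case(p, conventions)
    return compare(nac, ac, wtp)


def _clip(value: float, kind: str) -> float:
    if kind in ("probability", "utility"):
        return min(max(value, 0.0), 1.0)
    return max(value, 0.0)


def one_way(
    param_name: str,
    p: ParameterSet,
    wtp: float | None = None,
    relative_range: float = 0.2,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
) -> OneWayResult:
    """Re-evaluate the model with one parameter at 1 +/- ``relative_range``
    times its base value, all else held at base."""
    param = find_parameter(param_name)
    if wtp is None:
        wtp = p.wtp_threshold
    base = param.value(p)
    low = _clip(base * (1.0 - relative_range), param.kind)
    high = _clip(base * (1.0 + relative_range), param.kind)
    res_low = _evaluate(apply_value(p, param, low), wtp, conventions)
    res_high = _evaluate(apply_value(p, param, high), wtp, conventions)
    return OneWayResult(
        parameter=param.name,
        base_value=base,
        low_value=low,
        high_value=high,
        icer_low=res_low.icer,
        icer_high=res_high.icer,
        metric_low=res_low.nmb_difference,
        metric_high=res_high.nmb_difference,
        swing=abs(res_high.nmb_difference - res_low.nmb_difference),
    )


def tornado(
    p: ParameterSet,
    params: list[str] | None = None,
    wtp: float | None = None,
    relative_range: float = 0.2,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
) -> list[OneWayResult]:
    """One-way results for every parameter, sorted by swing (descending,
    ties broken by name).  Duplicate entries are dropped with a warning."""
    if params is None:
        params = [entry.name for entry in parameter_space()]
    seen: set[str] = set()
    unique: list[str] = []
    for name in params:
        if name in seen:
            warnings.warn(f"duplicate tornado parameter {name!r} ignored", stacklevel=2)
            continue
        seen.add(name)
        unique.append(name)
    results = [one_way(name, p, wtp, relative_range, conventions) for name in unique]
    return sorted(results, key=lambda r: (-r.swing, r.parameter))


def tornado_frame(results: list[OneWayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "base_value": [r.base_value for r in results],
            "low_value": [r.low_value for r in results],
            "high_value": [r.high_value for r in results],
            "icer_low": [r.icer_low for r in results],
            "icer_high": [r.icer_high for r in results],
            "nmb_diff_low": [r.metric_low for r in results],
            "nmb_diff_high": [r.metric_high for r in results],
            "swing": [r.swing for r in results],
        }
    )


def os_threshold(
    p: ParameterSet,
    wtp: float | None = None,
    bracket: tuple[float, float] = (0.0, 2.0),
    tol: float = 1e-6,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
) -> float:
    """Smallest OS advantage of NAC (years) making NAC cost-effective.

    Holds the AC overall survival at base, sets
    ``os_nac = os_ac + delta`` and bisects the net-monetary-benefit
    difference to ``tol`` years.  Requires AC cost-effective at the base
    (delta = 0) and a sign change within the bracket; the NMB difference
    is checked to be monotone in delta before the root is reported.
    """
    if wtp is None:
        wtp = p.wtp_threshold
    os_ac = p.os_ac_years
    ac_result = evaluate_arm("AC", p, conventions)

    def nmb_diff(delta: float) -> float:
        nac_result = evaluate_arm("NAC", set_value(p, "os_nac_years", os_ac + delta), conventions)
        return compare(nac_result, ac_result, wtp).nmb_difference

    lo, hi = bracket
    f_lo, f_hi = nmb_diff(lo), nmb_diff(hi)
    if f_lo >= 0.0:
        raise ValueError("NAC is already cost-effective at the base overall survival")
    if f_hi <= 0.0:
        raise ValueError(
            f"no crossing within bracket {bracket}: NMB difference stays negative "
            f"({f_hi:.2f} at delta={hi:g} y)"
        )
    # monotonicity sanity check (guaranteed when u_post_treatment > 0)
    grid = [lo + (hi - lo) * k / 8 for k in range(9)]
    values = [f_lo] + [nmb_diff(d) for d in grid[1:-1]] + [f_hi]
    if any(b < a for a, b in zip(values, values[1:])):
        raise ValueError("NMB difference is not monotone in the OS advantage; root not unique")
    return float(brentq(nmb_diff, lo, hi, xtol=tol))
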