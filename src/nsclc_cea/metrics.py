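"""Incremental cost-effectiveness metrics: ICER, dominance, net monetary benefit.

Increments are oriented NAC minus AC throughout (AC is the reference
comparator).  The incremental cost-effectiveness ratio (ICER) is
``delta_cost / delta_qaly`` and is undefined when ``delta_qaly`` is zero.
A negative ICER is reported as printed; its interpretation is carried by
the dominance label:

* ``ac_dominant`` — NAC costs more and yields fewer QALYs;
* ``nac_dominant`` — NAC costs less and yields more QALYs;
* ``tradeoff_ne`` — NAC costs more and yields more (north-east quadrant);
* ``tradeoff_sw`` — NAC costs less and yields fewer (south-west quadrant).

Net monetary benefit at willingness-to-pay ``wtp`` is
``NMB_s = wtp * E[QALY_s] - E[cost_s]``; the cost-effective strategy at a
threshold is the one with the higher NMB, which coincides with the
ICER-vs-threshold rule in the trade-off quadrants and with the dominant
strategy in the dominated quadrants.
"""
from __future__ import annotations

from dataclasses import dataclass

from .tree import ArmResult

__all__ = ["CEAResult", "compare", "cost_effective_at"]


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float  # NAC - AC
    delta_qaly: float  # NAC - AC
    icer: float | None  # RMB per QALY; None when delta_qaly == 0
    dominance: str  # nac_dominant | ac_dominant | tradeoff_ne | tradeoff_sw
    nmb_nac: float
    nmb_ac: float
    wtp: float

    @property
    def nmb_difference(self) -> float:
        """NMB of NAC minus NMB of AC (positive favours NAC)."""
        return self.nmb_nac - self.nmb_ac

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "nmb_nac": self.nmb_nac,
            "nmb_ac": self.nmb_ac,
            "wtp": self.wtp,
            "cost_effective": cost_effective_at(self),
        }


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost > 0 and delta_qaly < 0:
        return "ac_dominant"
    if delta_cost < 0 and delta_qaly > 0:
        return "nac_dominant"
    if delta_cost >= 0 and delta_qaly >= 0:
        return "tradeoff_ne"
    return "tradeoff_sw"


def compare(nac: ArmResult, ac: ArmResult, wtp: float) -> CEAResult:
    """Incremental comparison of the two arms at a willingness-to-pay."""
    dc = nac.expected_cost - ac.expected_cost
    dq = nac.expected_qaly - ac.expected_qaly
    icer = dc / dq if dq != 0.0 else None
    return CEAResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        dominance=_dominance(dc, dq),
        nmb_nac=wtp * nac.expected_qaly - nac.expected_cost,
        nmb_ac=wtp * ac.expected_qaly - ac.expected_cost,
        wtp=wtp,
    )


def cost_effective_at(result: CEAResult, wtp: float | None = None) -> str:
    """The cost-effective strategy ("NAC" or "AC") at a willingness-to-pay.

    Uses the NMB comparison, recomputed from the deltas when ``wtp``
    differs from the one stored in ``result``.  A dominant strategy wins
    at every threshold; ties go to the reference comparator AC.
    """
    if wtp is None:
        wtp = result.wtp
    nmb_diff = wtp * result.delta_qaly - result.delta_cost
    return "NAC" if nmb_diff > 0 else "AC"
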