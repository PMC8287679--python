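"""Full-analysis driver: parameters -> base case -> OWSA -> PSA -> microsim.

Writes machine-readable artifacts (CSV tables, JSON summaries), a
human-readable ``summary.txt`` mirroring the result structure of a
cost-effectiveness report, and a run manifest recording the command,
parameter digest, seed, every output file and every structural toggle in
effect.  Given (config, seed) the numeric outputs are byte-identical
between runs; only the manifest timestamp differs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import owsa as owsa_mod
from .metrics import compare, cost_effective_at
from .microsim import simulate_cohort
from .model import (
    DEFAULT_CONVENTIONS,
    StructuralConventions,
    build_arm,
    evaluate_base_case,
)
from .params import (
    ParameterSet,
    default_parameters,
    load_parameters,
    parameter_digest,
    save_parameters,
    set_value,
    validate_parameters,
)
from .psa import run_psa
from .tree import decision, to_edge_table, to_outline

__all__ = ["RunManifest", "run_full_analysis"]


@dataclass(frozen=True)
class RunManifest:
    command: str
    parameter_digest: str
    seed: int | None
    timestamp: str
    output_files: tuple[str, ...]
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-stream seeds derived from the run seed (all < 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _resolve_parameters(config: str | Path | None, u_post: float | None) -> ParameterSet:
    p = load_parameters(config) if config is not None else default_parameters()
    if u_post is not None:
        p = set_value(p, "utilities.u_post_treatment", u_post)
    findings = validate_parameters(p)
    if findings:
        raise ValueError("invalid parameters: " + "; ".join(str(f) for f in findings))
    return p


def run_full_analysis(
    out_dir: str | Path,
    config: str | Path | None = None,
    seed: int = 0,
    psa_n: int = 10_000,
    microsim_n: int = 200_000,
    wtp: float | None = None,
    os_correlated: bool = False,
    u_post: float | None = None,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
) -> RunManifest:
    """Execute every analysis stage and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "parameters"
    try:
        p = _resolve_parameters(config, u_post)
        if wtp is None:
            wtp = p.wtp_threshold
        seeds = _child_seeds(seed, 3)

        def emit(name: str, writer) -> None:
            path = out / name
            writer(path)
            outputs.append(name)

        emit("parameters.yaml", lambda path: save_parameters(p, path))

        # --- base case -----------------------------------------------------
        stage = "base case"
        nac, ac = evaluate_base_case(p, conventions)
        cea = compare(nac, ac, wtp)
        paths_frame = nac.to_frame().assign(strategy="NAC")
        paths_frame = pd.concat(
            [paths_frame, ac.to_frame().assign(strategy="AC")], ignore_index=True
        )[["strategy", "path", "probability", "cost", "qaly", "events"]]
        emit("basecase_paths.csv", lambda path: paths_frame.to_csv(path, index=False))
        basecase = {
            "nac": {"expected_cost": nac.expected_cost, "expected_qaly": nac.expected_qaly},
            "ac": {"expected_cost": ac.expected_cost, "expected_qaly": ac.expected_qaly},
            "cea": cea.to_dict(),
        }
        emit(
            "basecase_summary.json",
            lambda path: path.write_text(json.dumps(basecase, indent=2) + "\n"),
        )
        root = decision("NAC vs AC", [build_arm("NAC", p, conventions), build_arm("AC", p, conventions)])
        emit("tree_outline.txt", lambda path: path.write_text(to_outline(root)))
        emit("tree_edges.csv", lambda path: to_edge_table(root).to_csv(path, index=False))

        # --- one-way sensitivity -------------------------------------------
        stage = "one-way sensitivity"
        tornado_results = owsa_mod.tornado(p, wtp=wtp, conventions=conventions)
        emit(
            "tornado.csv",
            lambda path: owsa_mod.tornado_frame(tornado_results).to_csv(path, index=False),
        )
        stage = "OS threshold"
        try:
            threshold = owsa_mod.os_threshold(p, wtp=wtp, conventions=conventions)
            threshold_payload = {"wtp": wtp, "os_advantage_years": threshold}
        except ValueError as exc:
            threshold_payload = {"wtp": wtp, "os_advantage_years": None, "note": str(exc)}
        emit(
            "os_threshold.json",
            lambda path: path.write_text(json.dumps(threshold_payload, indent=2) + "\n"),
        )

        # --- probabilistic sensitivity -------------------------------------
        stage = "PSA"
        psa = run_psa(p, n=psa_n, seed=seeds[0], os_correlated=os_correlated, conventions=conventions)
        draws = pd.DataFrame(
            {
                "draw_id": np.arange(psa.n),
                "delta_cost": psa.delta_cost,
                "delta_qaly": psa.delta_qaly,
            }
        )
        emit("psa_draws.csv", lambda path: draws.to_csv(path, index=False))
        ceac = pd.DataFrame({"wtp": psa.ceac_wtp, "p_ac_cost_effective": psa.ceac_p_ac})
        emit("psa_ceac.csv", lambda path: ceac.to_csv(path, index=False))
        psa_summary = {
            "n": psa.n,
            "seed": psa.seed,
            "os_correlated": psa.os_correlated,
            "quadrant_fractions": psa.quadrant_fractions(),
            "p_ac_cost_effective_at_wtp": psa.p_ac_cost_effective(wtp),
            "wtp": wtp,
            "reduced_run": psa.n < 10_000,
        }
        emit(
            "psa_summary.json",
            lambda path: path.write_text(json.dumps(psa_summary, indent=2) + "\n"),
        )

        # --- microsimulation validation ------------------------------------
        stage = "microsimulation"
        sim = {}
        for strategy, s in (("NAC", seeds[1]), ("AC", seeds[2])):
            cohort = simulate_cohort(strategy, p, microsim_n, s, conventions, return_records=False)
            arm_res = nac if strategy == "NAC" else ac
            sim[strategy.lower()] = cohort.summary() | {
                "rollback_cost": arm_res.expected_cost,
                "rollback_qaly": arm_res.expected_qaly,
                "cost_z": (cohort.mean_cost - arm_res.expected_cost) / cohort.se_cost,
                "qaly_z": (cohort.mean_qaly - arm_res.expected_qaly) / cohort.se_qaly,
            }
        emit(
            "microsim_summary.json",
            lambda path: path.write_text(json.dumps(sim, indent=2) + "\n"),
        )

        # --- human-readable summary ----------------------------------------
        stage = "summary"
        ce = cost_effective_at(cea)
        lines = [
            "NAC vs AC cost-effectiveness analysis",
            "=====================================",
            "",
            "Base case",
            "---------",
            f"  AC : cost {ac.expected_cost:,.2f} RMB, {ac.expected_qaly:.4f} QALYs",
            f"  NAC: cost {nac.expected_cost:,.2f} RMB, {nac.expected_qaly:.4f} QALYs",
            f"  Increment (NAC - AC): cost {cea.delta_cost:,.2f} RMB, {cea.delta_qaly:.4f} QALYs",
            f"  ICER: {'undefined' if cea.icer is None else format(cea.icer, ',.1f') + ' RMB/QALY'}",
            f"  Dominance: {cea.dominance}",
            f"  Cost-effective strategy at WTP {wtp:,.0f} RMB/QALY: {ce}",
            "",
            "One-way sensitivity (top 5 by NMB-difference swing)",
            "---------------------------------------------------",
        ]
        for r in tornado_results[:5]:
            lines.append(f"  {r.parameter}: swing {r.swing:,.1f} RMB")
        if threshold_payload["os_advantage_years"] is not None:
            lines += [
                "",
                f"  NAC becomes cost-effective at WTP {wtp:,.0f} when its OS exceeds",
                f"  the AC OS by {threshold_payload['os_advantage_years']:.4f} years.",
            ]
        else:
            lines += ["", f"  OS threshold: {threshold_payload['note']}"]
        q = psa_summary["quadrant_fractions"]
        lines += [
            "",
            f"Probabilistic sensitivity ({psa.n:,} draws, seed {psa.seed})",
            "--------------------------------------------------",
            f"  AC dominant in {q['ac_dominant'] * 100:.1f}% of draws",
            f"  NAC dominant in {q['nac_dominant'] * 100:.1f}% of draws",
            f"  P(AC cost-effective at WTP {wtp:,.0f}) = {psa_summary['p_ac_cost_effective_at_wtp'] * 100:.1f}%",
            "",
            "Microsimulation check (cohort mean vs rollback, z-scores)",
            "---------------------------------------------------------",
            f"  NAC: cost z = {sim['nac']['cost_z']:+.2f}, QALY z = {sim['nac']['qaly_z']:+.2f}",
            f"  AC : cost z = {sim['ac']['cost_z']:+.2f}, QALY z = {sim['ac']['qaly_z']:+.2f}",
            "",
            "Structural settings",
            "-------------------",
            f"  os_correlated = {os_correlated}",
            f"  u_post_treatment = {p.utilities.u_post_treatment}",
        ]
        for key, value in conventions.as_dict().items():
            lines.append(f"  {key} = {value}")
        emit("summary.txt", lambda path: path.write_text("\n".join(lines) + "\n"))
    except Exception as exc:
        raise RuntimeError(
            f"analysis stage {stage!r} failed ({exc}); partial outputs: {outputs}"
        ) from exc

    manifest = RunManifest(
        command="run_full_analysis",
        parameter_digest=parameter_digest(p),
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        output_files=tuple(outputs) + ("manifest.json",),
        settings={
            "psa_n": psa_n,
            "microsim_n": microsim_n,
            "wtp": wtp,
            "os_correlated": os_correlated,
            "u_post_treatment": p.utilities.u_post_treatment,
            **conventions.as_dict(),
        },
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest
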