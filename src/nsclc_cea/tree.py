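"""Generic decision-tree engine with two payoff dimensions (cost, QALY).

A tree is a directed acyclic structure of :class:`TreeNode` objects.
Chance nodes carry branches whose probabilities sum to 1; terminal nodes
carry a ``(cost, qaly)`` payoff.  Expected values are obtained by
probability-weighted rollback from the leaves, and every root-to-leaf
path can be enumerated for audit.

Decision nodes are *compared*, never optimized over: the engine refuses
to roll back through a decision node, mirroring an analysis that reports
both strategies side by side and leaves the choice to the incremental
cost-effectiveness layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

__all__ = [
    "Branch",
    "TreeNode",
    "PathOutcome",
    "ArmResult",
    "StructuralError",
    "chance",
    "terminal",
    "decision",
    "enumerate_paths",
    "rollback",
    "validate_tree",
    "to_outline",
    "to_edge_table",
]

PROB_TOL = 1e-9


class StructuralError(ValueError):
    """Raised when a tree is malformed; the message names the node."""


@dataclass(frozen=True)
class TreeNode:
    kind: str  # "decision" | "chance" | "terminal"
    label: str
    branches: tuple["Branch", ...] = ()
    payoff: tuple[float, float] | None = None  # (cost, qaly), terminal only
    tags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Branch:
    probability: float
    child: TreeNode
    label: str = ""


@dataclass(frozen=True)
class PathOutcome:
    """One root-to-leaf trajectory with its probability and payoffs."""

    leaf_label: str
    probability: float
    cost: float
    qaly: float
    event_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ArmResult:
    """Expected payoffs of one strategy arm plus its audited path table."""

    expected_cost: float
    expected_qaly: float
    paths: tuple[PathOutcome, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [p.leaf_label for p in self.paths],
                "probability": [p.probability for p in self.paths],
                "cost": [p.cost for p in self.paths],
                "qaly": [p.qaly for p in self.paths],
                "events": ["|".join(sorted(p.event_flags)) for p in self.paths],
            }
        )


# --------------------------------------------------------------------------
# constructors

def terminal(label: str, cost: float, qaly: float, tags: Iterator[str] = ()) -> TreeNode:
    return TreeNode("terminal", label, payoff=(float(cost), float(qaly)), tags=frozenset(tags))


def chance(label: str, branches: list[tuple[float, TreeNode]] | tuple, tags=()) -> TreeNode:
    return TreeNode(
        "chance",
        label,
        branches=tuple(Branch(float(p), node) for p, node in branches),
        tags=frozenset(tags),
    )


def decision(label: str, alternatives: list[TreeNode]) -> TreeNode:
    """A decision root whose branches are compared, not chosen between."""
    return TreeNode("decision", label, branches=tuple(Branch(1.0, n, n.label) for n in alternatives))


# --------------------------------------------------------------------------
# core operations

def _check_node(node: TreeNode) -> None:
    if node.kind == "terminal":
        if node.branches:
            raise StructuralError(f"terminal node {node.label!r} has branches")
        if node.payoff is None:
            raise StructuralError(f"terminal node {node.label!r} has no payoff")
    elif node.kind == "chance":
        if not node.branches:
            raise StructuralError(f"chance node {node.label!r} has no branches")
        s = sum(b.probability for b in node.branches)
        if abs(s - 1.0) > PROB_TOL:
            raise StructuralError(
                f"chance node {node.label!r} branch probabilities sum {s:.10g}"
            )
        if any(b.probability < 0 for b in node.branches):
            raise StructuralError(f"chance node {node.label!r} has a negative branch probability")
    elif node.kind == "decision":
        raise StructuralError(
            f"decision node {node.label!r} cannot be rolled back; evaluate each alternative"
        )
    else:
        raise StructuralError(f"node {node.label!r} has unknown kind {node.kind!r}")


def enumerate_paths(root: TreeNode) -> list[PathOutcome]:
    """Depth-first enumeration of every root-to-leaf path.

    Path probability is the product of branch probabilities along the
    path; event flags are the union of node tags encountered.  Order is
    deterministic: depth-first in declared branch order.
    """
    out: list[PathOutcome] = []

    def walk(node: TreeNode, prob: float, flags: frozenset[str], stack: tuple[int, ...]) -> None:
        if id(node) in stack:
            raise StructuralError(f"cycle detected at node {node.label!r}")
        _check_node(node)
        flags = flags | node.tags
        if node.kind == "terminal":
            cost, qaly = node.payoff  # type: ignore[misc]
            out.append(PathOutcome(node.label, prob, cost, qaly, flags))
            return
        for b in node.branches:
            walk(b.child, prob * b.probability, flags, stack + (id(node),))

    walk(root, 1.0, frozenset(), ())
    return out


def rollback(root: TreeNode) -> tuple[float, float]:
    """Probability-weighted expected (cost, qaly) of a chance tree."""
    _check_node(root)
    if root.kind == "terminal":
        return root.payoff  # type: ignore[return-value]
    ec = 0.0
    eq = 0.0
    for b in root.branches:
        c, q = rollback(b.child)
        ec += b.probability * c
        eq += b.probability * q
    return ec, eq


def evaluate(root: TreeNode) -> ArmResult:
    """Roll back a chance tree and attach the enumerated path table."""
    paths = enumerate_paths(root)
    ec = sum(p.probability * p.cost for p in paths)
    eq = sum(p.probability * p.qaly for p in paths)
    return ArmResult(ec, eq, tuple(paths))


def validate_tree(root: TreeNode) -> list[str]:
    """Report structural findings (probability sums, orphan payoffs, cycles)."""
    findings: list[str] = []

    def walk(node: TreeNode, stack: tuple[int, ...]) -> None:
        if id(node) in stack:
            findings.append(f"cycle detected at node {node.label!r}")
            return
        if node.kind == "terminal":
            if node.branches:
                findings.append(f"terminal node {node.label!r} has branches")
            if node.payoff is None:
                findings.append(f"terminal node {node.label!r} has no payoff")
            return
        if node.kind not in ("chance", "decision"):
            findings.append(f"node {node.label!r} has unknown kind {node.kind!r}")
            return
        if node.payoff is not None:
            findings.append(f"non-terminal node {node.label!r} carries an orphan payoff")
        if not node.branches:
            findings.append(f"{node.kind} node {node.label!r} has no branches")
        if node.kind == "chance":
            s = sum(b.probability for b in node.branches)
            if abs(s - 1.0) > PROB_TOL:
                findings.append(f"chance node {node.label!r} probabilities sum {s:.10g}")
            for b in node.branches:
                if b.probability < 0:
                    findings.append(f"chance node {node.label!r} has negative probability {b.probability}")
        for b in node.branches:
            walk(b.child, stack + (id(node),))

    walk(root, ())
    return findings


# --------------------------------------------------------------------------
# audit exports

def to_outline(root: TreeNode, indent: str = "  ") -> str:
    """Indented text outline of the tree for visual audit."""
    lines: list[str] = []

    def walk(node: TreeNode, depth: int, prob: float | None) -> None:
        head = indent * depth
        ptxt = "" if prob is None else f" p={prob:g}"
        if node.kind == "terminal":
            cost, qaly = node.payoff  # type: ignore[misc]
            lines.append(f"{head}{node.label}{ptxt} -> cost={cost:.2f}, qaly={qaly:.4f}")
        else:
            lines.append(f"{head}[{node.kind}] {node.label}{ptxt}")
            for b in node.branches:
                walk(b.child, depth + 1, b.probability)

    walk(root, 0, None)
    return "\n".join(lines) + "\n"


def to_edge_table(root: TreeNode) -> pd.DataFrame:
    """Node/edge table (parent, child, kind, probability, payoffs) for audit."""
    rows: list[dict] = []

    def walk(node: TreeNode) -> None:
        for b in node.branches:
            child = b.child
            cost, qaly = child.payoff if child.payoff is not None else (None, None)
            rows.append(
                {
                    "parent": node.label,
                    "child": child.label,
                    "kind": child.kind,
                    "probability": b.probability,
                    "cost": cost,
                    "qaly": qaly,
                }
            )
            walk(child)

    walk(root)
    return pd.DataFrame(rows, columns=["parent", "child", "kind", "probability", "cost", "qaly"])
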