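"""Decision-tree containers and exact expected-value evaluation.

Payoffs live only at leaves; intervention-delivery cost and
outcome-phase care cost are kept as separate leaf components so the
societal perspective (which amplifies a designated subset of costs) can
be applied after evaluation without rebuilding the tree.

Evaluation is exact probability-weighted summation (no simulation).
Branches are visited in sorted node-id order, so the floating-point
summation order — and therefore the result — is reproducible.
:func:`enumerate_paths` provides an independent root-to-leaf oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional

from .parameters import PROB_TOL, HorizonSpec, Utilities

__all__ = [
    "LeafPayoff",
    "Node",
    "DecisionTree",
    "ArmResult",
    "PathRecord",
    "TreeInvalidError",
    "evaluate",
    "enumerate_paths",
    "accrue_qalys",
]


class TreeInvalidError(ValueError):
    pass


@dataclass(frozen=True)
class LeafPayoff:
    """Per-patient payoff at a terminal node.

    ``cost_intervention``: delivery cost of the treatment itself.
    ``cost_outcome``: follow-up-phase healthcare cost of the reached
    outcome (the component designated work-relevant under the societal
    perspective's default mode).
    ``qaly``: QALYs accrued over the whole 26-week horizon.
    """

    cost_intervention: float
    cost_outcome: float
    qaly: float

    @property
    def cost_healthcare(self) -> float:
        return self.cost_intervention + self.cost_outcome


@dataclass(frozen=True)
class Node:
    """Chance node (with branches) or terminal node (with payoff)."""

    node_id: str
    branches: Optional[tuple[tuple[float, "Node"], ...]] = None
    payoff: Optional[LeafPayoff] = None

    @property
    def is_leaf(self) -> bool:
        return self.branches is None

    def __post_init__(self):
        if (self.branches is None) == (self.payoff is None):
            raise TreeInvalidError(
                f"node {self.node_id!r} must have exactly one of branches/payoff"
            )


@dataclass(frozen=True)
class DecisionTree:
    arm_id: str
    root: Node

    def to_json_dict(self) -> dict:
        """Serialisable view: node ids, branch probabilities, leaf payoffs."""

        def conv(node: Node) -> dict:
            if node.is_leaf:
                p = node.payoff
                return {
                    "id": node.node_id,
                    "payoff": {
                        "cost_intervention": p.cost_intervention,
                        "cost_outcome": p.cost_outcome,
                        "qaly": p.qaly,
                    },
                }
            return {
                "id": node.node_id,
                "branches": [
                    {"probability": prob, "node": conv(child)}
                    for prob, child in node.branches
                ],
            }

        return {"arm_id": self.arm_id, "root": conv(self.root)}


@dataclass(frozen=True)
class ArmResult:
    """Expected payoffs for one arm.

    ``expected_cost_societal`` is populated by
    :func:`psilocea.cea.apply_perspective`; until then it is None.
    """

    arm_id: str
    expected_cost_healthcare: float
    expected_qalys: float
    expected_cost_intervention: float
    expected_cost_outcome: float
    expected_cost_societal: Optional[float] = None

    def cost(self, perspective) -> float:
        from .parameters import Perspective

        if perspective == Perspective.SOCIETAL or perspective == "societal":
            if self.expected_cost_societal is None:
                raise ValueError("societal cost not computed; apply_perspective first")
            return self.expected_cost_societal
        return self.expected_cost_healthcare

    def with_societal(self, cost: float) -> "ArmResult":
        return replace(self, expected_cost_societal=cost)


@dataclass(frozen=True)
class PathRecord:
    leaf_id: str
    probability: float
    cost_intervention: float
    cost_outcome: float
    qaly: float

    @property
    def cost_healthcare(self) -> float:
        return self.cost_intervention + self.cost_outcome


def _check_chance_node(node: Node) -> None:
    total = math.fsum(p for p, _ in node.branches)
    if abs(total - 1.0) > PROB_TOL:
        raise TreeInvalidError(
            f"branch probabilities at {node.node_id!r} sum to {total}, not 1"
        )
    for p, _ in node.branches:
        if p < -PROB_TOL or p > 1.0 + PROB_TOL:
            raise TreeInvalidError(
                f"branch probability {p} at {node.node_id!r} outside [0, 1]"
            )


def _sorted_branches(node: Node):
    return sorted(node.branches, key=lambda b: b[1].node_id)


def evaluate(tree: DecisionTree) -> ArmResult:
    """Expected cost components and QALYs by exact recursion.

    Refuses trees whose chance-node probabilities do not sum to 1
    within ``1e-9``.
    """

    def rec(node: Node) -> tuple[float, float, float]:
        if node.is_leaf:
            p = node.payoff
            return (p.cost_intervention, p.cost_outcome, p.qaly)
        _check_chance_node(node)
        ci = co = q = 0.0
        for prob, child in _sorted_branches(node):
            sci, sco, sq = rec(child)
            ci += prob * sci
            co += prob * sco
            q += prob * sq
        return (ci, co, q)

    ci, co, q = rec(tree.root)
    return ArmResult(
        arm_id=tree.arm_id,
        expected_cost_healthcare=ci + co,
        expected_qalys=q,
        expected_cost_intervention=ci,
        expected_cost_outcome=co,
    )


def enumerate_paths(tree: DecisionTree) -> list[PathRecord]:
    """All root-to-leaf paths with their probability products.

    Independent oracle for :func:`evaluate`: aggregating
    ``probability * payoff`` over the returned records reproduces the
    recursive expectation.
    """

    def walk(node: Node, prob: float) -> Iterator[PathRecord]:
        if node.is_leaf:
            p = node.payoff
            yield PathRecord(
                leaf_id=node.node_id,
                probability=prob,
                cost_intervention=p.cost_intervention,
                cost_outcome=p.cost_outcome,
                qaly=p.qaly,
            )
            return
        _check_chance_node(node)
        for bp, child in _sorted_branches(node):
            yield from walk(child, prob * bp)

    return list(walk(tree.root, 1.0))


def aggregate_paths(paths: list[PathRecord]) -> tuple[float, float, float]:
    """(expected healthcare cost, expected outcome-component cost, QALYs)."""
    cost = math.fsum(r.probability * r.cost_healthcare for r in paths)
    outcome = math.fsum(r.probability * r.cost_outcome for r in paths)
    qaly = math.fsum(r.probability * r.qaly for r in paths)
    return cost, outcome, qaly


def accrue_qalys(
    state_utility: float,
    relapsed: bool,
    utilities: Utilities,
    horizon: HorizonSpec,
    policy: str = "baseline-acute",
) -> float:
    """QALYs over the whole horizon for one terminal state.

    Under ``"baseline-acute"`` the 6-week acute phase accrues at
    ``u_baseline`` (every patient is still in-episode during treatment);
    it falls back to the state utility when ``u_baseline`` is absent.
    Under ``"state-acute"`` the acute phase accrues at the terminal
    state's utility.  Follow-up accrues at the state utility; relapsers
    switch to ``u_relapse`` at ``relapse_midpoint_fraction`` of the
    follow-up phase.
    """
    if policy == "baseline-acute":
        u_acute = (
            utilities.u_baseline if utilities.u_baseline is not None else state_utility
        )
    elif policy == "state-acute":
        u_acute = state_utility
    else:
        raise ValueError(f"unknown QALY accrual policy {policy!r}")

    fu = horizon.followup_weeks
    if relapsed:
        f = horizon.relapse_midpoint_fraction
        followup_qaly_weeks = fu * f * state_utility + fu * (1 - f) * utilities.u_relapse
    else:
        followup_qaly_weeks = fu * state_utility
    return (horizon.acute_weeks * u_acute + followup_qaly_weeks) / horizon.weeks_per_year
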