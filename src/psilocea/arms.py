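"""Build the four treatment-arm decision trees.

Tree topology (identical for every arm)::

    root ── complete ── remission ───── relapse / no relapse
         │           ├─ response ────── relapse / no relapse
         │           └─ no_response                      (terminal)
         └─ dropout ─── spont_remission ─ relapse / no relapse
                     ├─ improve_no_remission ─ relapse / no relapse
                     └─ no_improvement                   (terminal)

Ten leaves per arm.  The PAP and SSRI arms take their probabilities
directly from the parameter set; CBT and SSRI+CBT are derived from the
SSRI arm by relative risks.  Interior costs (treatment delivery) are
pushed down to leaves at build time so the tree engine only ever sees
leaf payoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .parameters import (
    ArmProbabilities,
    ParameterSet,
    RelativeRisks,
)
from .tree import DecisionTree, LeafPayoff, Node, accrue_qalys

__all__ = [
    "ARM_IDS",
    "ArmSpec",
    "InterventionCost",
    "DerivationError",
    "derive_arm_probabilities",
    "resolve_arm",
    "intervention_cost",
    "relapse_incremental_cost",
    "build_arm_spec",
    "build_arm_tree",
]

ARM_IDS = ("pap", "ssri", "cbt", "combo")

# terminal state -> utility key used for QALY accrual
_STATE_UTILITY = {
    "remission": "remission",
    "response": "response",
    "no_response": "no_response",
    "spont_remission": "remission",
    "improve_no_remission": "response",
    "no_improvement": "no_response",
}


class DerivationError(ValueError):
    """A relative risk pushed a derived probability outside [0, 1]."""


def derive_arm_probabilities(
    ssri: ArmProbabilities,
    rr: RelativeRisks,
    p_relapse: float | None = None,
) -> ArmProbabilities:
    """Apply relative risks to the SSRI arm to obtain a derived arm.

    Dropout probability and the completer remission/response
    probabilities are scaled by their relative risks; the completer
    no-response probability is the residual.  The dropout outcome split
    is inherited unchanged (dropouts receive no treatment effect).
    """
    p_dropout = rr.rr_dropout * ssri.p_dropout
    if p_dropout > 1.0:
        raise DerivationError(
            f"rr_dropout * p_dropout = {rr.rr_dropout} * {ssri.p_dropout} "
            f"= {p_dropout} > 1"
        )
    p_rem = rr.rr_remission * ssri.completer.p_remission
    if p_rem > 1.0:
        raise DerivationError(
            f"rr_remission * p_remission = {rr.rr_remission} * "
            f"{ssri.completer.p_remission} = {p_rem} > 1"
        )
    p_resp = rr.rr_response * ssri.completer.p_response
    if p_resp > 1.0:
        raise DerivationError(
            f"rr_response * p_response = {rr.rr_response} * "
            f"{ssri.completer.p_response} = {p_resp} > 1"
        )
    p_nr = 1.0 - p_rem - p_resp
    if p_nr < 0.0:
        raise DerivationError(
            f"derived remission + response = {p_rem + p_resp} > 1 "
            "(no-response residual negative)"
        )
    return ArmProbabilities(
        p_complete=1.0 - p_dropout,
        completer={
            "p_remission": p_rem,
            "p_response": p_resp,
            "p_no_response": p_nr,
        },
        dropout=ssri.dropout,
        p_relapse=ssri.p_relapse if p_relapse is None else p_relapse,
    )


def resolve_arm(params: ParameterSet, arm_id: str) -> ArmProbabilities:
    """The fully-resolved probabilities for any of the four arms."""
    if arm_id == "pap":
        return params.pap
    if arm_id == "ssri":
        return params.ssri
    if arm_id == "cbt":
        return derive_arm_probabilities(
            params.ssri, params.cbt.rr, p_relapse=params.cbt.p_relapse
        )
    if arm_id == "combo":
        return derive_arm_probabilities(
            params.ssri, params.combo.rr, p_relapse=params.combo.p_relapse
        )
    raise ValueError(f"unknown arm {arm_id!r}; expected one of {ARM_IDS}")


@dataclass(frozen=True)
class InterventionCost:
    """Itemised treatment-delivery cost for one arm, per patient.

    Completers and dropouts are itemised separately: dropouts incur a
    configurable fraction of the therapist/CBT course and no further
    medication.  The psilocybin drug component carries
    ``drug_cost_weight`` (expected uptake of the two-dose course), so
    expected PAP cost rises with price at slope ``drug_cost_weight``.
    """

    arm_id: str
    drug: float = 0.0
    therapist: float = 0.0
    medication: float = 0.0
    cbt_course: float = 0.0
    dropout_drug: float = 0.0
    dropout_therapist: float = 0.0
    dropout_medication: float = 0.0
    dropout_cbt_course: float = 0.0

    @property
    def completer_total(self) -> float:
        return self.drug + self.therapist + self.medication + self.cbt_course

    @property
    def dropout_total(self) -> float:
        return (
            self.dropout_drug
            + self.dropout_therapist
            + self.dropout_medication
            + self.dropout_cbt_course
        )


def intervention_cost(
    arm_id: str, params: ParameterSet, price: float | None = None
) -> InterventionCost:
    """Treatment-delivery cost components for an arm at a psilocybin price.

    ``price`` defaults to ``costs.psilocybin_price`` and only matters
    for the PAP arm.
    """
    c = params.costs
    if price is None:
        price = c.psilocybin_price
    if price < 0:
        raise ValueError(f"psilocybin price must be non-negative, got {price}")
    frac = c.dropout_intervention_fraction
    if arm_id == "pap":
        drug = c.drug_cost_weight * price
        therapist = c.therapist_hours * c.therapist_unit_cost_value
        return InterventionCost(
            arm_id=arm_id,
            drug=drug,
            therapist=therapist,
            dropout_drug=drug,
            dropout_therapist=frac * therapist,
        )
    if arm_id == "ssri":
        return InterventionCost(
            arm_id=arm_id, medication=c.ssri_daily_cost * c.ssri_days
        )
    if arm_id == "cbt":
        return InterventionCost(
            arm_id=arm_id,
            cbt_course=c.cbt_course_cost,
            dropout_cbt_course=frac * c.cbt_course_cost,
        )
    if arm_id == "combo":
        return InterventionCost(
            arm_id=arm_id,
            medication=c.ssri_daily_cost * c.ssri_days,
            cbt_course=c.cbt_course_cost,
            dropout_cbt_course=frac * c.cbt_course_cost,
        )
    raise ValueError(f"unknown arm {arm_id!r}; expected one of {ARM_IDS}")


def relapse_incremental_cost(
    c_relapse_full: float, c_maintenance_full: float
) -> float:
    """Extra follow-up cost incurred by a relapser, beyond maintenance.

    Relapse occurs on average halfway through follow-up, so the
    full-period relapse cost is halved and half the full-period
    maintenance cost is subtracted (that half is no longer incurred):
    ``c_relapse_full/2 - c_maintenance_full/2``.
    """
    if c_relapse_full < 0 or c_maintenance_full < 0:
        raise ValueError(
            "relapse/maintenance costs must be non-negative, got "
            f"({c_relapse_full}, {c_maintenance_full})"
        )
    value = c_relapse_full / 2.0 - c_maintenance_full / 2.0
    if value < 0:
        warnings.warn(
            "maintenance cost exceeds relapse cost; incremental relapse "
            f"cost is negative ({value})",
            stacklevel=2,
        )
    return value


def _outcome_cost(state: str, relapsed: bool, params: ParameterSet) -> float:
    """Follow-up-phase healthcare cost for a terminal state."""
    c = params.costs
    if state in ("no_response", "no_improvement"):
        return c.c_no_response
    if relapsed:
        return c.c_maintenance_full + relapse_incremental_cost(
            c.c_relapse_full, c.c_maintenance_full
        )
    return c.c_maintenance_full


@dataclass(frozen=True)
class ArmSpec:
    """Everything needed to build one arm's tree at one psilocybin price."""

    arm_id: str
    probabilities: ArmProbabilities
    intervention: InterventionCost
    price: float


def build_arm_spec(
    arm_id: str, params: ParameterSet, price: float | None = None
) -> ArmSpec:
    if price is None:
        price = params.costs.psilocybin_price
    return ArmSpec(
        arm_id=arm_id,
        probabilities=resolve_arm(params, arm_id),
        intervention=intervention_cost(arm_id, params, price),
        price=price,
    )


def build_arm_tree(
    arm: str | ArmSpec, params: ParameterSet, price: float | None = None
) -> DecisionTree:
    """Construct the ten-leaf decision tree for one arm.

    Each leaf carries the treatment-delivery cost appropriate to its
    completion status, the outcome-phase care cost of its terminal
    state, and the QALYs accrued under the configured policy.
    """
    spec = arm if isinstance(arm, ArmSpec) else build_arm_spec(arm, params, price)
    probs = spec.probabilities
    u = params.utilities
    h = params.horizon
    policy = params.analysis.qaly_policy

    def leaf(path: str, state: str, relapsed: bool, completer: bool) -> Node:
        state_u = u.for_state(_STATE_UTILITY[state])
        payoff = LeafPayoff(
            cost_intervention=(
                spec.intervention.completer_total
                if completer
                else spec.intervention.dropout_total
            ),
            cost_outcome=_outcome_cost(state, relapsed, params),
            qaly=accrue_qalys(state_u, relapsed, u, h, policy=policy),
        )
        return Node(node_id=path, payoff=payoff)

    def outcome_node(prefix: str, state: str, completer: bool) -> Node:
        path = f"{prefix}/{state}"
        if state in ("no_response", "no_improvement"):
            return leaf(path, state, relapsed=False, completer=completer)
        return Node(
            node_id=path,
            branches=(
                (probs.p_relapse, leaf(f"{path}/relapse", state, True, completer)),
                (
                    1.0 - probs.p_relapse,
                    leaf(f"{path}/no_relapse", state, False, completer),
                ),
            ),
        )

    complete = Node(
        node_id="complete",
        branches=(
            (probs.completer.p_remission, outcome_node("complete", "remission", True)),
            (probs.completer.p_response, outcome_node("complete", "response", True)),
            (
                probs.completer.p_no_response,
                outcome_node("complete", "no_response", True),
            ),
        ),
    )
    dropout = Node(
        node_id="dropout",
        branches=(
            (
                probs.dropout.p_spont_remission,
                outcome_node("dropout", "spont_remission", False),
            ),
            (
                probs.dropout.p_improve_no_remission,
                outcome_node("dropout", "improve_no_remission", False),
            ),
            (
                probs.dropout.p_no_improvement,
                outcome_node("dropout", "no_improvement", False),
            ),
        ),
    )
    root = Node(
        node_id="root",
        branches=((probs.p_complete, complete), (1.0 - probs.p_complete, dropout)),
    )
    return DecisionTree(arm_id=spec.arm_id, root=root)
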