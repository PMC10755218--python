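"""Incremental cost-effectiveness of PAP against each comparator.

Because the primary question is whether psilocybin-assisted
psychotherapy is worth funding, comparisons are pairwise — PAP against
the SSRI, CBT, and SSRI+CBT arms separately — rather than a four-way
frontier analysis.  The psilocybin price is not fixed but swept over a
grid (GBP 400–2000 by default); comparator results are price-invariant,
so the ICER against each comparator is a non-decreasing function of
price.

Perspectives
------------
Healthcare: intervention-delivery plus outcome-phase care costs.
Societal: adds lost-work costs, taken to be ``societal_multiplier``
times the work-relevant healthcare costs.  By default only the
outcome-phase care costs are designated work-relevant — lost work
tracks how ill people remain after treatment, not how the treatment was
delivered — so arms with better outcomes save proportionally more under
the societal perspective.  A strict mode (``multiplier_mode="all"``)
applies the multiplier to every healthcare cost instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .arms import ARM_IDS, build_arm_tree
from .parameters import AnalysisSpec, ParameterSet, Perspective
from .tree import ArmResult, evaluate

__all__ = [
    "Classification",
    "ICERResult",
    "ThresholdResult",
    "COMPARATORS",
    "apply_perspective",
    "arm_results",
    "icer",
    "icer_grid",
    "net_monetary_benefit",
    "is_cost_effective",
    "threshold_table",
    "threshold_price_search",
]

COMPARATORS = ("ssri", "cbt", "combo")


class Classification(str, Enum):
    ICER = "icer"
    PAP_DOMINATES = "pap_dominates"
    PAP_DOMINATED = "pap_dominated"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class ICERResult:
    """One pairwise comparison of PAP against a comparator.

    ``icer_value`` is present only when an ICER is meaningful: PAP more
    costly and more effective (north-east quadrant) or cheaper and less
    effective (south-west quadrant).  Dominance — cheaper and at least
    as effective, or the reverse — is classified instead of ratioed.
    """

    comparison: str  # comparator arm id
    delta_cost: float
    delta_qalys: float
    classification: Classification
    perspective: Perspective
    price: float
    icer_value: Optional[float] = None


@dataclass(frozen=True)
class ThresholdResult:
    comparison: str
    perspective: Perspective
    threshold: float
    max_cost_effective_price: Optional[float]
    dominance_price_ceiling: Optional[float]


def apply_perspective(result: ArmResult, spec: AnalysisSpec) -> ArmResult:
    """Fill in the societal cost on an evaluated ArmResult.

    societal = healthcare + multiplier x (work-relevant costs), where the
    work-relevant set is the outcome-phase costs (default) or all
    healthcare costs (``multiplier_mode="all"``).
    """
    if spec.multiplier_mode == "all":
        base = result.expected_cost_healthcare
    elif spec.multiplier_mode == "outcome":
        base = result.expected_cost_outcome
    else:
        raise ValueError(f"unknown multiplier_mode {spec.multiplier_mode!r}")
    societal = result.expected_cost_healthcare + spec.societal_multiplier * base
    return result.with_societal(societal)


def arm_results(
    params: ParameterSet, price: float | None = None
) -> dict[str, ArmResult]:
    """Evaluate all four arms at one psilocybin price.

    Returns results with both healthcare and societal costs populated.
    """
    out = {}
    for arm_id in ARM_IDS:
        tree = build_arm_tree(arm_id, params, price)
        out[arm_id] = apply_perspective(evaluate(tree), params.analysis)
    return out


def icer(
    pap: ArmResult,
    comparator: ArmResult,
    perspective: Perspective | str = Perspective.HEALTHCARE,
    price: float | None = None,
) -> ICERResult:
    """Classify and, where meaningful, compute the pairwise ICER."""
    perspective = Perspective(perspective)
    dc = pap.cost(perspective) - comparator.cost(perspective)
    dq = pap.expected_qalys - comparator.expected_qalys

    if dq == 0.0:
        # classification by cost alone; no ratio
        if dc < 0:
            cls = Classification.PAP_DOMINATES
        elif dc > 0:
            cls = Classification.PAP_DOMINATED
        else:
            cls = Classification.EQUIVALENT
        value = None
    elif dc <= 0 and dq > 0:
        cls, value = Classification.PAP_DOMINATES, None
    elif dc >= 0 and dq < 0:
        cls, value = Classification.PAP_DOMINATED, None
    else:
        cls, value = Classification.ICER, dc / dq
    return ICERResult(
        comparison=comparator.arm_id,
        delta_cost=dc,
        delta_qalys=dq,
        classification=cls,
        perspective=perspective,
        price=pap_price(pap, price),
        icer_value=value,
    )


def pap_price(pap: ArmResult, price: float | None) -> float:
    return float("nan") if price is None else float(price)


def net_monetary_benefit(result: ArmResult, threshold: float, perspective) -> float:
    """NMB = threshold x QALYs - cost."""
    return threshold * result.expected_qalys - result.cost(perspective)


def is_cost_effective(res: ICERResult, threshold: float) -> bool:
    """Decision rule on the ICER plane at willingness-to-pay ``threshold``.

    PAP is cost-effective if it dominates; if it buys QALYs at
    ``icer <= threshold`` (an ICER exactly at the threshold counts); or
    if it forgoes QALYs at a saving rate ``icer >= threshold``.
    Equivalent arms are treated as cost-effective (nothing is lost).
    """
    if res.classification is Classification.PAP_DOMINATES:
        return True
    if res.classification is Classification.PAP_DOMINATED:
        return False
    if res.classification is Classification.EQUIVALENT:
        return True
    if res.delta_qalys > 0:
        return res.icer_value <= threshold
    return res.icer_value >= threshold


def icer_grid(
    params: ParameterSet,
    perspectives: tuple = (Perspective.HEALTHCARE, Perspective.SOCIETAL),
    prices: list[float] | None = None,
) -> pd.DataFrame:
    """All pairwise ICERs over the price grid and perspectives.

    One row per comparison x price x perspective; the data behind the
    ICER-versus-price curves.
    """
    if prices is None:
        prices = params.analysis.price_grid
    rows = []
    for price in prices:
        results = arm_results(params, price)
        for perspective in perspectives:
            for comp in COMPARATORS:
                r = icer(results["pap"], results[comp], perspective, price)
                rows.append(
                    {
                        "price": price,
                        "perspective": Perspective(perspective).value,
                        "comparison": comp,
                        "delta_cost": r.delta_cost,
                        "delta_qalys": r.delta_qalys,
                        "classification": r.classification.value,
                        "icer": r.icer_value,
                    }
                )
    return pd.DataFrame(rows)


def threshold_table(
    params: ParameterSet,
    prices: list[float] | None = None,
    perspectives: tuple = (Perspective.HEALTHCARE, Perspective.SOCIETAL),
    thresholds: list[float] | None = None,
) -> list[ThresholdResult]:
    """Threshold-price results for every comparison in one grid pass.

    For each comparison x perspective x threshold, finds the largest
    grid price whose pairwise comparison passes
    :func:`is_cost_effective`, and the largest price (if any) at which
    PAP strictly dominates.  Because expected PAP cost is non-decreasing
    in price while comparators are price-invariant, the qualifying set
    is a prefix of the grid.
    """
    if prices is None:
        prices = params.analysis.price_grid
    if thresholds is None:
        thresholds = params.analysis.wtp_thresholds
    perspectives = tuple(Perspective(p) for p in perspectives)
    max_ce: dict = {}
    max_dom: dict = {}
    for price in prices:
        results = arm_results(params, price)
        for perspective in perspectives:
            for comp in COMPARATORS:
                r = icer(results["pap"], results[comp], perspective, price)
                for t in thresholds:
                    if is_cost_effective(r, t):
                        key = (comp, perspective, t)
                        max_ce[key] = max(max_ce.get(key, price), price)
                if r.classification is Classification.PAP_DOMINATES:
                    key = (comp, perspective)
                    max_dom[key] = max(max_dom.get(key, price), price)
    return [
        ThresholdResult(
            comparison=comp,
            perspective=perspective,
            threshold=t,
            max_cost_effective_price=max_ce.get((comp, perspective, t)),
            dominance_price_ceiling=max_dom.get((comp, perspective)),
        )
        for comp in COMPARATORS
        for perspective in perspectives
        for t in thresholds
    ]


def threshold_price_search(
    params: ParameterSet,
    comparison: str,
    perspective: Perspective | str,
    threshold: float,
    prices: list[float] | None = None,
) -> ThresholdResult:
    """Largest grid price at which PAP remains cost-effective vs one comparator."""
    perspective = Perspective(perspective)
    table = threshold_table(
        params, prices=prices, perspectives=(perspective,), thresholds=[threshold]
    )
    return next(t for t in table if t.comparison == comparison)
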