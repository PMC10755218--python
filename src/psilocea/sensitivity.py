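"""Deterministic sensitivity analysis.

Every scenario modifies one parameter family (multiplicatively or by
replacement) and is then crossed with the full psilocybin price grid,
so all analyses are two-way with price.  The catalogue covers the six
families that drive the results:

(i)   remission and response probabilities for each therapy,
(ii)  relapse probabilities,
(iii) cost of the therapist support around psilocybin dosing,
(iv)  cost of the CBT course,
(v)   healthcare costs following each outcome,
(vi)  the lost-work cost multiplier.

Probability modifications keep the arm's distribution on the simplex by
the residual rule: the modified remission/response mass is taken from
(or returned to) the no-response residual, response held fixed when
remission moves and vice versa.  A modification that pushes any
probability outside [0, 1] is never silently truncated; the modified
set fails validation and the scenario is flagged ``skipped_invalid``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cea import icer_grid, threshold_table
from .parameters import ParameterSet, ValidationReport, validate

__all__ = [
    "Modification",
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioInvalidError",
    "apply_scenario",
    "paper_scenario_catalogue",
    "run_scenario",
    "scenario_summary",
]

# completer-probability paths that trigger residual renormalisation
_COMPLETER_PREFIXES = ("pap.completer.", "ssri.completer.")

_FACTORS = {"-50pct": 0.5, "-25pct": 0.75, "+25pct": 1.25, "+50pct": 1.5}


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero, matching how varied values are reported.

    Works on the shortest decimal representation so 0.57 * 1.5 -> 0.855
    rounds up to 0.86 rather than down through its binary neighbour.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


class ScenarioInvalidError(ValueError):
    def __init__(self, name: str, report: ValidationReport):
        self.report = report
        failures = "; ".join(c.message for c in report.failures)
        super().__init__(f"scenario {name!r} produces an invalid parameter set: {failures}")


@dataclass(frozen=True)
class Modification:
    """One edit to a dotted path into the ParameterSet.

    ``op`` is ``"multiply"`` or ``"set"``; ``round_to`` optionally
    rounds the modified value to a number of decimals (used to mirror
    reported roundings such as 0.57 * 1.5 -> 0.86).
    """

    path: str
    op: str
    amount: float
    round_to: Optional[int] = None


@dataclass
class ScenarioSpec:
    name: str
    family: str
    modifications: list[Modification]
    skipped_invalid: Optional[bool] = None  # set when checked against a base set

    def describe(self) -> str:
        mods = ", ".join(
            f"{m.path} {'x' if m.op == 'multiply' else '='} {m.amount}"
            for m in self.modifications
        )
        return f"{self.name} [{self.family}]: {mods}"


@dataclass
class ScenarioResult:
    name: str
    params: ParameterSet
    icers: pd.DataFrame
    thresholds: list  # ThresholdResult per comparison x perspective x threshold


def _get_parent(params: ParameterSet, path: str):
    parts = path.split(".")
    obj = params
    for part in parts[:-1]:
        obj = getattr(obj, part)
    return obj, parts[-1]


def apply_scenario(params: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a modified deep copy; no validation is performed here."""
    modified = params.model_copy(deep=True)
    touched_completers = set()
    for mod in spec.modifications:
        parent, attr = _get_parent(modified, mod.path)
        old = getattr(parent, attr)
        if mod.op == "multiply":
            new = old * mod.amount
        elif mod.op == "set":
            new = mod.amount
        else:
            raise ValueError(f"unknown modification op {mod.op!r}")
        if mod.round_to is not None:
            new = _round_half_up(new, mod.round_to)
        setattr(parent, attr, new)
        for prefix in _COMPLETER_PREFIXES:
            if mod.path.startswith(prefix):
                touched_completers.add(prefix.split(".")[0])
    # residual rule: no-response absorbs the change
    for arm_name in touched_completers:
        comp = getattr(modified, arm_name).completer
        comp.p_no_response = 1.0 - comp.p_remission - comp.p_response
    return modified


def paper_scenario_catalogue(
    base: ParameterSet | None = None, round_probabilities: bool = True
) -> list[ScenarioSpec]:
    """The deterministic scenario catalogue, six families at +/-25/50%.

    When ``base`` is given, each scenario is pre-checked against it and
    flagged ``skipped_invalid`` if the modified set fails validation
    (e.g. a +50% probability exceeding 1).  When
    ``round_probabilities`` is set, scaled probabilities are rounded to
    two decimals, mirroring how varied probabilities are reported
    (0.57 increased by 50% is treated as 0.86, not 0.855).
    """
    prob_round = 2 if round_probabilities else None
    specs: list[ScenarioSpec] = []

    def add(name, family, mods):
        specs.append(ScenarioSpec(name=name, family=family, modifications=mods))

    # (i) remission and response for each therapy
    for arm in ("pap", "ssri"):
        for short, fld in (("remission", "p_remission"), ("response", "p_response")):
            for tag, factor in _FACTORS.items():
                add(
                    f"{arm}_{short}_{tag}",
                    "remission_response",
                    [
                        Modification(
                            f"{arm}.completer.{fld}", "multiply", factor, prob_round
                        )
                    ],
                )
    for arm in ("cbt", "combo"):
        for short, fld in (("remission", "rr_remission"), ("response", "rr_response")):
            for tag, factor in _FACTORS.items():
                add(
                    f"{arm}_{short}_{tag}",
                    "remission_response",
                    [Modification(f"{arm}.rr.{fld}", "multiply", factor)],
                )

    # (ii) relapse rates
    for arm in ("pap", "ssri", "cbt", "combo"):
        for tag, factor in _FACTORS.items():
            add(
                f"{arm}_relapse_{tag}",
                "relapse",
                [Modification(f"{arm}.p_relapse", "multiply", factor)],
            )

    # (iii) therapist support cost (scales the 38 h of support linearly)
    for tag, factor in _FACTORS.items():
        add(
            f"therapist_support_{tag}",
            "therapist_support",
            [Modification("costs.therapist_base_rate", "multiply", factor)],
        )

    # (iv) CBT course cost
    for tag, factor in _FACTORS.items():
        add(
            f"cbt_cost_{tag}",
            "cbt_cost",
            [Modification("costs.cbt_course_cost", "multiply", factor)],
        )

    # (v) healthcare costs following each outcome
    for tag, factor in _FACTORS.items():
        add(
            f"outcome_costs_{tag}",
            "outcome_costs",
            [
                Modification("costs.c_relapse_full", "multiply", factor),
                Modification("costs.c_maintenance_full", "multiply", factor),
                Modification("costs.c_no_response", "multiply", factor),
            ],
        )

    # (vi) lost-work multiplier
    for tag, factor in _FACTORS.items():
        add(
            f"lost_work_multiplier_{tag}",
            "lost_work_multiplier",
            [Modification("analysis.societal_multiplier", "multiply", factor)],
        )

    if base is not None:
        for spec in specs:
            modified = apply_scenario(base, spec)
            spec.skipped_invalid = not validate(modified).ok
    return specs


def run_scenario(params: ParameterSet, spec: ScenarioSpec) -> ScenarioResult:
    """Evaluate the full CEA grid under one scenario.

    Equivalent to modifying the parameter set and re-running the base
    analysis; an identity scenario (factor 1) reproduces base-case
    results exactly.
    """
    modified = apply_scenario(params, spec)
    report = validate(modified)
    if not report.ok:
        raise ScenarioInvalidError(spec.name, report)
    icers = icer_grid(modified)
    thresholds = threshold_table(modified)
    return ScenarioResult(name=spec.name, params=modified, icers=icers, thresholds=thresholds)


def scenario_summary(
    params: ParameterSet,
    specs: list[ScenarioSpec] | None = None,
    reporting_grid: bool = True,
) -> pd.DataFrame:
    """Maximum cost-effective psilocybin price per scenario.

    One row per scenario x comparison x perspective x threshold, giving
    the largest price (on the GBP 200-step reporting grid by default)
    at which PAP is cost-effective, plus the largest price at which it
    strictly dominates.  Scenarios whose modified parameter set fails
    validation are reported with status ``skipped_invalid``.
    """
    if specs is None:
        specs = paper_scenario_catalogue(params)
    prices = (
        params.analysis.reporting_grid if reporting_grid else params.analysis.price_grid
    )
    rows = []
    for spec in specs:
        try:
            modified = apply_scenario(params, spec)
            report = validate(modified)
            if not report.ok:
                raise ScenarioInvalidError(spec.name, report)
        except ScenarioInvalidError:
            rows.append(
                {
                    "scenario": spec.name,
                    "family": spec.family,
                    "status": "skipped_invalid",
                    "comparison": None,
                    "perspective": None,
                    "threshold": None,
                    "max_cost_effective_price": None,
                    "dominance_price_ceiling": None,
                }
            )
            continue
        for tr in threshold_table(modified, prices=prices):
            rows.append(
                {
                    "scenario": spec.name,
                    "family": spec.family,
                    "status": "ok",
                    "comparison": tr.comparison,
                    "perspective": tr.perspective.value,
                    "threshold": tr.threshold,
                    "max_cost_effective_price": tr.max_cost_effective_price,
                    "dominance_price_ceiling": tr.dominance_price_ceiling,
                }
            )
    return pd.DataFrame(rows)
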