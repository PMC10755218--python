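"""Parameter schema for the decision-tree cost-effectiveness model.

The model compares four treatment strategies for severe depression --
psilocybin-assisted psychotherapy (PAP), an SSRI alone (escitalopram),
CBT alone, and SSRI+CBT -- over a 26-week horizon split into a 6-week
acute phase and a 20-week follow-up phase.

A :class:`ParameterSet` holds everything the model needs:

* chance-node probabilities for the PAP and SSRI arms (the CBT and
  combination arms are derived from the SSRI arm by relative risks),
* health-state utility weights used to accrue QALYs,
* unit costs for delivering each intervention and for the care that
  follows each outcome,
* the horizon definition, the psilocybin price grid, and the
  willingness-to-pay thresholds.

Parameter files are YAML documents mirroring this schema; see
:func:`load_parameters` / :func:`save_parameters`.  All money is in GBP
at the published price year; the horizon is six months, so there is no
discounting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError
from pydantic import Field as PydanticField

__all__ = [
    "ArmProbabilities",
    "CompleterOutcomes",
    "DropoutOutcomes",
    "RelativeRisks",
    "DerivedArm",
    "Utilities",
    "CostInputs",
    "HorizonSpec",
    "AnalysisSpec",
    "Perspective",
    "ParameterSet",
    "ValidationReport",
    "CheckResult",
    "ParameterFormatError",
    "ParameterValidationError",
    "therapist_unit_cost",
    "load_parameters",
    "save_parameters",
    "validate",
]

PROB_TOL = 1e-9


class ParameterFormatError(ValueError):
    """A parameter file could not be parsed against the schema."""


class ParameterValidationError(ValueError):
    """A parsed parameter set violates model invariants.

    Carries the full :class:`ValidationReport` so every violated
    invariant is visible at once, not just the first.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        failures = "; ".join(c.message for c in report.failures)
        super().__init__(f"invalid parameter set: {failures}")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CompleterOutcomes(_Model):
    """Outcome split conditional on completing treatment."""

    p_remission: float
    p_response: float
    p_no_response: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_remission, self.p_response, self.p_no_response)


class DropoutOutcomes(_Model):
    """Outcome split conditional on dropping out of treatment.

    Dropouts receive no treatment response but may remit or improve
    spontaneously during follow-up.
    """

    p_spont_remission: float
    p_improve_no_remission: float
    p_no_improvement: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (
            self.p_spont_remission,
            self.p_improve_no_remission,
            self.p_no_improvement,
        )


class ArmProbabilities(_Model):
    """All chance-node probabilities for one treatment arm.

    ``p_relapse`` applies during follow-up to patients who achieved
    remission or sub-remission improvement (whether as completers or
    as dropouts).
    """

    p_complete: float
    completer: CompleterOutcomes
    dropout: DropoutOutcomes
    p_relapse: float

    @property
    def p_dropout(self) -> float:
        return 1.0 - self.p_complete


class RelativeRisks(_Model):
    """Relative risks applied to the SSRI arm to derive another arm.

    ``rr_dropout`` scales the probability of dropping out; ``rr_response``
    and ``rr_remission`` scale the completer outcome probabilities, the
    no-response probability being the residual.
    """

    rr_dropout: float
    rr_response: float
    rr_remission: float


class DerivedArm(_Model):
    """Specification of an arm derived from the SSRI arm (CBT, SSRI+CBT)."""

    rr: RelativeRisks
    p_relapse: float


class Utilities(_Model):
    """Health-state utility weights (QALY weight per year in state).

    ``u_baseline`` is the utility during the 6-week acute phase, when
    every patient is still in the depressive episode regardless of the
    outcome they eventually reach.  If omitted, the acute phase accrues
    at the terminal state's utility instead (see the QALY policy on
    :class:`AnalysisSpec`).
    """

    u_remission: float
    u_response: float
    u_no_response: float
    u_relapse: float
    u_baseline: Optional[float] = None

    def for_state(self, state: str) -> float:
        return {
            "remission": self.u_remission,
            "response": self.u_response,
            "no_response": self.u_no_response,
            "relapse": self.u_relapse,
        }[state]


class CostInputs(_Model):
    """Unit costs, all GBP.

    Intervention delivery
    ---------------------
    * PAP: 38 therapist hours per course (two guides across preparation,
      two dosing sessions, debriefs and calls), costed at a Band 7
      clinical psychologist rate of GBP 58/h uplifted by 30 minutes of
      non-direct time per contact hour (GBP 87/h), plus the psilocybin
      price itself.  ``drug_cost_weight`` is the fraction of the listed
      price that enters expected cost per patient entering the model;
      the default 0.95 reflects that a small share of patients do not
      take up the full two-dose course.
    * SSRI: escitalopram 10 mg/day, accruing for completers only and
      lasting through follow-up.
    * CBT: a 10-session course at GBP 1050.
    * Dropouts incur ``dropout_intervention_fraction`` of the
      therapist/CBT course cost (a partial course) and no further
      medication cost.

    Outcome-phase care (follow-up, per patient)
    -------------------------------------------
    ``c_relapse_full`` and ``c_maintenance_full`` are full-period care
    costs after relapse and after remission/response respectively;
    because relapse is assumed to occur on average halfway through
    follow-up, a relapser incurs half of each.  ``c_no_response`` is the
    full-period cost of continued care for non-responders.
    """

    psilocybin_price: float = 400.0
    therapist_hours: float = 38.0
    therapist_base_rate: float = 58.0
    nondirect_minutes_per_hour: float = 30.0
    ssri_daily_cost: float = 0.05
    ssri_days: float = 182.0
    cbt_course_cost: float = 1050.0
    c_relapse_full: float = 0.0
    c_maintenance_full: float = 0.0
    c_no_response: float = 0.0
    drug_cost_weight: float = 0.95
    dropout_intervention_fraction: float = 0.5

    @property
    def therapist_unit_cost_value(self) -> float:
        return therapist_unit_cost(
            self.therapist_base_rate, self.nondirect_minutes_per_hour
        )


class HorizonSpec(_Model):
    """Time horizon: 6-week acute phase plus 20-week follow-up.

    ``relapse_midpoint_fraction`` places the average relapse within the
    follow-up phase; 0.5 means relapse occurs on average halfway
    through, so relapsers spend half of follow-up in their achieved
    state and half in the relapse state.
    """

    acute_weeks: float = 6.0
    followup_weeks: float = 20.0
    relapse_midpoint_fraction: float = 0.5
    weeks_per_year: float = 52.0

    @property
    def total_weeks(self) -> float:
        return self.acute_weeks + self.followup_weeks


class Perspective(str, Enum):
    HEALTHCARE = "healthcare"
    SOCIETAL = "societal"


class AnalysisSpec(_Model):
    """What to compute and how to judge cost-effectiveness.

    ``societal_multiplier`` converts healthcare costs into lost-work
    costs (lost-work costs in treatment-resistant depression are around
    twice health-service costs, hence the default of 2).
    ``multiplier_mode`` controls which costs attract the multiplier:
    ``"outcome"`` (default) applies it to outcome-phase care costs only,
    ``"all"`` to every healthcare cost including intervention delivery.
    ``qaly_policy`` names the QALY-accrual convention: under
    ``"baseline-acute"`` (default) the acute phase accrues at
    ``u_baseline`` when provided; under ``"state-acute"`` it accrues at
    the terminal state's utility.
    """

    price_grid: list[float] = PydanticField(
        default_factory=lambda: [float(p) for p in range(400, 2001, 100)]
    )
    reporting_step: float = 200.0
    wtp_thresholds: list[float] = PydanticField(
        default_factory=lambda: [20000.0, 30000.0]
    )
    societal_multiplier: float = 2.0
    perspective: Perspective = Perspective.HEALTHCARE
    multiplier_mode: str = "outcome"
    qaly_policy: str = "baseline-acute"

    @property
    def reporting_grid(self) -> list[float]:
        """The coarser grid used in reported tables (default GBP 200 steps)."""
        lo = self.price_grid[0]
        return [p for p in self.price_grid if (p - lo) % self.reporting_step == 0]


class ParameterSet(_Model):
    """Complete model configuration.

    The PAP and SSRI arms are specified directly; the CBT and
    combination arms are derived by applying relative risks to the SSRI
    arm (with their own relapse probabilities).
    """

    pap: ArmProbabilities
    ssri: ArmProbabilities
    cbt: DerivedArm
    combo: DerivedArm
    utilities: Utilities
    costs: CostInputs
    horizon: HorizonSpec = HorizonSpec()
    analysis: AnalysisSpec = AnalysisSpec()
    provenance: dict[str, str] = {}


def therapist_unit_cost(base_rate: float, nondirect_minutes: float) -> float:
    """Hourly therapist cost including non-direct time.

    Each contact hour carries ``nondirect_minutes`` of non-direct time,
    so the effective unit cost is ``base_rate * (1 + nondirect_minutes/60)``.
    A Band 7 clinical psychologist at GBP 58/h with 30 minutes of
    non-direct time costs GBP 87/h.
    """
    if base_rate < 0 or nondirect_minutes < 0:
        raise ValueError(
            "therapist_unit_cost requires non-negative base_rate and minutes, "
            f"got ({base_rate}, {nondirect_minutes})"
        )
    return base_rate * (1.0 + nondirect_minutes / 60.0)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    message: str
    severity: str = "error"  # "error" or "warning"


@dataclass
class ValidationReport:
    """Outcome of every invariant check, failures and passes alike."""

    checks: list[CheckResult] = field(default_factory=list)

    def add(self, name: str, passed: bool, message: str, severity: str = "error"):
        self.checks.append(CheckResult(name, passed, message, severity))

    @property
    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed and c.severity == "error"]

    @property
    def warnings(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed and c.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": c.name,
                    "passed": c.passed,
                    "severity": c.severity,
                    "message": c.message,
                }
                for c in self.checks
            ],
            indent=2,
        )


def _check_distribution(report, name, entries: dict[str, float]):
    for key, p in entries.items():
        report.add(
            f"{name}.{key}.range",
            0.0 <= p <= 1.0,
            f"{name}.{key} = {p} outside [0, 1]",
        )
    total = math.fsum(entries.values())
    report.add(
        f"{name}.sum",
        abs(total - 1.0) <= PROB_TOL,
        f"{name} probabilities sum to {total}, not 1",
    )


def _check_arm(report: ValidationReport, arm_name: str, arm: ArmProbabilities):
    report.add(
        f"{arm_name}.p_complete.range",
        0.0 <= arm.p_complete <= 1.0,
        f"{arm_name}.p_complete = {arm.p_complete} outside [0, 1]",
    )
    report.add(
        f"{arm_name}.p_relapse.range",
        0.0 <= arm.p_relapse <= 1.0,
        f"{arm_name}.p_relapse = {arm.p_relapse} outside [0, 1]",
    )
    _check_distribution(
        report,
        f"{arm_name}.completer",
        {
            "p_remission": arm.completer.p_remission,
            "p_response": arm.completer.p_response,
            "p_no_response": arm.completer.p_no_response,
        },
    )
    _check_distribution(
        report,
        f"{arm_name}.dropout",
        {
            "p_spont_remission": arm.dropout.p_spont_remission,
            "p_improve_no_remission": arm.dropout.p_improve_no_remission,
            "p_no_improvement": arm.dropout.p_no_improvement,
        },
    )


def validate(params: ParameterSet) -> ValidationReport:
    """Check every model invariant and report all violations at once.

    The relative-risk-derived arms (CBT, combination) are resolved and
    re-checked, so an RR that would push a probability above 1 surfaces
    here rather than at tree-build time.
    """
    from .arms import derive_arm_probabilities  # deferred: avoid import cycle

    report = ValidationReport()

    _check_arm(report, "pap", params.pap)
    _check_arm(report, "ssri", params.ssri)

    for name, derived in (("cbt", params.cbt), ("combo", params.combo)):
        rr = derived.rr
        for fld in ("rr_dropout", "rr_response", "rr_remission"):
            v = getattr(rr, fld)
            report.add(
                f"{name}.{fld}.positive", v > 0, f"{name}.{fld} = {v} not > 0"
            )
        report.add(
            f"{name}.p_relapse.range",
            0.0 <= derived.p_relapse <= 1.0,
            f"{name}.p_relapse = {derived.p_relapse} outside [0, 1]",
        )
        try:
            resolved = derive_arm_probabilities(
                params.ssri, rr, p_relapse=derived.p_relapse
            )
        except ValueError as exc:
            report.add(f"{name}.derivable", False, f"{name}: {exc}")
        else:
            report.add(f"{name}.derivable", True, f"{name} arm resolvable")
            _check_arm(report, f"{name}(derived)", resolved)

    u = params.utilities
    for fld in ("u_remission", "u_response", "u_no_response", "u_relapse"):
        v = getattr(u, fld)
        report.add(
            f"utilities.{fld}.range",
            -1.0 <= v <= 1.0,
            f"utilities.{fld} = {v} outside [-1, 1]",
        )
    if u.u_baseline is not None:
        report.add(
            "utilities.u_baseline.range",
            -1.0 <= u.u_baseline <= 1.0,
            f"utilities.u_baseline = {u.u_baseline} outside [-1, 1]",
        )
    report.add(
        "utilities.ordering",
        u.u_remission >= u.u_response >= u.u_no_response,
        "expected u_remission >= u_response >= u_no_response "
        f"(got {u.u_remission}, {u.u_response}, {u.u_no_response})",
        severity="warning",
    )

    c = params.costs
    for fld in (
        "psilocybin_price",
        "therapist_hours",
        "therapist_base_rate",
        "nondirect_minutes_per_hour",
        "ssri_daily_cost",
        "ssri_days",
        "cbt_course_cost",
        "c_relapse_full",
        "c_maintenance_full",
        "c_no_response",
    ):
        v = getattr(c, fld)
        report.add(f"costs.{fld}.nonneg", v >= 0, f"costs.{fld} = {v} negative")
    report.add(
        "costs.drug_cost_weight.range",
        0.0 < c.drug_cost_weight <= 1.0,
        f"costs.drug_cost_weight = {c.drug_cost_weight} outside (0, 1]",
    )
    report.add(
        "costs.dropout_intervention_fraction.range",
        0.0 <= c.dropout_intervention_fraction <= 1.0,
        f"costs.dropout_intervention_fraction = {c.dropout_intervention_fraction} "
        "outside [0, 1]",
    )

    h = params.horizon
    report.add(
        "horizon.positive",
        h.acute_weeks > 0 and h.followup_weeks > 0 and h.weeks_per_year > 0,
        f"horizon weeks must be positive (got {h.acute_weeks}, {h.followup_weeks})",
    )
    report.add(
        "horizon.relapse_midpoint_fraction.range",
        0.0 < h.relapse_midpoint_fraction < 1.0,
        f"horizon.relapse_midpoint_fraction = {h.relapse_midpoint_fraction} "
        "outside (0, 1)",
    )

    a = params.analysis
    grid = a.price_grid
    report.add("analysis.price_grid.nonempty", len(grid) > 0, "price grid is empty")
    report.add(
        "analysis.price_grid.increasing",
        all(x < y for x, y in zip(grid, grid[1:])),
        f"price grid not strictly increasing: {grid}",
    )
    report.add(
        "analysis.price_grid.nonneg",
        all(p >= 0 for p in grid),
        "price grid contains negative prices",
    )
    report.add(
        "analysis.wtp_thresholds.positive",
        all(t > 0 for t in a.wtp_thresholds),
        f"thresholds must be positive: {a.wtp_thresholds}",
    )
    report.add(
        "analysis.societal_multiplier.nonneg",
        a.societal_multiplier >= 0,
        f"societal_multiplier = {a.societal_multiplier} negative",
    )
    report.add(
        "analysis.multiplier_mode.known",
        a.multiplier_mode in ("outcome", "all"),
        f"unknown multiplier_mode {a.multiplier_mode!r}",
    )
    report.add(
        "analysis.qaly_policy.known",
        a.qaly_policy in ("baseline-acute", "state-acute"),
        f"unknown qaly_policy {a.qaly_policy!r}",
    )

    for w in report.warnings:
        warnings.warn(w.message, stacklevel=2)
    return report


# ---------------------------------------------------------------------------
# File I/O


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and fully validate a YAML parameter file.

    Fields the model fixes by default (38 therapist hours, GBP 1050 CBT
    course, lost-work multiplier 2, the 6+20-week horizon, the GBP
    400-2000 price grid) may be omitted and are filled in.

    Raises
    ------
    ParameterFormatError
        if the file does not parse against the schema (the message names
        the offending keys).
    ParameterValidationError
        if any model invariant is violated; the attached report lists
        every violation.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterFormatError(f"{path}: expected a mapping at top level")
    try:
        params = ParameterSet(**raw)
    except ValidationError as exc:
        locs = ", ".join(
            ".".join(str(part) for part in err["loc"]) for err in exc.errors()
        )
        raise ParameterFormatError(f"{path}: invalid keys or values at: {locs}") from exc
    report = validate(params)
    if not report.ok:
        raise ParameterValidationError(report)
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet as YAML, round-trippable via load_parameters."""
    data = params.model_dump(mode="json", exclude_none=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
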