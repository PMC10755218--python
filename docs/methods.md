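# Methods

## Model structure and assumptions

The model is a static decision tree per treatment arm over a fixed
26-week horizon (6-week acute phase, 20-week follow-up). It assumes:

- Outcomes resolve at the end of the acute phase into one of three
  completer states (remission, response without remission, no
  response) or three dropout states (spontaneous remission,
  improvement without remission, no improvement). Dropouts receive no
  treatment effect; their outcome split is shared across arms.
- Relapse is a single binary event applying to remission *and*
  sub-remission improvement states, with one probability per arm, and
  occurs on average halfway through follow-up. No second-line
  treatment, no treatment sequences, no events beyond 26 weeks.
- Expected values are exact probability-weighted sums over the ten
  root-to-leaf paths (branches visited in sorted node-id order, so
  floating-point results are bit-reproducible). No discounting and no
  half-cycle correction beyond the explicit relapse-midpoint rule: the
  horizon is six months.
- The CBT and combination arms are not observed directly; they are the
  SSRI arm transformed by relative risks on dropout, response and
  remission, with no-response as the residual. A relative risk that
  would push any probability outside [0, 1] is a hard error, never a
  silent clamp.

## QALY accrual

QALYs weight time in state by utility. Two named policies are
implemented:

- `baseline-acute` (default): the acute phase accrues at `u_baseline`
  (all patients are still in the depressive episode while being
  treated), follow-up at the terminal state's utility; relapsers
  switch to `u_relapse` at `relapse_midpoint_fraction` (default 0.5)
  of follow-up.
- `state-acute`: the acute phase accrues at the terminal state's
  utility (used when no baseline utility is available).

The default was selected by calibration: `baseline-acute` reproduces
the published per-arm QALYs, while `state-acute` cannot (matching the
published values would require relapse probabilities above 1). With
every state utility equal to *u*, any arm's expected QALYs collapse to
*u*·26/52 regardless of probabilities — a structural identity used as a
test invariant.

## Costing

- **PAP**: drug price × `drug_cost_weight` + 38 therapist hours ×
  £87/h. The £87 unit cost is £58/h (Band 7 clinical psychologist,
  including capital and overheads) × (1 + 30/60) for 30 minutes of
  non-direct time per contact hour. `drug_cost_weight` defaults to
  0.95: the published PAP cost range (£6255 at a £400 price to £7775
  at £2000) implies the price enters expected cost with slope
  (7775−6255)/1600 = 0.95, which we interpret as the expected uptake
  of the full two-dose course and expose as a configuration field
  since no source states it directly.
- **SSRI**: escitalopram 10 mg/day for completers only, for the whole
  horizon (182 days).
- **CBT**: £1050 per ten-session course.
- **Dropouts** incur `dropout_intervention_fraction` (default 0.5) of
  the therapist/CBT course cost — a partial course — and no further
  medication cost. The value is a modelling assumption, configurable.
- **Outcome phase**: remission/response states incur a full-period
  maintenance cost; non-responders a full-period continued-care cost;
  relapsers incur half the maintenance and half the full-period
  relapse cost (relapse at the midpoint), i.e. maintenance plus the
  incremental `c_relapse_full/2 − c_maintenance_full/2`.

## Perspectives

Societal cost = healthcare cost + multiplier × (work-relevant costs),
multiplier 2 by default (lost-work costs in treatment-resistant
depression run at roughly twice health-service costs). Two modes are
provided because "applied to healthcare costs" is ambiguous:

- `outcome` (default): the multiplier applies to outcome-phase care
  costs only. Lost work tracks how ill people remain after treatment,
  not how the treatment was delivered, and this mode reproduces the
  published societal findings (PAP's position improves because its
  better outcomes avoid amplified downstream costs).
- `all`: the multiplier applies to every healthcare cost. Under this
  mode all costs scale by (1 + multiplier) and PAP's relative position
  cannot improve; provided for comparison.

## Decision rules

An ICER is reported only when a ratio is meaningful (PAP costlier and
more effective, or cheaper and less effective); otherwise the
comparison is classified as dominance. Cost-effectiveness at a
willingness-to-pay λ uses the standard quadrant rule, with a tie at
exactly λ counting as cost-effective. The net-monetary-benefit rule
(NMB = λ·Q − C) is implemented independently and the equivalence of
the two rules is a tested invariant. Threshold-price search scans the
price grid; because expected PAP cost is non-decreasing in price and
comparators are price-invariant, the qualifying set is a prefix of the
grid.

## Parameter fixture and calibration

The published parameter table for this model is not publicly
recoverable, so the fixture separates provenance per field
(`[PAPER-text]`, `[ASSUMED]`, `[ASSUMED-calibrated]`). Body-text
values are fixed: the relative risks, 38 therapist hours at £58→£87/h,
the £1050 CBT course, the multiplier of 2, PAP completer remission
0.57, SSRI response 0.48 (split 0.28 remission + 0.20
response-without-remission following the source trial's remission
rate), the price grid, thresholds, and the 6+20-week horizon. The
remaining fields — completion probabilities, the dropout outcome
split, relapse probabilities, utilities, outcome-phase costs, and the
escitalopram daily cost — were calibrated (bounded least squares with
plausibility priors, then an exact Newton/linear solve) so the model
reproduces the published base-case expected QALYs to 3 dp and expected
healthcare costs to within £1. The calibrated values are clinically
sensible: relapse 0.44 on the SSRI alone versus 0.28–0.29 with CBT or
psilocybin; utilities 0.89 (remission) / 0.63 (response) / 0.55
(relapse) / 0.53 (no response), baseline 0.315; full-period relapse
care £5652 versus £697 maintenance and £5337 continued care for
non-responders. Calibration is under-determined — these values are a
consistent reconstruction, not a transcription — which is why the
fixture tags them `ASSUMED-calibrated`.

## Sensitivity analysis

Scenarios are multiplicative edits to a dotted parameter path, crossed
with the full £100-step price grid (tables report the £200-step grid).
Probability edits follow the residual rule (mass moves to/from
no-response, the companion outcome held fixed) and are rounded
half-up to two decimals by default, mirroring how varied probabilities
are reported (0.57 + 50 % → 0.86); rounding can be disabled. The +50 %
variation on CBT/combination outcomes scales the relative risks, since
those arms have no free probabilities of their own. An edit whose
result fails validation is flagged `skipped_invalid`, never truncated.

## Synthetic parameter sets

The generator draws outcome distributions from symmetric Dirichlet
distributions (concentration 4 by default, i.e. moderately informative
and away from the simplex corners), completion in [0.5, 1], relapse in
[0, 0.8], ordered utilities in [0.1, 0.95], costs log-uniform in
[£50, £5000], and relative risks rejection-sampled so derived arms
always validate. It emulates the *structure* of the base case — every
generated set builds four evaluable trees — but not its clinical
correlations (e.g. no link between a therapy's remission gain and its
relapse rate), so property tests over the synthetic suite establish
mathematical correctness (conservation, oracle equivalence, NMB/ICER
consistency, monotonicity), not clinical realism.

## Numerical choices

- Distribution sums are checked to 1e-9; oracle equivalence
  (recursion versus path enumeration) is asserted at 1e-12 and is
  observed at ~1e-16.
- Exact summation uses `math.fsum` in the oracle; branch visiting
  order is fixed by sorted node ids.
- Degenerate inputs are well-defined: zero relapse or full completion
  zero out the corresponding subtree mass; a zero multiplier makes
  the perspectives coincide; a zero drug price leaves therapist cost
  only.
- Reports round money to £1 and QALYs to 3 dp; JSON outputs keep full
  precision.
- The property suites run on 40 generated sets in unit tests and 1000
  in the end-to-end suite; all runs are seeded and deterministic.

## Limitations

- A decision tree cannot represent the long-term, recurrent course of
  depression; a Markov or discrete-event model with longer follow-up
  would be needed for lifetime estimates.
- Only deterministic (one- and two-way) sensitivity analysis is
  implemented; there is no probabilistic sensitivity analysis and the
  parameter file deliberately carries point values, not distributions.
- The calibrated fixture reproduces the published aggregates but is
  not unique; conclusions that depend on individual calibrated fields
  (rather than the aggregates they were fitted to) should be checked
  against primary sources.
- Adverse-event costs, licensing/scheduling costs, and currency or
  inflation adjustments are out of scope.
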