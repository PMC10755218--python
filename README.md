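# psilocea

A decision-analytic cost-effectiveness model for psilocybin-assisted
psychotherapy (PAP) in severe depression, for health economists and
researchers appraising psychedelic therapies. The model compares PAP
with three comparators — an SSRI alone (escitalopram), CBT alone, and
combined SSRI + CBT — over a six-month horizon, and asks at what
psilocybin price, and at what level of therapist support, PAP is
cost-effective.

## The model

Each arm is a decision tree over a 6-week acute treatment phase and a
20-week follow-up. A patient completes treatment (probability
*p<sub>c</sub>*) or drops out; completers reach remission, response
without remission, or no response; dropouts receive no treatment effect
but may remit or improve spontaneously. Patients in remission or
sub-remission improvement may relapse during follow-up (probability
*p<sub>r</sub>*), on average halfway through the phase. Each of the
ten root-to-leaf paths carries a cost and a QALY payoff, and

- E[C] = Σ<sub>leaves</sub> p(path) · cost(path),
  E[Q] = Σ<sub>leaves</sub> p(path) · QALY(path),

computed by exact recursion (no simulation). QALYs weight time by
health-state utilities *u*: the acute phase at an in-episode baseline
utility, follow-up at the terminal state's utility, with relapsers
switching to *u<sub>relapse</sub>* at the follow-up midpoint. The CBT
and combination arms are derived from the SSRI arm by relative risks
(dropout/response/remission: 0.62/0.97/1.11 for CBT alone,
0.79/0.86/1.27 for the combination), with no-response as the residual.

Pairwise comparisons report the incremental cost-effectiveness ratio

- ICER = ΔC / ΔQ (GBP per QALY gained by choosing PAP),

or a dominance classification when one option is both cheaper and more
effective, judged against the NICE willingness-to-pay range of
£20 000–£30 000/QALY. Because a commercial psilocybin price does not
yet exist, the price is swept over £400–£2000 in £100 steps. The
healthcare perspective counts health-service costs; the societal
perspective adds lost-work costs at twice the outcome-phase healthcare
costs. Deterministic sensitivity analyses vary remission/response,
relapse, therapist-support cost, CBT cost, outcome-phase costs, and the
lost-work multiplier by ±25 % and ±50 %, each crossed with the full
price grid.

Intervention delivery: PAP costs the drug price (weight 0.95 per
patient entering the model) plus 38 therapist hours at £87/h (£58/h
Band 7 rate plus 30 min non-direct time per contact hour); escitalopram
accrues for completers; CBT is a £1050 ten-session course. The
base-case parameter fixture (`src/psilocea/data/paper_table1.yaml`)
tags each value's provenance; fields not recoverable from public
sources are calibrated against the published base-case results and
marked as such.

## Worked example

```
$ python examples/base_case.py

psilocybin price GBP 400:
arm        healthcare   societal   QALYs
pap              6255      11591   0.310
ssri             3700      11045   0.276
cbt              4405      11173   0.283
combo            4351      10971   0.287
```

PAP produces the most QALYs (0.310 against 0.276–0.287) but is the
most expensive arm from the healthcare perspective: £6255 at a £400
psilocybin price, rising to £7775 at £2000. At trial-level therapist
support every healthcare-perspective ICER exceeds £30 000/QALY, so PAP
is not cost-effective there; from the societal perspective the ICER
against the SSRI falls to about £16 000/QALY at a £400 price. Halving
the therapist-support cost makes PAP cost-effective at £30 000/QALY
from the healthcare perspective at low prices (up to £400 vs the SSRI,
£800 vs the combination) and strictly dominant — cheaper *and* more
effective — from the societal perspective up to prices of £1400 and
above (`examples/threshold_prices.py`).

The same analyses are available from the shell:

```
psilocea run --out results/base
psilocea sensitivity --scenario therapist_support_-50pct --out results/sens
psilocea validate --params my_params.yaml
psilocea generate --seed 1 --out synth.yaml
```

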