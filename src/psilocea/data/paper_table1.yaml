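# Base-case model parameters for the psilocybin cost-effectiveness model.
#
# Provenance tags per field:
#   [PAPER-text]          fixed in the source publication's body text
#   [ASSUMED-calibrated]  not publicly recoverable from the published
#                         parameter table; calibrated so the model
#                         reproduces the printed base-case expected
#                         QALYs (0.310 / 0.287 / 0.283 / 0.276) and
#                         expected healthcare costs (PAP 6255-7775,
#                         SSRI 3700, CBT 4405, SSRI+CBT 4351)
#   [ASSUMED]             plain modelling assumption (no printed value)

pap:
  p_complete: 0.94                 # [ASSUMED-calibrated] trial completion was high
  completer:
    p_remission: 0.57              # [PAPER-text] remission after psilocybin
    p_response: 0.13               # [ASSUMED] trial response 0.70 minus remitters
    p_no_response: 0.30            # residual
  dropout:
    p_spont_remission: 0.15        # [ASSUMED-calibrated] natural course
    p_improve_no_remission: 0.20   # [ASSUMED-calibrated]
    p_no_improvement: 0.65         # residual
  p_relapse: 0.2863                # [ASSUMED-calibrated] 6-month psilocybin follow-up
ssri:
  p_complete: 0.91                 # [ASSUMED-calibrated]
  completer:
    p_remission: 0.28              # [ASSUMED] trial remission on escitalopram
    p_response: 0.2                # [PAPER-text] 48% response minus remitters
    p_no_response: 0.52            # residual
  dropout:
    p_spont_remission: 0.15        # shared with PAP arm (no treatment effect)
    p_improve_no_remission: 0.2
    p_no_improvement: 0.65
  p_relapse: 0.4383                # [ASSUMED-calibrated] antidepressant alone
cbt:
  rr:
    rr_dropout: 0.62               # [PAPER-text] CBT alone vs medication alone
    rr_response: 0.97              # [PAPER-text]
    rr_remission: 1.11             # [PAPER-text]
  p_relapse: 0.2843                # [ASSUMED] same as combination (as stated)
combo:
  rr:
    rr_dropout: 0.79               # [PAPER-text] combination vs medication alone
    rr_response: 0.86              # [PAPER-text]
    rr_remission: 1.27             # [PAPER-text]
  p_relapse: 0.2843                # [ASSUMED-calibrated] antidepressant plus CBT
utilities:
  u_remission: 0.89                # [ASSUMED-calibrated]
  u_response: 0.63                 # [ASSUMED-calibrated]
  u_no_response: 0.53              # [ASSUMED-calibrated]
  u_relapse: 0.55                  # [ASSUMED-calibrated]
  u_baseline: 0.315                # [ASSUMED-calibrated] in-episode acute phase
costs:
  psilocybin_price: 400            # [PAPER-text] lower end of the price range
  therapist_hours: 38              # [PAPER-text]
  therapist_base_rate: 58          # [PAPER-text] Band 7 clinical psychologist /h
  nondirect_minutes_per_hour: 30   # [PAPER-text] -> unit cost 87/h
  ssri_daily_cost: 0.1659          # [ASSUMED-calibrated] escitalopram 10 mg/day
  ssri_days: 182                   # [ASSUMED] supply across the 26-week horizon
  cbt_course_cost: 1050            # [PAPER-text] 10-session course
  c_relapse_full: 5651.75          # [ASSUMED-calibrated] full-period relapse care
  c_maintenance_full: 697.3        # [ASSUMED-calibrated] care after remission/response
  c_no_response: 5336.73           # [ASSUMED-calibrated] continued care, non-responders
  drug_cost_weight: 0.95           # [ASSUMED-calibrated] implied by printed cost range
  dropout_intervention_fraction: 0.5  # [ASSUMED] dropouts consume part of a course
horizon:
  acute_weeks: 6                   # [PAPER-text]
  followup_weeks: 20               # [PAPER-text]
  relapse_midpoint_fraction: 0.5   # [PAPER-text] relapse halfway through follow-up
  weeks_per_year: 52
analysis:
  price_grid: [400, 500, 600, 700, 800, 900, 1000, 1100, 1200, 1300, 1400,
               1500, 1600, 1700, 1800, 1900, 2000]   # [PAPER-text]
  reporting_step: 200              # [PAPER-text] reporting increments
  wtp_thresholds: [20000, 30000]   # [PAPER-text] NICE bounds
  societal_multiplier: 2           # [PAPER-text] lost-work costs ~ 2x healthcare
  perspective: healthcare
  multiplier_mode: outcome         # reproduces the printed societal findings
  qaly_policy: baseline-acute      # reproduces the printed QALYs
provenance:
  source: base-case fixture (body-text values plus calibrated fields)
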