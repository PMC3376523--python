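# Primary-analysis configuration: itemized delivery costs, $45/h wage policy
# with 17% on-costs, $250 enrollment fee, 20-capacity classes, and the trial
# cohort's published distributional parameters.
wage_policy:
  base_rate: 45
  on_cost_multiplier: 1.17
  penalty_loading: 1.5

time_profile:
  contact_hours_f2f: 8
  extra_hours_web: 1.6
  participant_total_hours_f2f: 12
  participant_total_hours_web: 14.4

cost_structures:
  web:
    mode: web
    class_capacity: 20
    facilitator_hours: 14
    facilitator_rate: 60
    items:
      - {name: facilitator remuneration, amount: 840, recurrence: per-class-fixed}
      - {name: faculty ICT support fee, amount: 500, recurrence: per-class-fixed}
      - {name: administrative support, amount: 250, recurrence: per-class-fixed}
      - {name: stationery consumables, amount: 3, recurrence: per-participant-variable}
      - {name: delivery support DVD, amount: 5, recurrence: per-participant-variable}
  face_to_face:
    mode: face_to_face
    class_capacity: 20
    facilitator_hours: 9
    facilitator_rate: 90
    items:
      - {name: venue, amount: 1000, recurrence: per-class-fixed}
      - {name: presentation equipment rental, amount: 500, recurrence: per-class-fixed}
      - {name: facilitator remuneration, amount: 810, recurrence: per-class-fixed}
      - {name: faculty ICT support fee, amount: 500, recurrence: per-class-fixed}
      - {name: administrative support, amount: 250, recurrence: per-class-fixed}
      - {name: catering, amount: 25, recurrence: per-participant-variable}
      - {name: stationery consumables, amount: 5, recurrence: per-participant-variable}
      - {name: delivery support DVD, amount: 5, recurrence: per-participant-variable}

breakeven:
  enrollment_fee: 250
  max_enrollments: 60
  sweeps:
    web:
      - {axis: facilitator_hours, values: [8, 32, 40, 48]}
      - {axis: facilitator_rate, values: [35, 90, 120, 200]}
      - {axis: class_capacity, values: [10, 30, 40, 50, 60]}
      - {axis: enrollment_fee, values: [100, 200, 400, 600, 800, 1000]}
      - {axis: all_costs_scale, values: [2, 3, 4, 0.5]}
    face_to_face:
      - {axis: facilitator_hours, values: [12, 16]}
      - {axis: facilitator_rate, values: [35, 60, 120, 200]}
      - {axis: class_capacity, values: [10, 30, 40, 60]}
      - {axis: enrollment_fee, values: [100, 200, 400, 600, 800, 1000]}
      - {axis: all_costs_scale, values: [2, 3, 4, 0.5]}

cea:
  class_size: 20
  enrollment_fee: 250
  alternative_fee_factor: 2.1
  include_equal_attrition: true
  scenarios:
    - {label: "leisure time, fee paid by service", timing: leisure, fee_paid_by_service: true}
    - {label: "leisure time, fee paid by participant", timing: leisure, fee_paid_by_service: false}
    - {label: "working hours, fee paid by service", timing: working_hours, fee_paid_by_service: true, backfill: true}
    - {label: "working hours, fee paid by participant", timing: working_hours, fee_paid_by_service: false, backfill: true}
    - {label: "unpaid study leave, fee paid by service", timing: unpaid_leave, fee_paid_by_service: true}
    - {label: "unpaid study leave, fee paid by participant", timing: unpaid_leave, fee_paid_by_service: false}

cba:
  fee: 250
  benefit_context: 3
  scenarios:
    - {label: primary}
    - {label: "50% increase in fees", fee_scale: 1.5}
    - {label: "100% increase in fees", fee_scale: 2.0}
    - {label: "200% increase in fees", fee_scale: 3.0}
    - {label: "50% decrease in fees", fee_scale: 0.5}
    - {label: "25% increase in all associated costs", all_costs_scale: 1.25}
    - {label: "50% increase in all associated costs", all_costs_scale: 1.5}
    - {label: "25% decrease in all associated costs", all_costs_scale: 0.75}
    - {label: "50% decrease in all associated costs", all_costs_scale: 0.5}
    - {label: satellite-sourced internet, internet_variant: satellite}
    - {label: "leisure time (weekend)", timing: leisure}
    - {label: fee paid by health service, fee_paid_by_participant: false}

cohort:
  seed: 0
  arms:
    face_to_face:
      n_enrolled: 68
      completion_probability: 0.720588
      grade_mean: 81.6
      grade_sd: 9.5
      wtp_mean: {1: 129.17, 2: 192.26, 3: 199.0, 4: 314.14}
      wtp_sd: {1: 117.25, 2: 201.46, 3: 260.83, 4: 423.01}
      wtp_spearman: {1: 0.46, 2: 0.43, 3: 0.53, 4: 0.45}
      wtp_missing_rate: 0.42
    web:
      n_enrolled: 67
      completion_probability: 0.656716
      grade_mean: 83.2
      grade_sd: 9.9
      wtp_mean: {1: 96.33, 2: 165.57, 3: 159.72, 4: 190.94}
      wtp_sd: {1: 56.37, 2: 102.16, 3: 103.61, 4: 131.4}
      wtp_spearman: {1: 0.46, 2: 0.43, 3: 0.53, 4: 0.45}
      wtp_missing_rate: 0.24

output_dir: results
seed: 0
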