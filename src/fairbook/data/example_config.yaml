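# A complete run configuration for the fairbook CLI.
population:
  n_patients: 2000        # training population size for `simulate`
  fraction_group_b: 0.30
  history_length: 6
  seed: 1
grid:
  n_slots: 10
  slot_duration: 30       # minutes
  capacity: 2             # at most double-booking
weights:
  w_wait: 1.0
  w_idle: 1.0
  w_overtime: 1.0
objective:
  variant: TRADITIONAL    # TRADITIONAL | RACE_AWARE | RACE_UNAWARE
  # constraints:
  #   - {kind: GROUP_QUOTA, minima: {B: 0.2, nonB: 0.6}}
  #   - {kind: RISK_QUOTA, min_fraction: 0.2}
experiment:
  n_train: 2000
  n_patients: 12          # patients booked per clinic day
  n_days: 200
  methods: [SOTA, NO_ML, NO_SES, RACE_AWARE, RACE_UNAWARE]
  master_seed: 0
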