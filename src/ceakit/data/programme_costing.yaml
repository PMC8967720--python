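# Delivery costing for the 12-month group exercise programme.
# Quantities in minutes/hours/days are converted to hours at load time
# (7 working hours per day).  The capital equipment line is annuitized
# (equivalent annual cost) at 3.5% with payments in advance.
name: group exercise programme delivery
currency: GBP
price_year: 2018-19
hours_per_day: 7
n_sessions: 64
group_size: 15.2
components:
  - label: Link worker
    basis: per_participant
    quantity: 30
    unit: minutes
    unit_cost: 33.83
  - label: Coordinator
    basis: per_group
    quantity: 36
    unit: hours
    unit_cost: 33.83
  - label: Introductory sessions
    basis: per_participant
    quantity: 45
    unit: minutes
    unit_cost: 29.43
  - label: Pedometers
    basis: per_participant
    quantity: 1
    unit: items
    unit_cost: 9.95
  - label: Ankle weights and therabands
    basis: per_group
    quantity: 1
    unit: items
    annuity:
      capital: 136.27
      lifetime_years: 5
      discount_rate: 0.035
      timing: in_advance
  - label: Session preparation
    basis: per_session
    quantity: 30
    unit: minutes
    unit_cost: 29.43
  - label: Session travel
    basis: per_session
    quantity: 30
    unit: minutes
    unit_cost: 29.43
  - label: Session delivery
    basis: per_session
    quantity: 90
    unit: minutes
    unit_cost: 29.43
  - label: Refreshments
    # about one per attending participant per session; quantity is the
    # attendance-adjusted item count per group over the programme
    basis: per_group
    quantity: 621.32
    unit: items
    unit_cost: 1.00
  - label: Printed materials
    basis: per_participant
    quantity: 1
    unit: items
    unit_cost: 2.00
  - label: Venue hire
    basis: per_session
    quantity: 90
    unit: minutes
    unit_cost: 17.32
  - label: Trainer time
    # one leader trains four session leaders, each delivering four programmes
    basis: per_programme_share
    quantity: 10.5
    unit: hours
    unit_cost: 33.83
    share_divisor: 16
  - label: Session leader training time
    basis: per_programme_share
    quantity: 1.5
    unit: days
    unit_cost: 29.43
    share_divisor: 4
  - label: Training venue
    basis: per_programme_share
    quantity: 1.5
    unit: days
    unit_cost: 29.43
    share_divisor: 4
  - label: Training manual
    basis: per_programme_share
    quantity: 1
    unit: items
    unit_cost: 12.00
    share_divisor: 4
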