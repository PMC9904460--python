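# Base-case model inputs: first-line anlotinib vs sunitinib for metastatic
# renal cell carcinoma, Chinese societal perspective.  Transition
# probabilities are per one-month cycle; costs are USD per cycle
# (2022 exchange rate 6.3017 CNY/USD); ranges are the +/-20% one-way
# sensitivity bounds, also used to fit the PSA distributions.
name: anlotinib-vs-sunitinib-mrcc
currency: "USD, 2022 exchange rate 6.3017 CNY/USD"
reference: anlotinib
comparator: sunitinib
settings:
  cycle_length_months: 1
  horizon_cycles: 120
  annual_discount: 0.05
  wtp: 34340.50
utilities:
  stable: {value: 0.730, low: 0.584, high: 0.876}
  progressive: {value: 0.660, low: 0.528, high: 0.792}
  ae_disutility: {value: 0.157, low: 0.126, high: 0.188}
shared_costs:
  tests: {value: 248.96, low: 199.17, high: 298.75}
  outpatient: {value: 6.32, low: 5.06, high: 7.58}
  societal: {value: 54.58, low: 43.66, high: 65.50}
  progressive_state: {value: 4535.08, low: 3628.06, high: 5442.10}
strategies:
  anlotinib:
    transitions:
      stable_to_progressive: {value: 0.039, low: 0.031, high: 0.047}
      stable_to_dead: {value: 0.022, low: 0.018, high: 0.026}
      progressive_to_dead: {value: 0.050, low: 0.040, high: 0.061}
    drug_cost: {value: 864.76, low: 691.81, high: 1037.71}
    ae_cost: {value: 23.76, low: 19.01, high: 28.51}
    ae_rate: 0.289
  sunitinib:
    transitions:
      stable_to_progressive: {value: 0.041, low: 0.033, high: 0.049}
      stable_to_dead: {value: 0.022, low: 0.018, high: 0.026}
      progressive_to_dead: {value: 0.049, low: 0.039, high: 0.059}
    drug_cost: {value: 1830.48, low: 1464.38, high: 2196.58}
    ae_cost: {value: 265.44, low: 212.35, high: 318.53}
    ae_rate: 0.558
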