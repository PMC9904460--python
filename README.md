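# mrcc-cea

Decision-analytic cost-effectiveness model of **first-line anlotinib versus
sunitinib for metastatic renal cell carcinoma (mRCC)** from a Chinese
societal perspective, built as a tested, reusable Python package: a
three-state Markov cohort model with parameter derivation from trial
survival medians, discounted cost/QALY accrual, ICER and net-monetary-benefit
comparison, one-way (tornado) and probabilistic (CEAC) sensitivity analysis,
and a synthetic patient-level trial generator for end-to-end testing.

It is intended for health-economics analysts who want the full analysis —
not a spreadsheet or a point-and-click decision tree — as inspectable,
scriptable, reproducible code.

## The model

Patients start **stable** on first-line treatment, may move to
**progressive** disease (second-line care), and from either alive state to
the absorbing **dead** state. Each one-month cycle the cohort is advanced by

```
        stable   progressive   dead
stable  1-p_sp-p_sd   p_sp      p_sd
progr.      0        1-p_pd     p_pd
dead        0          0         1
```

Per-cycle transition probabilities come from the trial's median
times-to-event via the constant-hazard conversion

```
p(1 month) = 1 − 0.5^(1 / m),    m = median time to event (months)
```

applied to median PFS (progression from stable), median OS (death from
stable), and the post-progression interval OS − PFS (death after
progression). With the source trial's medians (anlotinib 17.5/30.9 months,
sunitinib 16.6/30.5) this yields per-cycle probabilities
(0.039, 0.022, 0.050) and (0.041, 0.022, 0.049).

Life-years, QALYs (stable utility 0.730, progressive 0.660, grade ≥3
adverse-event disutility 0.157 at trial incidence 28.9% vs 55.8%) and costs
(drug, tests, outpatient, societal, AE management while stable; a bundled
progressive-state cost plus societal costs after progression) are accrued
over a 10-year horizon and discounted at 5% per year. Strategies are
compared by the incremental cost-effectiveness ratio ΔC/ΔE and the net
monetary benefit NMB = WTP·ΔQALY − ΔC at a willingness-to-pay threshold of
$34,340.50/QALY (3× China's 2021 per-capita GDP), with strict-quadrant
dominance classification. Uncertainty is handled by ±20% one-way analysis
(discount rate 0–8%) and by 1000-draw Monte Carlo PSA with
method-of-moments beta (probabilities, utilities) and gamma (costs)
distributions, summarised as a cost-effectiveness acceptability curve.

## Worked example

The bundled configuration reproduces the base case:

```bash
$ mrcc-cea base-case --out results/base
 strategy  life_years  qalys  total_cost_usd
anlotinib      2.1981 1.4823      68966.4292
sunitinib      2.1960 1.4275      88394.0469
ICER (anlotinib vs sunitinib): -354,409.77 USD/QALY | NMB at WTP 34,340.50: 21,310.05 USD | verdict: reference_dominant
```

Anlotinib yields slightly more life-years (2.198 vs 2.196) and QALYs
(1.482 vs 1.427) at a cost about $19,400 lower, so it **dominates**
sunitinib: the negative ICER is reported but the verdict rests on the
dominance quadrant, not on comparing a negative ratio to the threshold.
Roughly 99.4% of both cohorts have died by the 10-year horizon.

```bash
$ mrcc-cea psa --out results/psa --n 1000 --seed 1
1000 draws; P(cost-effective at WTP 34,340.50) = 1.000
```

Every output directory contains full-precision CSVs (cohort traces, PSA
draws, CEAC, tornado rows), a JSON report, and a manifest with the
configuration digest and seed; reruns with the same config and seed are
byte-identical apart from the manifest timestamp. The same API is available
in Python:

```python
from mrcc_cea import load_config, full_base_case, run_psa, ceac

config = load_config()                  # or load_config("my_model.yaml")
report = full_base_case(config)
print(report.comparison.icer_per_qaly)  # -354409.77...
curve = ceac(run_psa(config, n=1000, seed=1))
```

Configurations are YAML/JSON; strategy blocks may give either per-cycle
transition probabilities or survival medians (`medians: {pfs: 17.5, os:
30.9}`), which are converted automatically. A synthetic two-arm trial with
the same constant-hazard structure can be generated with
`mrcc-cea simulate-trial --seed 1 --n-anlotinib 90 --n-sunitinib 43`.

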