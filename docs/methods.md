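# Methods

## Model structure and assumptions

The model is a discrete-time, three-state Markov cohort simulation
(stable → progressive → dead; stable → dead) with a one-month cycle and a
120-cycle (10-year) horizon, long enough that ~99.4% of both cohorts have
died at termination. All patients enter in the stable state on first-line
treatment and stop first-line treatment at progression. Transition
probabilities are constant over time (no tunnel states, no age-dependent
background mortality): the model inherits the exponential/constant-hazard
assumption embedded in the median-to-probability conversion
`p = 1 − 0.5^(c/m)`, which is `1 − exp(−R·c)` with hazard `R = ln 2 / m`.

Death from the stable state is derived directly from the OS median, even
though progression and death compete from that state; this slightly
double-counts death risk relative to a cause-specific decomposition, but
it is what reproduces the published per-cycle probabilities exactly
(0.039/0.022/0.050 and 0.041/0.022/0.049 at three decimals), and fidelity
to the published parameterisation wins over actuarial purity. The
probability of death after progression uses the post-progression interval
OS − PFS (13.4 and 13.9 months).

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| cycle length | 1 | month | |
| horizon | 120 | cycles | 10 years |
| annual discount | 0.05 | /year | applied to costs, LYs and QALYs; varied 0–0.08 in OWSA |
| WTP | 34,340.50 | USD/QALY | 3× 2021 per-capita GDP |
| utilities (stable/progressive) | 0.730 / 0.660 | /year | shared by both arms |
| AE disutility | 0.157 | /year | weighted by arm AE incidence (0.289 / 0.558) |
| costs | per Table in `data/base_case.yaml` | USD/cycle | 2022 exchange rate 6.3017 CNY/USD |

Sensitivity ranges default to ±20% of the base value (upper bounds of
probabilities/utilities clamped at 1); the bundled configuration carries
the published ranges explicitly. The discount rate is varied over 0–8%
annually rather than ±20%.

## Reward conventions and their calibration

Decision-tree packages differ silently on reward timing, so every
convention is an explicit switch on `ModelSettings`, and the defaults were
calibrated once against the published base-case aggregates:

- **State counting** (`begin` | `end` | `half`): membership credited at
  the **beginning** of each cycle by default; cycle *t*'s reward is
  discounted by `(1 + r_cycle)^(−t)`.
- **Discount compounding** (`compound` | `simple`): compound-equivalent
  monthly rate `1.05^(1/12) − 1` by default, preserving exactly 5%/year;
  the simple `0.05/12` alternative changes outputs by <0.2%.
- **AE disutility** (`per_cycle` | `one_time` | `duration_limited`):
  **per-cycle** by default — the stable-state utility is reduced by
  `ae_rate × disutility` for the whole on-treatment phase, i.e. AEs are
  treated as a standing quality-of-life decrement while on the drug. A
  one-time lump of `ae_rate × disutility` whole QALYs at entry and a
  duration-limited variant are available.
- **Cost attribution**: drug, tests, outpatient and AE-management costs
  accrue only while stable; the progressive-state cost subsumes subsequent
  treatment and monitoring; societal costs accrue in all alive states
  (both toggleable).

Under these defaults the model gives anlotinib 2.198 LY / 1.482 QALY /
$68,966 and sunitinib 2.196 / 1.427 / $88,394, versus the published 2.196 /
1.487 / $68,597.84 and 2.194 / 1.432 / $88,060.02 — every aggregate within
0.6% — and an ICER of −354,410 $/QALY versus the published −354,117.07
(0.08%). The begin-counting + per-cycle-AE combination is the only one in
the exposed convention space that reproduces the published *QALY
difference* (0.0548 vs the 0.0550 implied by the published ICER); the
one-time lump understates it by ~16%. Anlotinib remains strictly cheaper
and more effective under **every** convention combination, so the
cost-effectiveness conclusion does not depend on the calibration. The
per-LY ICER is not a meaningful reproduction target: it divides by a
life-year difference of ~0.002, whose fourth decimal is below the
resolution any convention choice can pin down.

## Comparison logic

Deltas are reference − comparator. ICERs are computed from full-precision
aggregates (the published ICER is likewise inconsistent with its own
rounded deltas, proving full precision was used) and are undefined when
the effect difference is zero. Dominance uses the strict quadrant rule;
negative ICERs in the dominant quadrant are reported numerically but never
compared to the WTP. In trade-off quadrants, cost-effectiveness is
ICER ≤ WTP when QALYs are gained and ICER ≥ WTP when QALYs are traded for
savings; NMB = WTP·ΔQALY − ΔC is emitted alongside and its sign always
agrees with the verdict.

## Sensitivity analysis

**One-way:** each parameter is pushed to its low/high bound with all else
at base and the full comparison is rerun. Rows carry both the ICER and the
NMB at each bound. The **default ranking metric is NMB**: with a dominant
base case the QALY difference passes through zero inside several
parameters' ranges, so ICER intervals explode (|ICER| > $7M for the
sunitinib progression probability) and their widths stop being comparable.
Bounds that would break a structural invariant against the other
parameters at base — the published utility ranges themselves cross
(stable low 0.584 < progressive base 0.660) — are clamped with a logged
warning. Under the NMB metric the two mortality-after-progression
probabilities are a statistical tie for the widest bar (spreads ≈11,700 vs
≈11,430, ~2% apart); the published tornado names the anlotinib one first,
a tie-break this reimplementation cannot recover, though it reproduces
that parameter's published ICER endpoints (−44,592.55 to 596,431.60)
within ~1.5%. Testing costs and the discount rate have very little ICER
leverage, as published.

**Probabilistic:** all varied parameters are sampled independently (no
correlation structure is published) from method-of-moments distributions —
beta for probabilities/utilities, gamma for costs — with
`sd = (high − low)/3.92`, i.e. the range is read as a 95% interval; the
fitted mean equals the base value by construction. Draws violating a
structural invariant (stable-exit probabilities summing past 1, or the
sampled progressive utility exceeding the sampled stable utility) are
rejected and resampled, preserving the marginal families; the rejection
count is reported. With 1000 seeded draws, anlotinib has positive NMB at
the $34,340.50 threshold in ~100% of draws, and the acceptability curve is
essentially flat at 1 over 0–3× WTP.

## Synthetic trial generator

`simulate_trial` emulates the two-arm source trial (default 90/43
patients): PFS ~ Exp with median `m_pfs`, OS = PFS + an independent
Exp post-progression time with median `m_os − m_pfs`, AE flags
Bernoulli(ae_rate) — exactly the constant-hazard structure the model
assumes, so the pipeline simulate → estimate → derive → compare closes on
the generating values. One estimator subtlety: the raw sample median of
the summed OS times targets the median of the *convolution* of the two
exponentials (≈37.3 months for the anlotinib parameters), not the
generating parameter 30.9; `estimate_summary` therefore estimates the OS
median component-wise as `median(PFS) + median(OS − PFS)`, which is
consistent for the quantity the median-to-probability derivation consumes.
An administrative-censoring hook (off by default) truncates follow-up and
switches estimation to Kaplan–Meier medians.

What the generator does **not** emulate: censoring patterns of a real
trial (accrual, dropout), non-exponential hazards (the real PFS/OS curves
surely deviate from constant hazard), covariates, or correlation between
AEs and survival. Tests passing on synthetic data therefore validate the
*pipeline's statistical machinery*, not the clinical realism of the
exponential assumption.

## Numerical choices

- The cohort trace is propagated by repeated vector–matrix products; rows
  are validated to sum to 1 within 1e-12 and death occupancy is monotone.
- Derived transition probabilities are used at full precision internally;
  rounding to 3 decimals happens only for reporting/validation. The
  bundled base case uses the published rounded values so that results
  correspond to the published parameterisation.
- Degenerate (zero-width) ranges yield point-mass distributions; PSA and
  OWSA treat such parameters as fixed.
- ICERs are `None` (CSV/JSON null) at zero effect difference; equal-cost,
  equal-QALY comparisons are classified `equivalent`.
- All randomness flows through `numpy.random.default_rng(seed)`; PSA
  draws, synthetic trials and CLI outputs are byte-reproducible for a
  fixed (config, seed) pair.

## Problem sizes used in validation

Unit and acceptance tests run the cohort model at its native size
(120 cycles), PSA at 1000 draws (10,000 for the mean-centering property),
the individual-level microsimulation cross-check at 100,000 patients, and
synthetic-trial parameter recovery at 100,000 patients per arm with 500
small-trial replicates — sizes at which Monte Carlo error is far below
every tolerance asserted.

## Known limitations

- Constant hazards and a fixed progressive-state cost ignore time-on-state
  effects (e.g. rising costs near death).
- No background (other-cause) mortality; acceptable over a 10-year horizon
  in metastatic disease, not for longer horizons.
- The OS-median-based death-from-stable probability double-counts some
  death risk jointly with the PFS-derived progression probability (see
  above); the model reproduces the published results, not a re-derivation
  from patient-level data.
- Only two-strategy comparisons; no efficiency frontier over >2 options,
  and no EVPI.
- Costs are fixed 2022 USD conversions of Chinese charges; no currency or
  inflation machinery.
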