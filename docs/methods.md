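# Methods

## Model structure

Five health states: asymptomatic hypertension (WELL), chronic
post-stroke (STROKE), chronic post-CHD (CHD), cardiovascular death
(DEAD_CVD), death from other causes (DEAD_OTHER). The cycle length is
one year; the cohort is closed, starts fully WELL at age 40 and runs 30
cycles by default.

The original description separates an "event" year from the chronic
state that follows; we collapse both into a single chronic state with
the case fatality applied at the incident transition and the one-time
hospitalization cost attached to the incident flow. This reproduces the
same accounting with the minimum state count, and the incident flows
are kept in the trace so tests can inspect them. Chronic states are
event-absorbing: no second events and no transitions between STROKE and
CHD.

Competing risks within a cycle compose sequentially on the complement:
first the event/fatality split, then background mortality over
everybody who did not die of the event. The WELL row is

    P(DEAD_CVD)   = p_s·f_s + p_c·f_c
    P(STROKE)     = p_s·(1 − f_s)·(1 − m)
    P(CHD)        = p_c·(1 − f_c)·(1 − m)
    P(DEAD_OTHER) = (1 − p_s·f_s − p_c·f_c)·m
    P(WELL)       = (1 − p_s − p_c)·(1 − m)

with p_e = table(age, event) · RR_event and f_e = case_fatality_e ·
RR_death. Rows sum to one by construction; the engine still verifies
conservation and raises if a composed incidence leaves [0, 1].

### Cycle accounting conventions

Two conventions are load-bearing for matching the published results and
are therefore the defaults, each switchable in the configuration:

* **RR_death acts on all mortality** (`rr_death_on_background`,
  default on): a drug's relative risk of death multiplies background
  life-table mortality as well as event case fatality. With the
  alternative (case fatality only), every drug's QALY gain over no
  treatment comes out at roughly half the published gap and the
  published EVPPI ranking (RR_death by far the most valuable parameter)
  is inexplicable. With the default, the published per-strategy NMBs
  are matched to a few tenths of a percent (see "Fidelity" below).
* **Half-cycle correction** (`half_cycle_correction`, default on):
  QALYs and state-occupancy costs accrue on the average of start- and
  end-of-cycle occupancy. Hospitalization attaches to the incident flow
  of the cycle in which the event occurs, at that cycle's discount
  factor.

Discounting uses (1+r)^−t with t = 0 for the first cycle
(`discount_first_cycle` switches to t = 1). The same drawn rate applies
to costs and QALYs.

### Fidelity to the published figures

With these defaults the deterministic point run of the high-risk
parameter set gives per-patient NMBs at $15,000/QALY of 89,676 /
101,664 / 94,102 / 98,530 / 101,922 (null / thiazide / beta blocker /
ACEI / CCB) — within 0.03–0.3% of the set of five NMBs the source
publication reports for its *medium*-risk scenario. Run on the
medium-risk table as printed, all five come out ≈20% higher. The
printed risk-table columns are internally consistent with their own
stratum definitions (the medium column's 10-year stroke risk at age 50
is ≈20%), so we conclude the published results paragraph drew on the
high-risk inputs, and we do not relabel anything: each stratum's
configuration carries its printed values exactly. Similarly, the
published low-risk probabilities of cost-effectiveness (ACEI 0.526,
thiazide 0.278) contradict the same publication's low-risk frontier narrative
(thiazide optimal from ≈$2,600 to $15,000/QALY, which this model
reproduces almost exactly) and are not reproducible under any
convention we examined; our low-risk probabilities at $15,000/QALY are
≈0.63 (thiazide) and ≈0.06 (ACEI).

## Parameters and distributions

All monetary values are 2010 USD. `inflate_cost` (compound interest)
and `ppp_convert` (PPP over market exchange rate) are provided for
re-deriving price inputs; the bundled set stores already-adjusted
values. `annualize_risk` converts an h-year risk to the constant-hazard
annual equivalent, 1 − (1 − p)^(1/h).

| Quantity | Distribution | Notes |
|---|---|---|
| annual event probabilities | gamma, mean = table value | CV unstated in the source; default 0.10, config-exposed; draws capped at 1 |
| relative risks | normal(mean, se), resampled until > 0 | log-normal alternative via `rr_sampling` |
| case fatality | beta(0.27, 0.73) stroke; beta(0.51, 0.49) CHD | the CHD cell is printed transposed; the mean is anchored to the stated 51% rate with α+β = 1 as printed. These shapes are extremely dispersed (U-shaped); a fatality product cf·RR_death > 1 is clamped to 1 |
| utilities | beta, shape parameters as published | dead states fixed at 0 |
| cost items | triangular(min, mode, max) | null strategy's drug cost fixed at 0 |
| discount rate | triangular(0, 0.03, 0.05) | one draw per PSA iteration, shared by costs and QALYs |

Age-band lookup (risk table and life table) is a left-closed step
function; band boundaries belong to the new band, and ages beyond the
last band carry the last band forward so horizons past the printed
bands stay defined.

Treated-arm event risks default to the High-BP column times the drug's
relative risks (`treated_risk_source = high_bp_times_rr`). The
Controlled-BP columns are loaded, validated and available through
`controlled_bp_column`, but a single shared controlled column cannot
represent per-drug effect differences, so it is not the default.

## Probabilistic sensitivity analysis

One seeded generator draws every parameter once per iteration in a
fixed, documented order (risk-table entries by event/column/band, case
fatalities, per-strategy RRs, per-strategy drug costs, event costs,
utilities, discount rate); all strategies in an iteration share the
same draw of every non-strategy-specific parameter, so per-iteration
rankings reflect parameter uncertainty only. 1000 iterations is the
study size and the default. Identical seeds give bit-identical results;
collapsing every distribution to its point (`degenerate_config`)
reproduces the deterministic base case exactly, which the tests assert.

## Decision statistics

NMB is monetary (λ·QALY − cost). The published formula is typeset as a
net *health* benefit, but the magnitudes it reports (~10⁵ USD at
λ = 15,000) are only dimensionally consistent with the monetary form,
which is therefore primary; `nhb` exposes the health scale.
Per-iteration argmax indicators (ties split equally — relevant only for
degenerate draws) averaged over iterations give the probability of
cost-effectiveness. The CEAC excludes the null comparator; the CEAF
includes it and reports, at each λ, the strategy with the highest
*expected* NMB together with that strategy's probability. The default
grid is 58 evenly spaced points on [0, 15,000] (the source states the
count but not the spacing), so frontier crossover values are
grid-quantized to ≈263-dollar steps. The ICER table sorts by expected
cost, flags strict dominance, removes extended dominance iteratively,
and refuses to divide by a zero QALY increment.

## Value of information

Per-patient EVPI(λ) = mean over iterations of the best per-iteration
NMB minus the best mean NMB, floored at zero. Population scaling
multiplies by the discounted effective population Σ_{t=0}^{29}
1000/1.03ᵗ = 20,188.45 as the last step. EVPPI uses the two-level
nested estimator: outer draws of the parameter group of interest, inner
draws of everything else conditional on them, per-patient EVPPI =
mean_outer[max_s mean_inner NMB] − max_s[overall mean NMB]. The
published recipe (100 outer × 10 inner) is the default; small inner
loops bias the estimate upward (a test demonstrates the bias on an
irrelevant parameter), and the Monte Carlo standard error from
outer-loop variability is reported alongside every estimate. Parameter
groups default to the published reporting rows (the frontier drug's
three RRs, the three utilities, the four cost items) and accept any
subset of the canonical parameter names.

## Synthetic data and oracles

`random_config` generates fully valid configurations (risk tables as
sorted uniform draws so age-monotonicity holds by construction, a
fixed-at-1 null strategy always present) for property tests.
`closed_form_case` builds annuity, constant-mortality and
constant-hazard models whose discounted QALY expectations are geometric
sums, matched by the engine to 1e−9. Two independent oracles share the
engine's transition semantics but not its code path: exhaustive path
enumeration (exact, horizons ≤ 6) and a vectorized patient-level
microsimulation whose 200,000-patient means agree with the cohort
engine within 3 Monte Carlo standard errors on every strategy and
stratum. These oracles validate the expectation the cohort engine
computes; none of them models features the cohort engine lacks
(adherence, treatment switching, elevated post-event background
mortality), so agreement says nothing about those real-world phenomena.

## Problem sizes and limitations

Defaults throughout are the study sizes: 1000 PSA iterations, 30
cycles, 58-point WTP grid, 100×10 nested EVPPI; the full acceptance
recomputation runs in a few seconds on one core. Known limitations:
no treatment switching or adherence; no second events; post-event
survivors face life-table (not elevated) background mortality; no
correlation between parameters; frontier crossovers are reported at
grid resolution; and the EVPI at a near-crossover λ is a noisy
max-statistic, so seed-to-seed variation of a few percent is expected
at 1000 iterations.
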