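# htncea

Cost-utility analysis of first-line antihypertensive drug classes for
Nigeria, built as a tested, reusable Python package.

Hypertension control in Nigeria is a pharmacoeconomic problem: four
first-line drug classes — thiazide diuretic (hydrochlorothiazide),
beta blocker (propranolol), ACE inhibitor (lisinopril) and calcium
channel blocker (nifedipine) — differ widely in price, and the payer
needs to know which one buys the most health per dollar compared with
leaving asymptomatic patients untreated until a cardiovascular event.
`htncea` implements the full decision-analytic pipeline for that
question: a Markov cohort model, probabilistic sensitivity analysis
(PSA), net-monetary-benefit ranking, cost-effectiveness acceptability
curves and frontiers, and expected value of (partial) perfect
information. It is aimed at health economists and modellers who want
the analysis reproducible, scriptable and property-tested rather than
locked in a spreadsheet.

## The model

A closed cohort of 1000 hypertensive patients starts asymptomatic at
age 40 and moves through five states over 30 annual cycles:

    WELL → {WELL, STROKE, CHD, DEAD_CVD, DEAD_OTHER}

Each cycle a WELL patient suffers an incident stroke or CHD event with
an age-banded annual probability taken from a recalibrated Framingham
risk table (three cardiovascular risk strata: low / medium / high); an
incident event is fatal with case fatality *f* (27% stroke, 51% CHD).
A drug modifies the event probabilities multiplicatively (RR_stroke,
RR_CHD) and all mortality through RR_death; survivors face Nigerian
life-table background mortality *m(a)*. Competing risks compose on the
complement, so every transition row is exactly stochastic.

Outcomes per patient are discounted quality-adjusted life years
(utilities: well 0.57, stroke 0.04, CHD 0.13, dead 0) and discounted
2010-USD costs (annual drug + physician cost while WELL, one-time
hospitalization at the event, annual management cost in the chronic
states), both at 3% with a half-cycle correction. Decision statistics
follow the standard net-monetary-benefit framework at
willingness-to-pay λ:

    NMB_s(λ) = λ · E[QALY_s] − E[Cost_s]

The PSA draws every uncertain parameter from its stated distribution
(normal RRs, beta utilities and case fatalities, triangular costs and
discount rate, gamma event probabilities) with one shared draw per
iteration across strategies; the acceptability frontier tracks the
argmax-NMB strategy over a 58-point λ grid, and per-patient EVPI

    EVPI(λ) = E[max_s NMB_s] − max_s E[NMB_s]

is scaled to the population by the discounted effective population
Σₜ 1000/1.03ᵗ ≈ 20 188. EVPPI per parameter group uses the two-level
nested Monte Carlo estimator (default 100 outer × 10 inner).

## Worked example

The deterministic base case for the high-risk stratum:

```sh
$ htncea base --stratum high --wtp 15000
    strategy  expected_cost  expected_qaly           nmb
        null    1921.598402       6.106475  89675.532422
    thiazide    2663.457871       6.955143 101663.684389
beta_blocker    2912.987667       6.467673  94102.112553
        acei    6513.855643       7.002899  98529.636655
         ccb    5135.397573       7.137169 101922.138954
```

Reading: an untreated high-risk patient accrues 6.11 discounted QALYs
and $1,922 of event costs; the thiazide adds 0.85 QALYs for $742 extra,
so at $15,000/QALY its net monetary benefit (~$101.7k) beats no
treatment (~$89.7k) by ~$12k per patient. The ACE inhibitor gains
similar health but costs ~$6.5k, so it ranks below the much cheaper
thiazide; the calcium channel blocker is the closest contender.

Under parameter uncertainty (1000 PSA iterations):

```python
>>> from htncea import reference_config, run_psa, prob_cost_effective
>>> psa = run_psa(reference_config("high"), 1000, seed=7)
>>> prob_cost_effective(psa, 15000)
{'null': 0.0, 'thiazide': 0.402, 'beta_blocker': 0.002, 'acei': 0.118, 'ccb': 0.478}
```

At $15,000/QALY the decision is a near coin-flip between the calcium
channel blocker (0.48) and the thiazide (0.40); the null scenario never
wins an iteration, and the beta blocker is never a contender. The
frontier (`htncea ceaf`), EVPI (`htncea evpi`) and per-parameter EVPPI
(`htncea evppi`) commands write the corresponding CSV tables, each with
a manifest that makes the run bit-reproducible. `htncea validate`
checks a YAML configuration and prints every violation;
`htncea export-fixture` dumps the bundled parameter set as CSV;
`htncea make-fixtures` generates random synthetic configurations.

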