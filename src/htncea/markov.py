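"""Closed-cohort Markov engine for the hypertension life-cycle model.

Five health states: asymptomatic hypertension (WELL), chronic post-stroke
(STROKE), chronic post-CHD (CHD), cardiovascular death (DEAD_CVD) and
death from other causes (DEAD_OTHER).  Each annual cycle a WELL patient
may suffer an incident stroke or CHD event — fatal with the case-fatality
probability (scaled by the drug's relative risk of death) — and everyone
alive faces life-table background mortality, which by default is also
scaled by the relative risk of death while on treatment.  Competing
risks are composed sequentially on the complement: events and their
fatality first, then background mortality over the non-CVD-death
survivors, which guarantees a proper stochastic matrix without
renormalization.

Chronic states are event-absorbing: no second events, and drug event
effects (and drug costs) stop mattering after an event.  Per cycle the
cohort accrues utility weights (dead states 0) and costs — annual drug
cost in WELL, a one-time hospitalization attached to the cycle of the
incident event, and annual management cost for every cycle of chronic
occupancy — discounted at (1+r)^-t with t = 0 for the first cycle by
default and, with the default half-cycle correction, on the average of
start- and end-of-cycle occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import ModelConfig

__all__ = [
    "STATES",
    "WELL",
    "STROKE",
    "CHD",
    "DEAD_CVD",
    "DEAD_OTHER",
    "ParameterDraw",
    "CohortTrace",
    "PerPatientOutcome",
    "build_transition_matrix",
    "run_cohort",
    "summarize",
    "run_strategy",
    "trace_frame",
]

STATES = ("well", "stroke", "chd", "dead_cvd", "dead_other")
WELL, STROKE, CHD, DEAD_CVD, DEAD_OTHER = range(5)


@dataclass
class ParameterDraw:
    """One coherent realization of every model parameter.

    ``rr`` maps strategy name to (rr_stroke, rr_chd, rr_death);
    ``drug_cost`` maps strategy name to its annual cost.  Event
    probabilities are resolved per (event, band) of the active risk
    column.  All shared quantities (risks, utilities, event costs, case
    fatalities, discount rate) are common across strategies so that a
    PSA iteration compares strategies under identical conditions.
    """

    rr: dict[str, tuple[float, float, float]]
    risk: dict[tuple[str, int], float]  # (event, band) -> annual probability
    cf_stroke: float
    cf_chd: float
    u_well: float
    u_stroke: float
    u_chd: float
    drug_cost: dict[str, float]
    cost_stroke_hosp: float
    cost_chd_hosp: float
    cost_management: float
    discount_rate: float
    values: Optional[dict[str, float]] = field(default=None, repr=False)

    def risk_at(self, age: float, event: str, bands: list[int]) -> float:
        chosen = bands[0]
        if age < chosen:
            raise ValueError(f"age {age} below first band {chosen}")
        for b in bands:
            if b <= age:
                chosen = b
        return self.risk[(event, chosen)]


@dataclass
class CohortTrace:
    """Per-cycle record of one cohort run.

    ``occupancy`` has ``horizon + 1`` rows (row 0 is the all-WELL start);
    ``incident`` holds the flows WELL -> STROKE/CHD (survivors entering
    the chronic state) during each cycle; ``cycle_qaly`` / ``cycle_cost``
    are the discounted per-patient accruals of each of the ``horizon``
    cycles.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    incident_stroke: np.ndarray
    incident_chd: np.ndarray
    cycle_qaly: np.ndarray
    cycle_cost: np.ndarray
    strategy: str
    discount_rate: float


@dataclass(frozen=True)
class PerPatientOutcome:
    qaly: float
    cost: float


def _fatality(cf: float, rr_death: float) -> float:
    """Composed fatality probability of an incident event, clamped at 1.

    The published case-fatality betas are highly dispersed, so a draw
    near 1 combined with a relative risk of death above 1 can push the
    product past 1; clamping keeps the matrix stochastic while leaving
    the distributional specification untouched.
    """
    return min(cf * rr_death, 1.0)


def _well_row(p_s: float, p_c: float, fs: float, fc: float, m: float):
    """Transition probabilities out of WELL for one cycle.

    Returns (to_well, to_stroke, to_chd, to_dead_cvd, to_dead_other).
    """
    for label, p in (
        ("stroke incidence", p_s),
        ("CHD incidence", p_c),
        ("combined incidence", p_s + p_c),
        ("stroke fatality", fs),
        ("CHD fatality", fc),
        ("background mortality", m),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"composed probability out of range: {label} = {p}")
    dead_cvd = p_s * fs + p_c * fc
    to_stroke = p_s * (1.0 - fs) * (1.0 - m)
    to_chd = p_c * (1.0 - fc) * (1.0 - m)
    dead_other = (1.0 - dead_cvd) * m
    to_well = (1.0 - p_s - p_c) * (1.0 - m)
    return to_well, to_stroke, to_chd, dead_cvd, dead_other


def build_transition_matrix(
    draw: ParameterDraw, strategy: str, age: float, config: ModelConfig
) -> np.ndarray:
    """One-cycle transition matrix at ``age`` for one strategy.

    Rows/columns follow :data:`STATES`.  Death rows are identity; the
    matrix is guaranteed row-stochastic by construction.
    """
    rr_s, rr_c, rr_d = draw.rr[strategy]
    bands = config.risk_table.bands
    if config.treated_risk_source == "controlled_bp_column" and strategy != "null":
        p_s = draw.risk_at(age, "stroke_controlled", bands)
        p_c = draw.risk_at(age, "chd_controlled", bands)
    else:
        p_s = draw.risk_at(age, "stroke", bands) * rr_s
        p_c = draw.risk_at(age, "chd", bands) * rr_c
    fs = _fatality(draw.cf_stroke, rr_d)
    fc = _fatality(draw.cf_chd, rr_d)
    m = config.life_table.rate(age)
    if config.rr_death_on_background:
        m = min(m * rr_d, 1.0)

    M = np.zeros((5, 5))
    M[WELL] = _well_row(p_s, p_c, fs, fc, m)
    M[STROKE, STROKE] = 1.0 - m
    M[STROKE, DEAD_OTHER] = m
    M[CHD, CHD] = 1.0 - m
    M[CHD, DEAD_OTHER] = m
    M[DEAD_CVD, DEAD_CVD] = 1.0
    M[DEAD_OTHER, DEAD_OTHER] = 1.0
    return M


def run_cohort(config: ModelConfig, strategy: str, draw: ParameterDraw) -> CohortTrace:
    """Advance the closed cohort through ``horizon_cycles`` annual cycles.

    The cohort starts fully WELL at ``starting_age``; age increments by
    one each cycle.  Accrual uses beginning-of-cycle occupancy (or the
    mid-cycle average when ``half_cycle_correction`` is on).
    """
    if strategy not in draw.rr:
        raise KeyError(f"strategy {strategy!r} not present in draw")
    T = config.horizon_cycles
    if T < 1:
        raise ValueError("horizon_cycles must be >= 1")
    r = draw.discount_rate
    bands = config.risk_table.bands
    controlled = config.treated_risk_source == "controlled_bp_column" and strategy != "null"
    rr_s, rr_c, rr_d = draw.rr[strategy]
    fs = _fatality(draw.cf_stroke, rr_d)
    fc = _fatality(draw.cf_chd, rr_d)
    drug = draw.drug_cost[strategy]
    mng = draw.cost_management
    hosp_s = draw.cost_stroke_hosp
    hosp_c = draw.cost_chd_hosp
    u = (draw.u_well, draw.u_stroke, draw.u_chd)

    ages = np.arange(config.starting_age, config.starting_age + T + 1, dtype=float)
    occ = np.zeros((T + 1, 5))
    occ[0, WELL] = 1.0
    inc_s = np.zeros(T)
    inc_c = np.zeros(T)
    qaly = np.zeros(T)
    cost = np.zeros(T)
    t_offset = 1 if config.discount_first_cycle else 0

    w, s, c, dv, do = 1.0, 0.0, 0.0, 0.0, 0.0
    for t in range(T):
        age = ages[t]
        if controlled:
            p_s = draw.risk_at(age, "stroke_controlled", bands)
            p_c = draw.risk_at(age, "chd_controlled", bands)
        else:
            p_s = draw.risk_at(age, "stroke", bands) * rr_s
            p_c = draw.risk_at(age, "chd", bands) * rr_c
        m = config.life_table.rate(age)
        if config.rr_death_on_background:
            m = min(m * rr_d, 1.0)
        to_w, to_s, to_c, to_dv, to_do = _well_row(p_s, p_c, fs, fc, m)

        nw = w * to_w
        ns = s * (1.0 - m) + w * to_s
        nc = c * (1.0 - m) + w * to_c
        ndv = dv + w * to_dv
        ndo = do + (s + c) * m + w * to_do
        inc_s[t] = w * to_s
        inc_c[t] = w * to_c

        disc = (1.0 + r) ** -(t + t_offset)
        if config.half_cycle_correction:
            occ_w, occ_s, occ_c = 0.5 * (w + nw), 0.5 * (s + ns), 0.5 * (c + nc)
        else:
            occ_w, occ_s, occ_c = w, s, c
        qaly[t] = disc * (occ_w * u[0] + occ_s * u[1] + occ_c * u[2])
        cost[t] = disc * (
            occ_w * drug + (occ_s + occ_c) * mng + inc_s[t] * hosp_s + inc_c[t] * hosp_c
        )

        w, s, c, dv, do = nw, ns, nc, ndv, ndo
        occ[t + 1] = (w, s, c, dv, do)

    return CohortTrace(
        ages=ages,
        occupancy=occ,
        incident_stroke=inc_s,
        incident_chd=inc_c,
        cycle_qaly=qaly,
        cycle_cost=cost,
        strategy=strategy,
        discount_rate=r,
    )


def summarize(trace: CohortTrace) -> PerPatientOutcome:
    """Total discounted per-patient QALYs and costs of a trace."""
    return PerPatientOutcome(qaly=float(trace.cycle_qaly.sum()), cost=float(trace.cycle_cost.sum()))


def run_strategy(config: ModelConfig, strategy: str, draw: ParameterDraw) -> PerPatientOutcome:
    """Convenience: run one cohort and summarize it."""
    return summarize(run_cohort(config, strategy, draw))


def trace_frame(trace: CohortTrace):
    """Trace as a tidy DataFrame, one row per cycle."""
    import pandas as pd

    T = len(trace.cycle_qaly)
    df = pd.DataFrame(
        {
            "cycle": np.arange(T),
            "age": trace.ages[:T],
            **{f"occ_{name}": trace.occupancy[:T, i] for i, name in enumerate(STATES)},
            "incident_stroke": trace.incident_stroke,
            "incident_chd": trace.incident_chd,
            "discounted_cost": trace.cycle_cost,
            "discounted_qaly": trace.cycle_qaly,
        }
    )
    return df
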