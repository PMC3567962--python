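"""Synthetic configurations and independent oracles for the cohort engine.

Three kinds of test instruments live here:

* :func:`random_config` — randomly generated but fully valid model
  configurations (monotone risk tables, a null strategy, legal
  distribution specs) for property testing of every pipeline stage.
* :func:`closed_form_case` — tiny configurations whose expected
  discounted QALYs are known analytically (annuity, mortality-only,
  single-event), for exact engine checks.
* :func:`microsim_oracle` and :func:`enumerate_paths_outcome` —
  patient-level microsimulation and exhaustive path enumeration that
  share the engine's transition semantics but none of its code path,
  so cohort expectations can be validated statistically (CLT bands)
  and exactly (small horizons).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .markov import (
    CHD,
    DEAD_CVD,
    DEAD_OTHER,
    STROKE,
    WELL,
    ParameterDraw,
    PerPatientOutcome,
    build_transition_matrix,
)
from .parameters import (
    AgeBandRiskTable,
    BetaSpec,
    CaseFatalitySet,
    CostSet,
    DiscountSpec,
    DrugEffect,
    GammaSpec,
    LifeTable,
    ModelConfig,
    NormalSpec,
    TriangularSpec,
    UtilitySet,
)

__all__ = [
    "SyntheticSpec",
    "random_config",
    "closed_form_case",
    "microsim_oracle",
    "enumerate_paths_outcome",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges controlling random configuration generation."""

    seed: int = 0
    risk_scale: tuple[float, float] = (0.001, 0.08)
    rr_range: tuple[float, float] = (0.4, 1.2)
    cost_range: tuple[float, float] = (10.0, 1000.0)
    utility_range: tuple[float, float] = (0.05, 0.95)
    horizon: int = 30
    n_strategies: int = 3  # treated strategies, in addition to the null

    def __post_init__(self):
        if not 0.0 <= self.risk_scale[0] <= self.risk_scale[1] <= 1.0:
            raise ValueError("risk_scale must be an ordered sub-range of [0, 1]")
        if self.rr_range[0] <= 0:
            raise ValueError("rr_range must be positive")
        if not 0.0 < self.utility_range[0] <= self.utility_range[1] < 1.0:
            raise ValueError("utility_range must lie inside (0, 1)")
        if self.horizon < 1 or self.n_strategies < 1:
            raise ValueError("horizon and n_strategies must be >= 1")


def _monotone_series(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    return np.sort(rng.uniform(lo, hi, size=n))


def _tri_around(rng: np.random.Generator, lo: float, hi: float) -> TriangularSpec:
    mode = rng.uniform(lo, hi)
    spread = rng.uniform(0.0, 0.3) * mode
    return TriangularSpec(minimum=max(mode - spread, 0.0), mode=mode, maximum=mode + spread)


def _beta_from_mean(rng: np.random.Generator, mean: float) -> BetaSpec:
    kappa = rng.uniform(2.0, 400.0)
    return BetaSpec(alpha=mean * kappa, beta=(1.0 - mean) * kappa)


def random_config(spec: SyntheticSpec) -> ModelConfig:
    """A random, fully valid configuration.

    Risk tables are sorted uniform draws so the age-monotonicity
    invariant holds by construction; a fixed-at-1 null strategy is
    always included.
    """
    rng = np.random.default_rng(spec.seed)
    starting_age = int(rng.integers(30, 60))
    bands = [starting_age + 5 * i for i in range(7)]

    entries = []
    for event in ("chd", "stroke"):
        for bp in ("high_bp", "controlled_bp"):
            probs = _monotone_series(rng, len(bands), *spec.risk_scale)
            for band, p in zip(bands, probs):
                entries.append(
                    {
                        "age": band,
                        "event": event,
                        "bp": bp,
                        "probability": GammaSpec(mean=float(p), cv=float(rng.uniform(0, 0.2))),
                    }
                )
    life_bands = bands + [bands[-1] + 5 * (i + 1) for i in range(4)]
    life_rates = _monotone_series(rng, len(life_bands), 0.005, 0.35)

    strategies = [
        DrugEffect(
            name="null",
            rr_stroke=NormalSpec(mean=1.0, se=0.0),
            rr_chd=NormalSpec(mean=1.0, se=0.0),
            rr_death=NormalSpec(mean=1.0, se=0.0),
        )
    ]
    for k in range(spec.n_strategies):
        strategies.append(
            DrugEffect(
                name=f"drug_{k}",
                rr_stroke=NormalSpec(
                    mean=float(rng.uniform(*spec.rr_range)), se=float(rng.uniform(0, 0.1))
                ),
                rr_chd=NormalSpec(
                    mean=float(rng.uniform(*spec.rr_range)), se=float(rng.uniform(0, 0.1))
                ),
                rr_death=NormalSpec(
                    mean=float(rng.uniform(*spec.rr_range)), se=float(rng.uniform(0, 0.1))
                ),
            )
        )

    drug_cost = {"null": TriangularSpec(minimum=0.0, mode=0.0, maximum=0.0)}
    for s in strategies[1:]:
        drug_cost[s.name] = _tri_around(rng, *spec.cost_range)

    return ModelConfig(
        stratum=str(rng.choice(["low", "medium", "high"])),
        starting_age=starting_age,
        horizon_cycles=spec.horizon,
        cohort_size=int(rng.integers(1, 5000)),
        risk_table=AgeBandRiskTable(entries=entries),
        life_table=LifeTable(
            entries=[{"age": a, "rate": float(r)} for a, r in zip(life_bands, life_rates)]
        ),
        strategies=strategies,
        costs=CostSet(
            annual_drug_cost=drug_cost,
            stroke_hospitalization=_tri_around(rng, *spec.cost_range),
            chd_hospitalization=_tri_around(rng, *spec.cost_range),
            chronic_management=_tri_around(rng, *spec.cost_range),
        ),
        utilities=UtilitySet(
            well=_beta_from_mean(rng, float(rng.uniform(*spec.utility_range))),
            stroke=_beta_from_mean(rng, float(rng.uniform(*spec.utility_range))),
            chd=_beta_from_mean(rng, float(rng.uniform(*spec.utility_range))),
        ),
        case_fatality=CaseFatalitySet(
            stroke=_beta_from_mean(rng, float(rng.uniform(0.1, 0.9))),
            chd=_beta_from_mean(rng, float(rng.uniform(0.1, 0.9))),
        ),
        discount=DiscountSpec(
            rate=0.03, sampling=TriangularSpec(minimum=0.0, mode=0.03, maximum=0.05)
        ),
    )


# --------------------------------------------------------------------------
# closed-form cases


def _flat_config(
    *,
    event_p: float,
    mortality: float,
    u_well: float,
    u_chronic: float,
    case_fatality: float,
    discount_rate: float,
    horizon: int,
) -> ModelConfig:
    """Single-band, constant-hazard configuration used by the closed forms."""
    entries = []
    for event in ("chd", "stroke"):
        for bp in ("high_bp", "controlled_bp"):
            p = event_p if event == "stroke" else 0.0
            entries.append(
                {"age": 40, "event": event, "bp": bp, "probability": GammaSpec(mean=p, cv=0.0)}
            )
    cf = max(min(case_fatality, 1.0), 0.0)
    sampling = TriangularSpec(minimum=discount_rate, mode=discount_rate, maximum=discount_rate)
    return ModelConfig(
        stratum="low",
        starting_age=40,
        horizon_cycles=horizon,
        cohort_size=1000,
        risk_table=AgeBandRiskTable(entries=entries),
        life_table=LifeTable(entries=[{"age": 40, "rate": mortality}]),
        strategies=[
            DrugEffect(
                name="null",
                rr_stroke=NormalSpec(mean=1.0, se=0.0),
                rr_chd=NormalSpec(mean=1.0, se=0.0),
                rr_death=NormalSpec(mean=1.0, se=0.0),
            )
        ],
        costs=CostSet(
            annual_drug_cost={"null": TriangularSpec(minimum=0.0, mode=0.0, maximum=0.0)},
            stroke_hospitalization=TriangularSpec(minimum=0.0, mode=0.0, maximum=0.0),
            chd_hospitalization=TriangularSpec(minimum=0.0, mode=0.0, maximum=0.0),
            chronic_management=TriangularSpec(minimum=0.0, mode=0.0, maximum=0.0),
        ),
        utilities=UtilitySet(
            well=BetaSpec(alpha=1.0, beta=1.0, fixed=u_well),
            stroke=BetaSpec(alpha=1.0, beta=1.0, fixed=u_chronic),
            chd=BetaSpec(alpha=1.0, beta=1.0, fixed=u_chronic),
        ),
        case_fatality=CaseFatalitySet(
            stroke=BetaSpec(alpha=1.0, beta=1.0, fixed=cf),
            chd=BetaSpec(alpha=1.0, beta=1.0, fixed=cf),
        ),
        discount=DiscountSpec(rate=discount_rate, sampling=sampling),
        half_cycle_correction=False,
    )


def closed_form_case(
    kind: str,
    *,
    horizon: int = 30,
    discount_rate: float = 0.0,
    mortality: float = 0.02,
    hazard: float = 0.05,
    u_well: float = 1.0,
    u_chronic: float = 0.5,
) -> tuple[ModelConfig, PerPatientOutcome]:
    """A configuration plus its analytically expected per-patient outcome.

    ``annuity``: no events, no mortality — the cohort stays WELL and
    the QALY total is the discounted annuity of ``u_well``.
    ``mortality_only``: constant background mortality ``m`` — WELL
    occupancy decays geometrically, QALY = sum u (1-m)^t v^t.
    ``single_event``: constant stroke hazard ``h``, zero case fatality
    and mortality — QALY mixes the geometric WELL occupancy with its
    chronic complement at ``u_chronic``.
    """
    v = 1.0 / (1.0 + discount_rate)
    t = np.arange(horizon)
    if kind == "annuity":
        config = _flat_config(
            event_p=0.0, mortality=0.0, u_well=u_well, u_chronic=u_chronic,
            case_fatality=0.0, discount_rate=discount_rate, horizon=horizon,
        )
        qaly = float(np.sum(u_well * v**t))
    elif kind == "mortality_only":
        config = _flat_config(
            event_p=0.0, mortality=mortality, u_well=u_well, u_chronic=u_chronic,
            case_fatality=0.0, discount_rate=discount_rate, horizon=horizon,
        )
        qaly = float(np.sum(u_well * (1.0 - mortality) ** t * v**t))
    elif kind == "single_event":
        config = _flat_config(
            event_p=hazard, mortality=0.0, u_well=u_well, u_chronic=u_chronic,
            case_fatality=0.0, discount_rate=discount_rate, horizon=horizon,
        )
        well_occ = (1.0 - hazard) ** t
        qaly = float(np.sum((well_occ * u_well + (1.0 - well_occ) * u_chronic) * v**t))
    else:
        raise ValueError(f"unknown closed-form kind {kind!r}")
    return config, PerPatientOutcome(qaly=qaly, cost=0.0)


# --------------------------------------------------------------------------
# independent oracles


def microsim_oracle(
    config: ModelConfig,
    strategy: str,
    draw: ParameterDraw,
    n_patients: int,
    seed: int | None = None,
    return_se: bool = False,
) -> PerPatientOutcome | tuple[PerPatientOutcome, PerPatientOutcome]:
    """Patient-level microsimulation mean outcome (vectorized).

    Simulates ``n_patients`` independent annual trajectories under the
    same transition, accrual and discount rules as the cohort engine;
    by the law of large numbers the mean converges to the cohort
    expectation.  With ``return_se`` the Monte Carlo standard errors of
    the two means are returned as a second outcome.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    T = config.horizon_cycles
    r = draw.discount_rate
    t_offset = 1 if config.discount_first_cycle else 0
    u = np.array([draw.u_well, draw.u_stroke, draw.u_chd, 0.0, 0.0])
    drug = draw.drug_cost[strategy]
    mng = draw.cost_management

    state_cost = np.array([drug, mng, mng, 0.0, 0.0])
    state = np.zeros(n_patients, dtype=np.int8)
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    for t in range(T):
        age = config.starting_age + t
        M = build_transition_matrix(draw, strategy, age, config)
        disc = (1.0 + r) ** -(t + t_offset)

        udraw = rng.random(n_patients)
        new_state = state.copy()
        for s in (WELL, STROKE, CHD):
            mask = state == s
            if not mask.any():
                continue
            cum = np.cumsum(M[s])
            new_state[mask] = np.searchsorted(cum, udraw[mask], side="right")

        if config.half_cycle_correction:
            occ_qaly = 0.5 * (u[state] + u[new_state])
            occ_cost = 0.5 * (state_cost[state] + state_cost[new_state])
        else:
            occ_qaly = u[state]
            occ_cost = state_cost[state].copy()
        incident_stroke = (state == WELL) & (new_state == STROKE)
        incident_chd = (state == WELL) & (new_state == CHD)
        occ_cost = occ_cost + np.where(incident_stroke, draw.cost_stroke_hosp, 0.0)
        occ_cost += np.where(incident_chd, draw.cost_chd_hosp, 0.0)
        qaly += disc * occ_qaly
        cost += disc * occ_cost
        state = new_state

    mean = PerPatientOutcome(qaly=float(qaly.mean()), cost=float(cost.mean()))
    if not return_se:
        return mean
    root_n = np.sqrt(n_patients)
    se = PerPatientOutcome(
        qaly=float(qaly.std(ddof=1) / root_n), cost=float(cost.std(ddof=1) / root_n)
    )
    return mean, se


def enumerate_paths_outcome(
    config: ModelConfig, strategy: str, draw: ParameterDraw
) -> PerPatientOutcome:
    """Exact expectation by exhaustive enumeration of all state paths.

    Feasible only for small horizons (5**T paths); shares no code with
    the cohort recursion beyond the one-cycle matrices.
    """
    T = config.horizon_cycles
    if T > 6:
        raise ValueError("path enumeration is intended for horizons <= 6")
    r = draw.discount_rate
    t_offset = 1 if config.discount_first_cycle else 0
    u = [draw.u_well, draw.u_stroke, draw.u_chd, 0.0, 0.0]
    state_cost = [
        draw.drug_cost[strategy],
        draw.cost_management,
        draw.cost_management,
        0.0,
        0.0,
    ]
    matrices = [
        build_transition_matrix(draw, strategy, config.starting_age + t, config)
        for t in range(T)
    ]
    total_qaly = 0.0
    total_cost = 0.0
    for path in product(range(5), repeat=T):
        full = (WELL,) + path
        prob = 1.0
        for t in range(T):
            prob *= matrices[t][full[t], full[t + 1]]
        if prob == 0.0:
            continue
        q = 0.0
        c = 0.0
        for t in range(T):
            disc = (1.0 + r) ** -(t + t_offset)
            if config.half_cycle_correction:
                q += disc * 0.5 * (u[full[t]] + u[full[t + 1]])
                c += disc * 0.5 * (state_cost[full[t]] + state_cost[full[t + 1]])
            else:
                q += disc * u[full[t]]
                c += disc * state_cost[full[t]]
            if full[t] == WELL and full[t + 1] in (STROKE, CHD):
                c += disc * (
                    draw.cost_stroke_hosp if full[t + 1] == STROKE else draw.cost_chd_hosp
                )
        total_qaly += prob * q
        total_cost += prob * c
    return PerPatientOutcome(qaly=total_qaly, cost=total_cost)
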