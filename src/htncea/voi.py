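"""Value-of-information analysis: population EVPI and nested-MC EVPPI.

Per-patient EVPI at willingness-to-pay ``lambda`` is the expected gain
from resolving all parameter uncertainty before choosing a strategy:
``mean_i max_s NMB(s, i) - max_s mean_i NMB(s, i)`` over PSA
iterations.  Partial EVPI (EVPPI) for a named parameter group uses a
two-level nested Monte Carlo estimator: the outer loop fixes a draw of
the group, the inner loop integrates the remaining parameters
conditional on it.  Small inner loops bias the estimate upward; the
iteration counts are configurable and reported alongside a Monte Carlo
standard error from outer-loop variability.

Population values scale per-patient quantities by the discounted
effective population — the sum of annual incident cohorts over the
decision horizon, each discounted to the present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import nmb_matrix
from .markov import run_strategy
from .parameters import ModelConfig
from .psa import PSAResults, parameter_names, sample_values, values_to_draw

__all__ = [
    "EffectivePopulationSpec",
    "VOIResult",
    "effective_population",
    "evpi",
    "population_evpi",
    "evppi",
    "standard_parameter_groups",
]


@dataclass(frozen=True)
class EffectivePopulationSpec:
    """Annual cohort size, decision horizon and discount rate."""

    annual_cohort: int = 1000
    horizon: int = 30
    discount_rate: float = 0.03

    def __post_init__(self):
        if self.annual_cohort < 1 or self.horizon < 1:
            raise ValueError("annual_cohort and horizon must be >= 1")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount_rate must lie in [0, 1]")


@dataclass
class VOIResult:
    """EVPI / EVPPI summary at one willingness-to-pay value."""

    wtp: float
    per_patient: float
    effective_population: float
    population: float
    parameter_group: str | None = None
    outer: int | None = None
    inner: int | None = None
    mc_se: float | None = None
    details: dict = field(default_factory=dict, repr=False)


def effective_population(spec: EffectivePopulationSpec) -> float:
    """Discounted sum of annual cohorts: sum_t N / (1+r)^t, t = 0..T-1."""
    t = np.arange(spec.horizon)
    return float(np.sum(spec.annual_cohort / (1.0 + spec.discount_rate) ** t))


def evpi(psa: PSAResults, wtp: float) -> float:
    """Per-patient expected value of perfect information (USD, >= 0)."""
    m = nmb_matrix(psa, wtp)
    value = float(m.max(axis=0).mean() - m.mean(axis=1).max())
    return max(value, 0.0)


def population_evpi(
    psa: PSAResults, wtp: float, spec: EffectivePopulationSpec = EffectivePopulationSpec()
) -> VOIResult:
    pp = evpi(psa, wtp)
    pop = effective_population(spec)
    return VOIResult(wtp=wtp, per_patient=pp, effective_population=pop, population=pp * pop)


def standard_parameter_groups(config: ModelConfig, drug: str = "thiazide") -> dict[str, list[str]]:
    """Named parameter groups for EVPPI reporting.

    Mirrors the study's reporting rows: each relative-risk component of
    the frontier drug, each health-state utility, and each cost item
    relevant to that drug.  Groups are plain name lists and can be
    extended with any entry of :func:`parameter_names`.
    """
    return {
        f"rr_{drug}_stroke": [f"rr:{drug}:stroke"],
        f"rr_{drug}_chd": [f"rr:{drug}:chd"],
        f"rr_{drug}_death": [f"rr:{drug}:death"],
        "utility_well": ["utility:well"],
        "utility_stroke": ["utility:stroke"],
        "utility_chd": ["utility:chd"],
        "cost_stroke_hospitalization": ["cost:stroke_hospitalization"],
        "cost_chd_hospitalization": ["cost:chd_hospitalization"],
        "cost_management": ["cost:management"],
        f"cost_drug_{drug}": [f"drug_cost:{drug}"],
    }


def evppi(
    config: ModelConfig,
    parameter_group: list[str],
    wtp: float,
    outer: int = 100,
    inner: int = 10,
    seed: int | None = None,
    spec: EffectivePopulationSpec = EffectivePopulationSpec(),
    group_name: str | None = None,
) -> VOIResult:
    """Two-level nested Monte Carlo partial EVPI for one parameter group.

    The outer loop draws the group of interest; for each outer draw the
    inner loop redraws every remaining parameter and evaluates the
    per-strategy NMB through the cohort engine.  Per-patient EVPPI is
    ``mean_outer max_s mean_inner NMB - max_s overall-mean NMB``,
    floored at zero, and is scaled by the effective population.
    """
    if not parameter_group:
        raise ValueError("parameter_group must be non-empty")
    if outer < 1 or inner < 1:
        raise ValueError("outer and inner iteration counts must be >= 1")
    valid = set(parameter_names(config))
    unknown = [p for p in parameter_group if p not in valid]
    if unknown:
        raise KeyError(
            f"unknown parameter name(s) {unknown}; valid names: {sorted(valid)}"
        )

    rng = np.random.default_rng(seed)
    names = config.strategy_names
    S = len(names)
    inner_means = np.zeros((outer, S))
    all_nmb = np.zeros((outer, inner, S))
    for o in range(outer):
        outer_values = sample_values(config, rng)
        fixed = {p: outer_values[p] for p in parameter_group}
        for i in range(inner):
            values = sample_values(config, rng)
            values.update(fixed)
            draw = values_to_draw(config, values)
            for s, name in enumerate(names):
                out = run_strategy(config, name, draw)
                all_nmb[o, i, s] = wtp * out.qaly - out.cost
        inner_means[o] = all_nmb[o].mean(axis=0)

    perfect = inner_means.max(axis=1)  # best attainable given the group, per outer draw
    current = all_nmb.reshape(-1, S).mean(axis=0).max()
    per_patient = max(float(perfect.mean() - current), 0.0)
    mc_se = float(perfect.std(ddof=1) / np.sqrt(outer)) if outer > 1 else float("nan")
    pop = effective_population(spec)
    return VOIResult(
        wtp=wtp,
        per_patient=per_patient,
        effective_population=pop,
        population=per_patient * pop,
        parameter_group=group_name or "+".join(parameter_group),
        outer=outer,
        inner=inner,
        mc_se=mc_se,
        details={"perfect_per_outer": perfect, "current": current},
    )
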