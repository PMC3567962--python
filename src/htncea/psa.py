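"""Probabilistic sensitivity analysis: parameter sampling and Monte Carlo runs.

Every uncertain quantity is drawn once per iteration from its stated
distribution and the same draw of all shared parameters is used for
every strategy (common random numbers), so per-iteration strategy
comparisons reflect parameter uncertainty, not sampling noise between
arms.

Draw order is fixed and documented (see :func:`parameter_names`): risk
table entries sorted by (event, blood-pressure status, age band), then
case fatalities, per-strategy relative risks in configuration order,
per-strategy drug costs, event costs, utilities, and the discount rate.
A single seeded generator consumes the draws in this order, making
iteration ``i`` reproducible and the draw log a stable file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .markov import ParameterDraw, PerPatientOutcome, run_strategy
from .parameters import (
    BetaSpec,
    GammaSpec,
    ModelConfig,
    NormalSpec,
    TriangularSpec,
)

__all__ = [
    "PSAResults",
    "sample_triangular",
    "sample_beta",
    "sample_normal_positive",
    "sample_gamma",
    "parameter_names",
    "sample_values",
    "point_values",
    "values_to_draw",
    "draw_parameters",
    "point_draw",
    "run_base_case",
    "run_psa",
    "degenerate_config",
]

_EVENT_KEYS = {
    ("chd", "high_bp"): "chd",
    ("stroke", "high_bp"): "stroke",
    ("chd", "controlled_bp"): "chd_controlled",
    ("stroke", "controlled_bp"): "stroke_controlled",
}


# --------------------------------------------------------------------------
# samplers


def sample_triangular(spec: TriangularSpec, rng: np.random.Generator) -> float:
    """One triangular draw; degenerate specs return the mode exactly."""
    if spec.maximum - spec.minimum <= 0.0:
        return spec.mode
    return float(rng.triangular(spec.minimum, spec.mode, spec.maximum))


def sample_beta(spec: BetaSpec, rng: np.random.Generator) -> float:
    if spec.fixed is not None:
        return spec.fixed
    return float(rng.beta(spec.alpha, spec.beta))


def sample_normal_positive(spec: NormalSpec, rng: np.random.Generator) -> float:
    """Normal(mean, se) resampled until strictly positive.

    For the relative risks here the mean sits many standard errors
    above zero, so the truncation is numerically negligible but keeps
    the multiplicative scale legal.
    """
    if spec.se == 0.0:
        return spec.mean
    while True:
        x = float(rng.normal(spec.mean, spec.se))
        if x > 0.0:
            return x


def sample_lognormal_rr(spec: NormalSpec, rng: np.random.Generator) -> float:
    """Log-normal alternative for relative risks, moment-matched to the spec."""
    if spec.se == 0.0:
        return spec.mean
    sigma2 = np.log1p((spec.se / spec.mean) ** 2)
    mu = np.log(spec.mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def sample_gamma(
    spec: GammaSpec, rng: np.random.Generator, cap: Optional[float] = None
) -> float:
    """One gamma draw with the spec's mean and coefficient of variation.

    ``cap`` truncates the unbounded support (event probabilities are
    capped at 1; at the fixture means a cap event is astronomically
    rare).
    """
    if spec.cv == 0.0 or spec.mean == 0.0:
        x = spec.mean
    else:
        shape = spec.cv**-2
        scale = spec.mean / shape
        x = float(rng.gamma(shape, scale))
    if cap is not None:
        x = min(x, cap)
    return x


# --------------------------------------------------------------------------
# parameter enumeration


def _risk_items(config: ModelConfig):
    table = config.risk_table
    for event in ("chd", "stroke"):
        for bp in ("high_bp", "controlled_bp"):
            for band in table.bands:
                yield f"risk:{_EVENT_KEYS[(event, bp)]}:{band}", table.spec(band, event, bp)


def parameter_names(config: ModelConfig) -> list[str]:
    """Canonical draw-order list of sampled parameter names."""
    names = [name for name, _ in _risk_items(config)]
    names += ["case_fatality:stroke", "case_fatality:chd"]
    for s in config.strategies:
        names += [f"rr:{s.name}:stroke", f"rr:{s.name}:chd", f"rr:{s.name}:death"]
    for s in config.strategies:
        names.append(f"drug_cost:{s.name}")
    names += ["cost:stroke_hospitalization", "cost:chd_hospitalization", "cost:management"]
    names += ["utility:well", "utility:stroke", "utility:chd"]
    names.append("discount_rate")
    return names


def sample_values(config: ModelConfig, rng: np.random.Generator) -> dict[str, float]:
    """Draw every parameter once, in canonical order."""
    rr_sampler = (
        sample_lognormal_rr if config.rr_sampling == "lognormal" else sample_normal_positive
    )
    values: dict[str, float] = {}
    for name, spec in _risk_items(config):
        values[name] = sample_gamma(spec, rng, cap=1.0)
    values["case_fatality:stroke"] = sample_beta(config.case_fatality.stroke, rng)
    values["case_fatality:chd"] = sample_beta(config.case_fatality.chd, rng)
    for s in config.strategies:
        values[f"rr:{s.name}:stroke"] = rr_sampler(s.rr_stroke, rng)
        values[f"rr:{s.name}:chd"] = rr_sampler(s.rr_chd, rng)
        values[f"rr:{s.name}:death"] = rr_sampler(s.rr_death, rng)
    for s in config.strategies:
        values[f"drug_cost:{s.name}"] = sample_triangular(
            config.costs.annual_drug_cost[s.name], rng
        )
    values["cost:stroke_hospitalization"] = sample_triangular(
        config.costs.stroke_hospitalization, rng
    )
    values["cost:chd_hospitalization"] = sample_triangular(config.costs.chd_hospitalization, rng)
    values["cost:management"] = sample_triangular(config.costs.chronic_management, rng)
    values["utility:well"] = sample_beta(config.utilities.well, rng)
    values["utility:stroke"] = sample_beta(config.utilities.stroke, rng)
    values["utility:chd"] = sample_beta(config.utilities.chd, rng)
    values["discount_rate"] = sample_triangular(config.discount.sampling, rng)
    return values


def point_values(config: ModelConfig) -> dict[str, float]:
    """Deterministic base-case values: every distribution at its point estimate."""
    values: dict[str, float] = {}
    for name, spec in _risk_items(config):
        values[name] = spec.point()
    values["case_fatality:stroke"] = config.case_fatality.stroke.point()
    values["case_fatality:chd"] = config.case_fatality.chd.point()
    for s in config.strategies:
        values[f"rr:{s.name}:stroke"] = s.rr_stroke.point()
        values[f"rr:{s.name}:chd"] = s.rr_chd.point()
        values[f"rr:{s.name}:death"] = s.rr_death.point()
    for s in config.strategies:
        values[f"drug_cost:{s.name}"] = config.costs.annual_drug_cost[s.name].point()
    values["cost:stroke_hospitalization"] = config.costs.stroke_hospitalization.point()
    values["cost:chd_hospitalization"] = config.costs.chd_hospitalization.point()
    values["cost:management"] = config.costs.chronic_management.point()
    values["utility:well"] = config.utilities.well.point()
    values["utility:stroke"] = config.utilities.stroke.point()
    values["utility:chd"] = config.utilities.chd.point()
    values["discount_rate"] = config.discount.rate
    return values


def values_to_draw(config: ModelConfig, values: dict[str, float]) -> ParameterDraw:
    """Assemble a :class:`ParameterDraw` from a named value mapping."""
    risk = {}
    for name, _spec in _risk_items(config):
        _, event_key, band = name.split(":")
        risk[(event_key, int(band))] = values[name]
    rr = {
        s.name: (
            values[f"rr:{s.name}:stroke"],
            values[f"rr:{s.name}:chd"],
            values[f"rr:{s.name}:death"],
        )
        for s in config.strategies
    }
    return ParameterDraw(
        rr=rr,
        risk=risk,
        cf_stroke=values["case_fatality:stroke"],
        cf_chd=values["case_fatality:chd"],
        u_well=values["utility:well"],
        u_stroke=values["utility:stroke"],
        u_chd=values["utility:chd"],
        drug_cost={s.name: values[f"drug_cost:{s.name}"] for s in config.strategies},
        cost_stroke_hosp=values["cost:stroke_hospitalization"],
        cost_chd_hosp=values["cost:chd_hospitalization"],
        cost_management=values["cost:management"],
        discount_rate=values["discount_rate"],
        values=values,
    )


def draw_parameters(config: ModelConfig, rng: np.random.Generator) -> ParameterDraw:
    """One coherent random parameter draw."""
    return values_to_draw(config, sample_values(config, rng))


def point_draw(config: ModelConfig) -> ParameterDraw:
    """The deterministic base-case draw."""
    return values_to_draw(config, point_values(config))


def run_base_case(config: ModelConfig) -> dict[str, PerPatientOutcome]:
    """Deterministic point-estimate run of every strategy."""
    draw = point_draw(config)
    return {name: run_strategy(config, name, draw) for name in config.strategy_names}


def degenerate_config(config: ModelConfig) -> ModelConfig:
    """Copy of ``config`` with every distribution collapsed to its point.

    Normal standard errors and gamma CVs go to zero, triangulars pin to
    their mode, betas freeze at their mean, and the discount sampling
    pins to the base-case rate.  A PSA over the result reproduces the
    deterministic base case exactly.
    """

    def tri_fix(x: float) -> dict:
        return {"minimum": x, "mode": x, "maximum": x}

    data = config.model_dump()
    for e in data["risk_table"]["entries"]:
        e["probability"]["cv"] = 0.0
    for s in data["strategies"]:
        for f in ("rr_stroke", "rr_chd", "rr_death"):
            s[f]["se"] = 0.0
    for name, spec in data["costs"]["annual_drug_cost"].items():
        data["costs"]["annual_drug_cost"][name] = tri_fix(spec["mode"])
    for f in ("stroke_hospitalization", "chd_hospitalization", "chronic_management"):
        data["costs"][f] = tri_fix(data["costs"][f]["mode"])
    for group, fields in (("utilities", ("well", "stroke", "chd")), ("case_fatality", ("stroke", "chd"))):
        for f in fields:
            spec = data[group][f]
            spec["fixed"] = (
                spec["fixed"]
                if spec.get("fixed") is not None
                else spec["alpha"] / (spec["alpha"] + spec["beta"])
            )
    data["discount"]["sampling"] = tri_fix(data["discount"]["rate"])
    return ModelConfig.model_validate(data)


# --------------------------------------------------------------------------
# Monte Carlo


@dataclass
class PSAResults:
    """Strategy x iteration matrix of per-patient discounted outcomes."""

    strategies: list[str]
    qaly: np.ndarray  # (n_strategies, n_iter)
    cost: np.ndarray  # (n_strategies, n_iter)
    seed: Optional[int]
    n_iter: int
    draw_log: Optional[list[dict[str, float]]] = field(default=None, repr=False)

    def index(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def outcome(self, strategy: str, iteration: int) -> PerPatientOutcome:
        i = self.index(strategy)
        return PerPatientOutcome(
            qaly=float(self.qaly[i, iteration]), cost=float(self.cost[i, iteration])
        )

    def frame(self):
        """Long DataFrame, one row per (iteration, strategy)."""
        import pandas as pd

        rows = []
        for i, name in enumerate(self.strategies):
            for it in range(self.n_iter):
                rows.append(
                    {
                        "iteration": it,
                        "strategy": name,
                        "qaly": self.qaly[i, it],
                        "cost": self.cost[i, it],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} n_iter={self.n_iter}\n")
            self.frame().to_csv(fh, index=False)


def run_psa(
    config: ModelConfig,
    n_iter: int = 1000,
    seed: Optional[int] = None,
    keep_draws: bool = False,
) -> PSAResults:
    """Monte Carlo PSA: ``n_iter`` shared draws evaluated for every strategy."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    names = config.strategy_names
    qaly = np.zeros((len(names), n_iter))
    cost = np.zeros((len(names), n_iter))
    log: Optional[list[dict[str, float]]] = [] if keep_draws else None
    for it in range(n_iter):
        values = sample_values(config, rng)
        draw = values_to_draw(config, values)
        for i, name in enumerate(names):
            out = run_strategy(config, name, draw)
            qaly[i, it] = out.qaly
            cost[i, it] = out.cost
        if log is not None:
            log.append(values)
    return PSAResults(
        strategies=list(names), qaly=qaly, cost=cost, seed=seed, n_iter=n_iter, draw_log=log
    )
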