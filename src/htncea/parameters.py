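"""Parameter data model for the antihypertensive cost-utility analysis.

The model is driven entirely by a structured parameter set: age-banded
annual probabilities of coronary heart disease (CHD) and stroke for a
hypertensive cohort, a national life table for background mortality,
per-strategy drug effects (relative risks), cost items, health-state
utilities, case-fatality probabilities and a discount specification.
Each uncertain quantity carries the distribution used by the
probabilistic sensitivity analysis (normal for relative risks, beta for
utilities and case fatalities, triangular for costs and the discount
rate, gamma for event probabilities).

Configurations serialize to/from a YAML document whose layout mirrors
the class fields one-to-one; :func:`load_config` validates every
invariant and reports violations with field paths.
"""

from __future__ import annotations

import io
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ValidationError, model_validator

__all__ = [
    "NormalSpec",
    "BetaSpec",
    "TriangularSpec",
    "GammaSpec",
    "DrugEffect",
    "RiskEntry",
    "AgeBandRiskTable",
    "LifeTable",
    "CostSet",
    "UtilitySet",
    "CaseFatalitySet",
    "DiscountSpec",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "validate_config",
    "inflate_cost",
    "ppp_convert",
    "annualize_risk",
    "lookup_annual_risk",
    "export_tables",
    "RISK_STRATA",
    "NULL_STRATEGY",
]

RISK_STRATA = ("low", "medium", "high")
NULL_STRATEGY = "null"

Stratum = Literal["low", "medium", "high"]
Event = Literal["chd", "stroke"]
BPStatus = Literal["high_bp", "controlled_bp"]


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant.

    ``errors`` holds one human-readable message per violation, each
    prefixed with the dotted path of the offending field.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class _Spec(BaseModel):
    model_config = {"extra": "forbid"}


class NormalSpec(_Spec):
    """Normal distribution given as mean and standard error.

    ``se == 0`` denotes a point mass at the mean (used by the null
    strategy and by degenerate configurations).
    """

    mean: float
    se: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.se < 0:
            raise ValueError("se must be >= 0")
        return self

    def point(self) -> float:
        return self.mean


class BetaSpec(_Spec):
    """Beta distribution with shape parameters ``alpha`` and ``beta``.

    If ``fixed`` is set the spec is a point mass at that value; this is
    how degenerate configurations freeze beta-distributed quantities
    (a beta cannot be made degenerate through finite shape parameters).
    """

    alpha: float
    beta: float
    fixed: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if self.fixed is not None:
            if not 0.0 <= self.fixed <= 1.0:
                raise ValueError("fixed value must lie in [0, 1]")
            return self
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        return self

    def point(self) -> float:
        if self.fixed is not None:
            return self.fixed
        return self.alpha / (self.alpha + self.beta)


class TriangularSpec(_Spec):
    """Triangular distribution (minimum, mode, maximum)."""

    minimum: float
    mode: float
    maximum: float

    @model_validator(mode="after")
    def _check(self):
        if not self.minimum <= self.mode <= self.maximum:
            raise ValueError("requires minimum <= mode <= maximum")
        return self

    def point(self) -> float:
        return self.mode


class GammaSpec(_Spec):
    """Gamma distribution parameterized by mean and coefficient of variation.

    shape = cv**-2, scale = mean * cv**2, so the sampled mean equals the
    stated point estimate.  ``cv == 0`` is a point mass.  The default
    cv of 0.10 is the package-wide choice for event probabilities,
    whose spread is otherwise unspecified; it is exposed in the
    configuration precisely because it is a modelling choice.
    """

    mean: float
    cv: float = 0.10

    @model_validator(mode="after")
    def _check(self):
        if self.mean < 0:
            raise ValueError("mean must be >= 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        return self

    def point(self) -> float:
        return self.mean


class DrugEffect(_Spec):
    """Multiplicative drug effects of one strategy on event risks.

    ``rr_stroke`` / ``rr_chd`` scale the annual probabilities of stroke
    and CHD; ``rr_death`` scales the case-fatality probability of an
    incident event (cardiovascular death), not background mortality.
    """

    name: str
    rr_stroke: NormalSpec
    rr_chd: NormalSpec
    rr_death: NormalSpec

    @model_validator(mode="after")
    def _check(self):
        for field in ("rr_stroke", "rr_chd", "rr_death"):
            if getattr(self, field).mean <= 0:
                raise ValueError(f"{field}: point estimate must be > 0")
        return self


class RiskEntry(_Spec):
    age: int
    event: Event
    bp: BPStatus
    probability: GammaSpec

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.probability.mean <= 1.0:
            raise ValueError(
                f"probability {self.probability.mean} outside [0, 1] "
                f"(age {self.age}, {self.event}, {self.bp})"
            )
        return self


class AgeBandRiskTable(_Spec):
    """Annual event probabilities by five-year age band.

    Lookup is a left-closed step function: an age maps to the greatest
    band start not exceeding it, and ages beyond the last band reuse
    the last band (carry-forward).  Within each (event, blood-pressure
    status) series the probabilities must be non-decreasing in age.
    """

    entries: list[RiskEntry]

    @model_validator(mode="after")
    def _check(self):
        errors: list[str] = []
        bands = sorted({e.age for e in self.entries})
        seen: dict[tuple[int, str, str], float] = {}
        for e in self.entries:
            key = (e.age, e.event, e.bp)
            if key in seen:
                errors.append(f"duplicate entry for age {e.age}, {e.event}, {e.bp}")
            seen[key] = e.probability.mean
        for event in ("chd", "stroke"):
            for bp in ("high_bp", "controlled_bp"):
                series = []
                for band in bands:
                    key = (band, event, bp)
                    if key not in seen:
                        errors.append(
                            f"missing entry for age {band}, {event}, {bp}"
                        )
                    else:
                        series.append((band, seen[key]))
                for (a0, p0), (a1, p1) in zip(series, series[1:]):
                    if p1 < p0:
                        errors.append(
                            f"{event}/{bp}: probability decreases from "
                            f"{p0} at age {a0} to {p1} at age {a1}"
                        )
        if errors:
            raise ValueError("; ".join(errors))
        return self

    @property
    def bands(self) -> list[int]:
        return sorted({e.age for e in self.entries})

    def value(self, age: float, event: Event, bp: BPStatus = "high_bp") -> float:
        return lookup_annual_risk(self, age, event, bp)

    def spec(self, band: int, event: Event, bp: BPStatus) -> GammaSpec:
        for e in self.entries:
            if e.age == band and e.event == event and e.bp == bp:
                return e.probability
        raise KeyError((band, event, bp))


class LifeEntry(_Spec):
    age: int
    rate: float

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mortality rate {self.rate} outside [0, 1] (age {self.age})")
        return self


class LifeTable(_Spec):
    """Age-banded annual all-cause mortality, step-function lookup."""

    entries: list[LifeEntry]

    @model_validator(mode="after")
    def _check(self):
        ages = [e.age for e in self.entries]
        if len(set(ages)) != len(ages):
            raise ValueError("duplicate age bands in life table")
        return self

    @property
    def bands(self) -> list[int]:
        return sorted(e.age for e in self.entries)

    def rate(self, age: float) -> float:
        bands = self.bands
        if age < bands[0]:
            raise ValueError(f"age {age} below first life-table band {bands[0]}")
        chosen = bands[0]
        for b in bands:
            if b <= age:
                chosen = b
        for e in self.entries:
            if e.age == chosen:
                return e.rate
        raise AssertionError("unreachable")


class CostSet(_Spec):
    """Annual cost items in 2010 US dollars per patient.

    Drug costs (keyed by strategy name) are all-inclusive annual
    outpatient costs — medication plus physician visits.  Event costs
    are a one-time hospitalization at the incident event and an annual
    chronic-management cost shared by stroke and CHD survivors.
    """

    annual_drug_cost: dict[str, TriangularSpec]
    stroke_hospitalization: TriangularSpec
    chd_hospitalization: TriangularSpec
    chronic_management: TriangularSpec

    @model_validator(mode="after")
    def _check(self):
        errors = []
        for name, spec in self.annual_drug_cost.items():
            if spec.minimum < 0:
                errors.append(f"annual_drug_cost[{name}]: negative cost")
        for field in ("stroke_hospitalization", "chd_hospitalization", "chronic_management"):
            if getattr(self, field).minimum < 0:
                errors.append(f"{field}: negative cost")
        if NULL_STRATEGY in self.annual_drug_cost:
            spec = self.annual_drug_cost[NULL_STRATEGY]
            if not (spec.minimum == spec.mode == spec.maximum == 0.0):
                errors.append("annual_drug_cost[null]: must be fixed at 0")
        if errors:
            raise ValueError("; ".join(errors))
        return self


class UtilitySet(_Spec):
    """Health-state utility weights; the dead states have utility 0."""

    well: BetaSpec
    stroke: BetaSpec
    chd: BetaSpec


class CaseFatalitySet(_Spec):
    """Probability that an incident event is fatal in its cycle."""

    stroke: BetaSpec
    chd: BetaSpec

    @model_validator(mode="after")
    def _check(self):
        for field in ("stroke", "chd"):
            spec = getattr(self, field)
            if spec.fixed is None and not 0.0 < spec.point() < 1.0:
                raise ValueError(f"{field}: case-fatality mean must be in (0, 1)")
        return self


class DiscountSpec(_Spec):
    """Discounting of both costs and QALYs.

    ``rate`` is the deterministic base-case rate; ``sampling`` is the
    distribution drawn once per PSA iteration and applied to both
    streams.
    """

    rate: float = 0.03
    sampling: TriangularSpec = TriangularSpec(minimum=0.0, mode=0.03, maximum=0.05)

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        if not self.sampling.minimum <= self.rate <= self.sampling.maximum:
            raise ValueError("base-case rate must lie inside the sampling range")
        return self


class ModelConfig(_Spec):
    """Complete parameter set for one cardiovascular risk stratum.

    ``treated_risk_source`` selects how treated-arm event risks are
    formed: ``high_bp_times_rr`` (default) multiplies the High-BP risk
    column by the drug relative risks; ``controlled_bp_column`` reads
    the Controlled-BP column directly (a single shared column, so the
    per-drug relative risks are ignored for event incidence).

    ``rr_sampling`` chooses between zero-truncated normal sampling of
    relative risks (default, matching their stated distributions) and
    a log-normal alternative.  ``rr_death_on_background`` (default on)
    makes a drug's relative risk of death multiply background all-cause
    mortality as well as event case fatality; ``half_cycle_correction``
    (default on) accrues each cycle on the average of its start and end
    occupancy.  Both conventions, together with
    ``discount_first_cycle`` (default off: the first cycle is
    undiscounted), are the cycle-accounting choices that reproduce the
    published results and can be switched off individually.
    """

    stratum: Stratum
    starting_age: int = 40
    horizon_cycles: int = 30
    cohort_size: int = 1000
    risk_table: AgeBandRiskTable
    life_table: LifeTable
    strategies: list[DrugEffect]
    costs: CostSet
    utilities: UtilitySet
    case_fatality: CaseFatalitySet
    discount: DiscountSpec = DiscountSpec()
    treated_risk_source: Literal["high_bp_times_rr", "controlled_bp_column"] = "high_bp_times_rr"
    rr_sampling: Literal["truncated_normal", "lognormal"] = "truncated_normal"
    rr_death_on_background: bool = True
    half_cycle_correction: bool = True
    discount_first_cycle: bool = False

    @model_validator(mode="after")
    def _check(self):
        errors: list[str] = []
        if self.horizon_cycles < 1:
            errors.append("horizon_cycles: must be >= 1")
        if self.cohort_size < 1:
            errors.append("cohort_size: must be >= 1")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            errors.append("strategies: names must be unique")
        if NULL_STRATEGY not in names:
            errors.append("strategies: null strategy required")
        else:
            null = next(s for s in self.strategies if s.name == NULL_STRATEGY)
            for field in ("rr_stroke", "rr_chd", "rr_death"):
                spec = getattr(null, field)
                if spec.mean != 1.0 or spec.se != 0.0:
                    errors.append(f"strategies[null].{field}: must be fixed at exactly 1")
        for name in names:
            if name not in self.costs.annual_drug_cost:
                errors.append(f"costs.annual_drug_cost: missing strategy {name!r}")
        if self.risk_table.entries and self.risk_table.bands[0] > self.starting_age:
            errors.append(
                f"risk_table: first band {self.risk_table.bands[0]} exceeds "
                f"starting_age {self.starting_age}"
            )
        if self.life_table.entries and self.life_table.bands[0] > self.starting_age:
            errors.append(
                f"life_table: first band {self.life_table.bands[0]} exceeds "
                f"starting_age {self.starting_age}"
            )
        if errors:
            raise ValueError("; ".join(errors))
        return self

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def strategy(self, name: str) -> DrugEffect:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)


# --------------------------------------------------------------------------
# serialization


def _format_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        msg = err["msg"]
        # pydantic prefixes wrapped ValueErrors with "Value error, "
        msg = msg.removeprefix("Value error, ")
        out.append(f"{path}: {msg}")
    return out


def load_config(source: Union[str, "io.TextIOBase"]) -> ModelConfig:
    """Load and validate a configuration from a YAML path, text or stream.

    Raises :class:`ConfigError` listing every violated invariant with
    its field path.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and (text.endswith((".yaml", ".yml")) or "/" in text):
            with open(text, "r") as fh:
                text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"<document>: invalid YAML ({exc})"]) from exc
    if not isinstance(data, dict):
        raise ConfigError(["<document>: expected a mapping at top level"])
    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def save_config(config: ModelConfig, path: Optional[str] = None) -> str:
    """Serialize a configuration to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def validate_config(source) -> list[str]:
    """Return the list of violations (empty when the document is valid)."""
    try:
        load_config(source)
    except ConfigError as exc:
        return exc.errors
    return []


# --------------------------------------------------------------------------
# pre-processing utilities


def inflate_cost(amount: float, annual_rate: float, years: int) -> float:
    """Compound a monetary amount forward: amount * (1 + rate)**years."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return amount * (1.0 + annual_rate) ** years


def ppp_convert(median_price: float, ppp_rate: float, fx_rate: float) -> float:
    """Convert an international median price to local USD.

    The price is multiplied by the purchasing-power-parity rate (local
    currency per USD) and divided by the market exchange rate.
    """
    if ppp_rate <= 0 or fx_rate <= 0:
        raise ValueError("rates must be > 0")
    if median_price < 0:
        raise ValueError("price must be >= 0")
    return median_price * ppp_rate / fx_rate


def annualize_risk(p_multi: float, horizon_years: int) -> float:
    """Convert a multi-year event probability to the equivalent annual one.

    Assumes a constant hazard over the horizon:
    ``1 - (1 - p)**(1/h)``.
    """
    if not 0.0 <= p_multi <= 1.0:
        raise ValueError("p_multi must lie in [0, 1]")
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    return 1.0 - (1.0 - p_multi) ** (1.0 / horizon_years)


def lookup_annual_risk(
    table: AgeBandRiskTable, age: float, event: Event, bp: BPStatus = "high_bp"
) -> float:
    """Step-function lookup of the annual event probability at ``age``.

    The value of the greatest band start not exceeding ``age`` applies;
    ages beyond the last band carry the last band forward.  Band
    boundaries belong to the new band.
    """
    bands = table.bands
    if not bands:
        raise ValueError("empty risk table")
    if age < bands[0]:
        raise ValueError(f"age {age} below first band {bands[0]}")
    chosen = bands[0]
    for b in bands:
        if b <= age:
            chosen = b
    return table.spec(chosen, event, bp).mean


def export_tables(config: ModelConfig, outdir: str) -> list[str]:
    """Write the parameter set as CSV tables for inspection.

    Produces risk_table.csv, life_table.csv and distributions.csv in
    ``outdir`` and returns the written paths.
    """
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    paths = []

    risk = pd.DataFrame(
        [
            {
                "age_band": e.age,
                "event": e.event,
                "bp_status": e.bp,
                "annual_probability": e.probability.mean,
                "gamma_cv": e.probability.cv,
            }
            for e in config.risk_table.entries
        ]
    ).sort_values(["event", "bp_status", "age_band"])
    p = os.path.join(outdir, "risk_table.csv")
    risk.to_csv(p, index=False)
    paths.append(p)

    life = pd.DataFrame(
        [{"age_band": e.age, "annual_mortality_rate": e.rate} for e in config.life_table.entries]
    ).sort_values("age_band")
    p = os.path.join(outdir, "life_table.csv")
    life.to_csv(p, index=False)
    paths.append(p)

    rows = []
    for s in config.strategies:
        for field in ("rr_stroke", "rr_chd", "rr_death"):
            spec = getattr(s, field)
            rows.append(
                {
                    "parameter": f"{field}:{s.name}",
                    "distribution": "normal",
                    "a": spec.mean,
                    "b": spec.se,
                }
            )
    for name, spec in config.costs.annual_drug_cost.items():
        rows.append(
            {
                "parameter": f"annual_drug_cost:{name}",
                "distribution": "triangular",
                "a": spec.minimum,
                "b": spec.maximum,
                "mode": spec.mode,
            }
        )
    for field in ("stroke_hospitalization", "chd_hospitalization", "chronic_management"):
        spec = getattr(config.costs, field)
        rows.append(
            {
                "parameter": f"cost:{field}",
                "distribution": "triangular",
                "a": spec.minimum,
                "b": spec.maximum,
                "mode": spec.mode,
            }
        )
    for field in ("well", "stroke", "chd"):
        spec = getattr(config.utilities, field)
        rows.append(
            {"parameter": f"utility:{field}", "distribution": "beta", "a": spec.alpha, "b": spec.beta}
        )
    for field in ("stroke", "chd"):
        spec = getattr(config.case_fatality, field)
        rows.append(
            {
                "parameter": f"case_fatality:{field}",
                "distribution": "beta",
                "a": spec.alpha,
                "b": spec.beta,
            }
        )
    rows.append(
        {
            "parameter": "discount_rate",
            "distribution": "triangular",
            "a": config.discount.sampling.minimum,
            "b": config.discount.sampling.maximum,
            "mode": config.discount.sampling.mode,
        }
    )
    p = os.path.join(outdir, "distributions.csv")
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)
    return paths
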