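"""Built-in parameter set of the Nigerian antihypertensive cost-utility study.

The study compared hydrochlorothiazide (thiazide diuretic), propranolol
(beta blocker), lisinopril (ACE inhibitor) and nifedipine (calcium
channel blocker) against a no-treatment null scenario in a cohort of
1000 hypertensive Nigerians followed for 30 annual cycles from age 40,
stratified into low / medium / high cardiovascular risk by WHO/ISH
criteria.  All monetary values are 2010 US dollars.

:func:`reference_config` returns the complete :class:`ModelConfig` for
one stratum, reproducing the published inputs verbatim: age-banded
annual CHD/stroke probabilities, the Nigerian life table, drug relative
risks with standard errors from a meta-analysis, triangular cost items,
beta-distributed utilities and case fatalities, and the 3% (0–5%)
discount specification.
"""

from __future__ import annotations

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

__all__ = ["reference_config", "STRATEGIES", "EVENT_PROBABILITY_CV"]

#: Default coefficient of variation of the gamma distributions placed on
#: the annual event probabilities (their spread is not reported).
EVENT_PROBABILITY_CV = 0.10

STRATEGIES = ("null", "thiazide", "beta_blocker", "acei", "ccb")

# Annual probabilities of CHD and stroke by age band:
# {stratum: {band: (chd_high, stroke_high, chd_controlled, stroke_controlled)}}
_RISK = {
    "low": {
        40: (0.0010, 0.0041, 0.0010, 0.0030),
        45: (0.0020, 0.0062, 0.0010, 0.0041),
        50: (0.0030, 0.0094, 0.0020, 0.0051),
        55: (0.0041, 0.0138, 0.0030, 0.0083),
        60: (0.0051, 0.0196, 0.0041, 0.0116),
        65: (0.0072, 0.0284, 0.0062, 0.0161),
        70: (0.0105, 0.0407, 0.0083, 0.0233),
    },
    "medium": {
        40: (0.0041, 0.0105, 0.0030, 0.0051),
        45: (0.0051, 0.0150, 0.0041, 0.0072),
        50: (0.0072, 0.0221, 0.0051, 0.0105),
        55: (0.0105, 0.0310, 0.0072, 0.0150),
        60: (0.0150, 0.0452, 0.0105, 0.0221),
        65: (0.0209, 0.0651, 0.0150, 0.0323),
        70: (0.0297, 0.0922, 0.0209, 0.0452),
    },
    "high": {
        40: (0.0072, 0.0221, 0.0041, 0.0094),
        45: (0.0094, 0.0323, 0.0062, 0.0127),
        50: (0.0138, 0.0467, 0.0083, 0.0185),
        55: (0.0185, 0.0670, 0.0116, 0.0271),
        60: (0.0271, 0.0946, 0.0161, 0.0393),
        65: (0.0378, 0.1330, 0.0233, 0.0563),
        70: (0.0530, 0.1846, 0.0323, 0.0809),
    },
}

# Nigerian life table: annual all-cause mortality by five-year band.
_LIFE = {
    40: 0.01372,
    45: 0.01529,
    50: 0.01900,
    55: 0.02569,
    60: 0.03287,
    65: 0.04781,
    70: 0.07221,
    75: 0.10773,
    80: 0.15920,
    85: 0.22886,
    90: 0.32027,
}

# Relative risks (mean, se) versus no treatment: (stroke, chd, death).
_RR = {
    "thiazide": ((0.63, 0.056), (0.84, 0.060), (0.89, 0.037)),
    "beta_blocker": ((0.83, 0.076), (0.90, 0.071), (0.96, 0.056)),
    "acei": ((0.65, 0.116), (0.81, 0.075), (0.83, 0.071)),
    "ccb": ((0.58, 0.183), (0.77, 0.174), (0.86, 0.120)),
}

# Annual all-inclusive drug + physician cost (min, mode, max), 2010 USD.
_DRUG_COST = {
    "null": (0.0, 0.0, 0.0),
    "thiazide": (71.75, 89.69, 107.63),
    "beta_blocker": (82.69, 103.36, 124.03),
    "acei": (323.26, 404.08, 484.89),
    "ccb": (235.78, 294.72, 353.67),
}

_STROKE_HOSP = (698.89, 873.62, 1048.34)
_CHD_HOSP = (249.39, 311.73, 374.08)
_MANAGEMENT = (334.20, 417.74, 501.29)

_UTILITY = {
    "well": (206.1, 155.1),  # mean 0.57, asymptomatic hypertensive
    "stroke": (1.0, 23.3),  # mean 0.04
    "chd": (4.9, 32.9),  # mean 0.13
}

# Case fatality of an incident event.  The reported rates are 27%
# (stroke) and 51% (CHD); the beta shapes keep alpha + beta = 1 as
# published, with the mean anchored to the reported rate.
_CASE_FATALITY = {"stroke": (0.27, 0.73), "chd": (0.51, 0.49)}


def _tri(t: tuple[float, float, float]) -> TriangularSpec:
    return TriangularSpec(minimum=t[0], mode=t[1], maximum=t[2])


def reference_config(
    stratum: str = "medium", event_probability_cv: float = EVENT_PROBABILITY_CV
) -> ModelConfig:
    """Return the full study configuration for one cardiovascular risk stratum.

    Parameters
    ----------
    stratum
        ``"low"``, ``"medium"`` or ``"high"``.
    event_probability_cv
        Coefficient of variation of the gamma distributions on the
        annual event probabilities.
    """
    if stratum not in _RISK:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {sorted(_RISK)}")

    entries = []
    for band, (chd_h, str_h, chd_c, str_c) in _RISK[stratum].items():
        for event, bp, p in (
            ("chd", "high_bp", chd_h),
            ("stroke", "high_bp", str_h),
            ("chd", "controlled_bp", chd_c),
            ("stroke", "controlled_bp", str_c),
        ):
            entries.append(
                {
                    "age": band,
                    "event": event,
                    "bp": bp,
                    "probability": GammaSpec(mean=p, cv=event_probability_cv),
                }
            )

    strategies = [
        DrugEffect(
            name="null",
            rr_stroke=NormalSpec(mean=1.0, se=0.0),
            rr_chd=NormalSpec(mean=1.0, se=0.0),
            rr_death=NormalSpec(mean=1.0, se=0.0),
        )
    ]
    for name, ((rs, ses), (rc, sec), (rd, sed)) in _RR.items():
        strategies.append(
            DrugEffect(
                name=name,
                rr_stroke=NormalSpec(mean=rs, se=ses),
                rr_chd=NormalSpec(mean=rc, se=sec),
                rr_death=NormalSpec(mean=rd, se=sed),
            )
        )

    return ModelConfig(
        stratum=stratum,
        starting_age=40,
        horizon_cycles=30,
        cohort_size=1000,
        risk_table=AgeBandRiskTable(entries=entries),
        life_table=LifeTable(entries=[{"age": a, "rate": r} for a, r in _LIFE.items()]),
        strategies=strategies,
        costs=CostSet(
            annual_drug_cost={k: _tri(v) for k, v in _DRUG_COST.items()},
            stroke_hospitalization=_tri(_STROKE_HOSP),
            chd_hospitalization=_tri(_CHD_HOSP),
            chronic_management=_tri(_MANAGEMENT),
        ),
        utilities=UtilitySet(
            well=BetaSpec(alpha=_UTILITY["well"][0], beta=_UTILITY["well"][1]),
            stroke=BetaSpec(alpha=_UTILITY["stroke"][0], beta=_UTILITY["stroke"][1]),
            chd=BetaSpec(alpha=_UTILITY["chd"][0], beta=_UTILITY["chd"][1]),
        ),
        case_fatality=CaseFatalitySet(
            stroke=BetaSpec(alpha=_CASE_FATALITY["stroke"][0], beta=_CASE_FATALITY["stroke"][1]),
            chd=BetaSpec(alpha=_CASE_FATALITY["chd"][0], beta=_CASE_FATALITY["chd"][1]),
        ),
        discount=DiscountSpec(
            rate=0.03, sampling=TriangularSpec(minimum=0.0, mode=0.03, maximum=0.05)
        ),
    )
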