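"""Decision statistics over PSA output.

Net monetary benefit (NMB) is computed on the monetary scale,
``lambda * QALY - cost`` at willingness-to-pay ``lambda`` (USD/QALY);
the equivalent net health benefit ``QALY - cost/lambda`` is exposed as
a derived output.  Per-iteration NMB maxima give the probability of
cost-effectiveness; sweeping a willingness-to-pay grid yields the
cost-effectiveness acceptability curve (CEAC, null comparator excluded)
and frontier (CEAF, null included, tracking the strategy with the
highest *expected* NMB).  An ICER table with strict and extended
dominance completes the standard reporting set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import NULL_STRATEGY
from .psa import PSAResults

__all__ = [
    "WTPGrid",
    "CEAFPoint",
    "default_wtp_grid",
    "nmb",
    "nhb",
    "nmb_matrix",
    "expected_nmb",
    "prob_cost_effective",
    "ceac",
    "ceaf",
    "ceaf_frame",
    "icer_table",
    "frontier_switch_lambda",
    "overtake_lambda",
]


@dataclass(frozen=True)
class WTPGrid:
    """Strictly increasing, non-negative willingness-to-pay values."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty WTP grid")
        if np.any(v < 0):
            raise ValueError("WTP values must be non-negative")
        if np.any(np.diff(v) <= 0):
            raise ValueError("WTP values must be strictly increasing")

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


def default_wtp_grid(
    wtp_min: float = 0.0, wtp_max: float = 15000.0, points: int = 58
) -> WTPGrid:
    """Evenly spaced grid; the default spans $0-15,000/QALY in 58 points."""
    return WTPGrid(values=tuple(np.linspace(wtp_min, wtp_max, points)))


@dataclass(frozen=True)
class CEAFPoint:
    """Frontier summary at one willingness-to-pay value."""

    wtp: float
    prob_optimal: dict[str, float]
    expected_nmb: dict[str, float]
    frontier_strategy: str
    frontier_probability: float


def nmb(qaly, cost, wtp):
    """Net monetary benefit ``wtp * qaly - cost`` (USD/patient)."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(qaly) - np.asarray(cost)


def nhb(qaly, cost, wtp):
    """Net health benefit ``qaly - cost / wtp`` (QALY/patient); wtp > 0."""
    if np.any(np.asarray(wtp) <= 0):
        raise ValueError("willingness-to-pay must be > 0 for the health scale")
    return np.asarray(qaly) - np.asarray(cost) / wtp


def nmb_matrix(psa: PSAResults, wtp: float) -> np.ndarray:
    """(strategy, iteration) matrix of per-iteration NMB."""
    return nmb(psa.qaly, psa.cost, wtp)


def expected_nmb(psa: PSAResults, wtp: float) -> dict[str, float]:
    """Mean per-patient NMB by strategy."""
    means = nmb_matrix(psa, wtp).mean(axis=1)
    return dict(zip(psa.strategies, means.tolist()))


def _argmax_probabilities(matrix: np.ndarray) -> np.ndarray:
    """Per-row share of iterations in which each row attains the maximum.

    Ties split equally among the tied strategies, so columns always
    contribute exactly 1 in total.
    """
    top = matrix.max(axis=0, keepdims=True)
    is_max = matrix == top
    weights = is_max / is_max.sum(axis=0, keepdims=True)
    return weights.mean(axis=1)


def prob_cost_effective(
    psa: PSAResults, wtp: float, include: list[str] | None = None
) -> dict[str, float]:
    """Probability that each strategy has the highest per-iteration NMB."""
    names = list(psa.strategies) if include is None else list(include)
    idx = [psa.index(n) for n in names]
    probs = _argmax_probabilities(nmb_matrix(psa, wtp)[idx])
    return dict(zip(names, probs.tolist()))


def ceac(psa: PSAResults, grid: WTPGrid) -> pd.DataFrame:
    """Acceptability curve over the grid, null comparator excluded."""
    names = [n for n in psa.strategies if n != NULL_STRATEGY]
    rows = []
    for wtp in grid:
        probs = prob_cost_effective(psa, wtp, include=names)
        rows.append({"wtp": wtp, **probs})
    return pd.DataFrame(rows)


def ceaf(psa: PSAResults, grid: WTPGrid) -> list[CEAFPoint]:
    """Acceptability frontier over the grid, null comparator included.

    At each willingness-to-pay the frontier strategy maximizes the
    expected NMB; its probability of cost-effectiveness is read off the
    all-strategy acceptability probabilities.
    """
    points = []
    for wtp in grid:
        probs = prob_cost_effective(psa, wtp)
        enmb = expected_nmb(psa, wtp)
        frontier = max(enmb, key=enmb.get)
        points.append(
            CEAFPoint(
                wtp=float(wtp),
                prob_optimal=probs,
                expected_nmb=enmb,
                frontier_strategy=frontier,
                frontier_probability=probs[frontier],
            )
        )
    return points


def ceaf_frame(points: list[CEAFPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"wtp": p.wtp, "frontier_strategy": p.frontier_strategy,
               "frontier_probability": p.frontier_probability}
        row.update({f"prob_{k}": v for k, v in p.prob_optimal.items()})
        row.update({f"enmb_{k}": v for k, v in p.expected_nmb.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frontier_switch_lambda(points: list[CEAFPoint], strategy: str) -> float | None:
    """Smallest grid willingness-to-pay at which ``strategy`` is the frontier."""
    for p in points:
        if p.frontier_strategy == strategy:
            return p.wtp
    return None


def overtake_lambda(psa: PSAResults, challenger: str, incumbent: str, grid: WTPGrid) -> float | None:
    """Smallest grid value where the challenger's expected NMB exceeds the incumbent's."""
    i, j = psa.index(challenger), psa.index(incumbent)
    dq = psa.qaly[i].mean() - psa.qaly[j].mean()
    dc = psa.cost[i].mean() - psa.cost[j].mean()
    for wtp in grid:
        if wtp * dq - dc > 0:
            return float(wtp)
    return None


def icer_table(psa: PSAResults) -> pd.DataFrame:
    """Expected costs/QALYs with strict and extended dominance and ICERs.

    Strategies are sorted by expected cost.  A strategy is strictly
    dominated if another costs no more and yields at least as many
    QALYs (one inequality strict); extended dominance removes
    strategies whose ICER exceeds that of the next more effective
    option.  ICERs are reported between successive frontier members;
    a zero QALY difference is flagged indeterminate rather than
    divided.
    """
    mean_cost = psa.cost.mean(axis=1)
    mean_qaly = psa.qaly.mean(axis=1)
    df = pd.DataFrame(
        {"strategy": psa.strategies, "expected_cost": mean_cost, "expected_qaly": mean_qaly}
    ).sort_values(["expected_cost", "expected_qaly"], ignore_index=True)

    n = len(df)
    dominated = np.zeros(n, dtype=bool)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            better_cost = df.expected_cost[b] <= df.expected_cost[a]
            better_qaly = df.expected_qaly[b] >= df.expected_qaly[a]
            strict = (df.expected_cost[b] < df.expected_cost[a]) or (
                df.expected_qaly[b] > df.expected_qaly[a]
            )
            if better_cost and better_qaly and strict:
                dominated[a] = True
                break
    df["dominated"] = dominated

    extended = np.zeros(n, dtype=bool)
    while True:
        active = [i for i in range(n) if not dominated[i] and not extended[i]]
        removed = False
        for k in range(1, len(active) - 1):
            prev_i, i, next_i = active[k - 1], active[k], active[k + 1]

            def _icer(a, b):
                dq = df.expected_qaly[b] - df.expected_qaly[a]
                dc = df.expected_cost[b] - df.expected_cost[a]
                return np.inf if dq <= 0 else dc / dq

            if _icer(prev_i, i) > _icer(i, next_i):
                extended[i] = True
                removed = True
                break
        if not removed:
            break
    df["extended_dominated"] = extended

    icers: list[object] = [np.nan] * n
    frontier = [i for i in range(n) if not dominated[i] and not extended[i]]
    for prev_i, i in zip(frontier, frontier[1:]):
        dq = df.expected_qaly[i] - df.expected_qaly[prev_i]
        dc = df.expected_cost[i] - df.expected_cost[prev_i]
        icers[i] = "indeterminate" if dq == 0 else dc / dq
    df["icer"] = icers
    return df
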