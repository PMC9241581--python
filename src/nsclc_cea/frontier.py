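"""Incremental cost-effectiveness analysis: ICERs, dominance, the frontier.

The cost-effectiveness frontier is the lower-left convex hull of the
cost-QALY plane.  A strategy is *dominated* when another is no worse on
both axes and strictly better on at least one; it is *extended dominated*
when its ICER against the previous retained strategy exceeds the ICER of
the next retained strategy (a convex combination of its neighbours buys
QALYs more cheaply).  Sequential ICERs along the remaining frontier are
increasing by construction — strictly so except for exactly collinear
points, which are kept since no combination strictly improves on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .markov import CEResult

__all__ = [
    "ON_FRONTIER",
    "DOMINATED",
    "EXTENDED_DOMINATED",
    "Icer",
    "icer",
    "nmb",
    "FrontierResult",
    "build_frontier",
]

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class Icer:
    """Outcome of an incremental comparison a vs b.

    ``status`` is ``"ratio"`` (a regular ICER), ``"dominant"`` (a is cheaper
    and at least as effective), ``"dominated"`` (the reverse) or
    ``"degenerate"`` (zero QALY difference).  ``value`` holds the ratio; for
    dominance it is the forced ratio (negative or misleadingly small, kept
    for reporting), ``nan`` when degenerate.
    """

    status: str
    value: float


def icer(a: CEResult, b: CEResult) -> Icer:
    """Incremental cost-effectiveness ratio of ``a`` versus ``b``."""
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    if dq == 0.0:
        return Icer("degenerate", math.nan)
    ratio = dc / dq
    if dc <= 0.0 and dq >= 0.0:
        return Icer("dominant", ratio)
    if dc >= 0.0 and dq <= 0.0:
        return Icer("dominated", ratio)
    return Icer("ratio", ratio)


def nmb(result: CEResult, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * result.qaly - result.cost


@dataclass
class FrontierResult:
    """Classification of every arm plus sequential ICERs along the frontier."""

    classifications: dict[str, str]
    frontier: list[str]  # on-frontier arm names sorted by ascending cost
    sequential_icers: dict[str, float]  # vs the next-cheaper frontier arm
    results: dict[str, CEResult] = field(default_factory=dict)

    def to_frame(self, reference: str | None = None) -> pd.DataFrame:
        """Tabular report: totals, ICER vs reference, sequential ICER, class."""
        rows = []
        ref = self.results.get(reference) if reference else None
        for name, res in self.results.items():
            icer_vs_ref = math.nan
            if ref is not None and name != reference:
                icer_vs_ref = icer(res, ref).value
            rows.append(
                {
                    "arm": name,
                    "cost": res.cost,
                    "qaly": res.qaly,
                    "ly": res.ly,
                    "icer_vs_reference": icer_vs_ref,
                    "sequential_icer": self.sequential_icers.get(name, math.nan),
                    "classification": self.classifications[name],
                }
            )
        return pd.DataFrame(rows).sort_values("cost").reset_index(drop=True)


def build_frontier(results: list[CEResult]) -> FrontierResult:
    """Strict- and extended-dominance analysis of a set of strategies.

    Exact-tie pairs (equal cost and equal QALYs) keep the first arm by input
    order; the duplicate is classified as dominated.
    """
    if not results:
        raise ValueError("need at least one result")
    names = [r.arm for r in results]
    if len(set(names)) != len(names):
        raise ValueError("arm names must be unique")

    classifications: dict[str, str] = {}
    # strict (weak) dominance, with the first-by-input tie rule
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            if i == j:
                continue
            if b.cost == a.cost and b.qaly == a.qaly:
                if j < i:  # a is the later duplicate
                    classifications[a.arm] = DOMINATED
                    break
                continue
            if b.cost <= a.cost and b.qaly >= a.qaly:
                classifications[a.arm] = DOMINATED
                break

    survivors = [r for r in results if r.arm not in classifications]
    survivors.sort(key=lambda r: (r.cost, r.qaly))

    # extended dominance: drop arms until sequential ICERs are increasing.
    # The violation test is strict, so exactly-collinear points (for which no
    # convex combination offers a strict improvement) stay on the frontier.
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            left = icer(survivors[i], survivors[i - 1]).value
            right = icer(survivors[i + 1], survivors[i]).value
            if left > right:
                classifications[survivors[i].arm] = EXTENDED_DOMINATED
                del survivors[i]
                changed = True
                break

    sequential: dict[str, float] = {}
    for i in range(1, len(survivors)):
        sequential[survivors[i].arm] = icer(survivors[i], survivors[i - 1]).value
    for r in survivors:
        classifications[r.arm] = ON_FRONTIER

    return FrontierResult(
        classifications={r.arm: classifications[r.arm] for r in results},
        frontier=[r.arm for r in survivors],
        sequential_icers=sequential,
        results={r.arm: r for r in results},
    )
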