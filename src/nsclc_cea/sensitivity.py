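"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the deterministic model with a single parameter at
its low and high bound and reports the ICER of a named comparison at each;
the tornado builder ranks parameters by the width of that ICER swing.
Scenario analyses apply documented override sets (updated osimertinib OS
data, alternative health-state utilities, UK list prices, osimertinib as
second-line therapy for T790M-positive patients) and re-run the base case.

The probabilistic analysis is a second-order Monte Carlo simulation: every
uncertain parameter is drawn from its distribution (gamma for costs,
lognormal for hazard ratios, beta for utilities and probabilities, uniform
for the discount rate; the reference Weibull scale/shape pairs are drawn
jointly on the log scale through their stored Cholesky factor), the cohort
model is re-run per draw, and cost-effectiveness acceptability curves
report, per willingness-to-pay threshold, the fraction of iterations in
which each strategy attains the maximum net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CEResult, accrue, build_trace, run_all
from .params import (
    ModelInputs,
    ParamValue,
    DistributionSpec,
    get_param,
    iter_dsa_params,
    iter_params,
    set_param_base,
)

__all__ = [
    "PSASample",
    "CEACCurve",
    "one_way",
    "tornado",
    "SCENARIOS",
    "scenario_inputs",
    "run_scenario",
    "sample_params",
    "run_psa",
    "psa_to_frame",
    "ceac",
]


# --------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# --------------------------------------------------------------------------


def _pair_icer(inputs: ModelInputs, comparison: tuple[str, str]) -> float:
    """Forced ICER value of comparison[0] vs comparison[1] (model re-run)."""
    res = {}
    for name in comparison:
        arm = inputs.arm(name)
        res[name] = accrue(build_trace(arm, inputs), arm, inputs)
    dc = res[comparison[0]].cost - res[comparison[1]].cost
    dq = res[comparison[0]].qaly - res[comparison[1]].qaly
    return dc / dq if dq != 0 else float("nan")


def one_way(
    inputs: ModelInputs, param_id: str, comparison: tuple[str, str]
) -> tuple[float, float]:
    """ICER of the comparison with one parameter at its low, then high bound."""
    pv = get_param(inputs, param_id)  # raises KeyError on unknown ids
    out = []
    for bound in (pv.low, pv.high):
        modified = inputs.copy()
        set_param_base(modified, param_id, bound)
        out.append(_pair_icer(modified, comparison))
    return out[0], out[1]


def tornado(
    inputs: ModelInputs,
    comparison: tuple[str, str],
    param_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One-way analysis over many parameters, sorted by ICER swing.

    The default set covers every scalar parameter with a published range;
    the reference Weibull scale/shape pairs are excluded because they are
    correlated, jointly-sampled curve parameters for which independent
    one-at-a-time variation is not meaningful — pass their ids
    (``pfs_ref.scale`` etc., see :func:`iter_dsa_params`) explicitly to
    include them anyway.
    """
    if param_ids is None:
        param_ids = [p for p, _ in iter_params(inputs)]
    rows = []
    for pid in param_ids:
        low_icer, high_icer = one_way(inputs, pid, comparison)
        rows.append(
            {
                "param": pid,
                "low_icer": low_icer,
                "high_icer": high_icer,
                "swing": abs(high_icer - low_icer),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("swing", ascending=False).reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# scenario analyses
# --------------------------------------------------------------------------

#: Scenario constants not printed in the main source tables are documented
#: stand-ins (see docs/methods.md) and can be edited here or overridden by
#: rebuilding the returned inputs.
FLAURA_UPDATED_OS_HR = 0.60
ALT_UTILITIES = {"UK": {"u_pf": 0.653, "u_pd": 0.473}, "China": {"u_pf": 0.804, "u_pd": 0.473}}
T790M_UPTAKE = 0.60
OSI_SECOND_LINE_WEEKS = 44  # ~10 months of second-line osimertinib
#: approximate BNF list prices per week, replacing eMIT procurement prices
BNF_PRICE_OVERRIDES_UK = {
    "oral": {"gefitinib": 506.0, "erlotinib": 381.0,
             "gefitinib_pemetrexed": 506.0, "gefitinib_pbct": 506.0,
             "erlotinib_bevacizumab": 381.0},
    "infusion": {"pbct": 560.0, "pfct": 60.0,
                 "gefitinib_pemetrexed": 533.0, "gefitinib_pbct": 560.0},
    "second_line": {"pem_platinum_per_week": 540.0, "docetaxel_per_week": 35.0},
}

_EARLY_GEN_TKI_ARMS = (
    "gefitinib",
    "erlotinib",
    "afatinib",
    "dacomitinib",
    "icotinib",
    "afatinib_cetuximab",
    "erlotinib_bevacizumab",
)


def _rescale_param(pv: ParamValue, new_base: float) -> None:
    """Move a parameter to a new base, keeping its relative range and CV."""
    ratio = new_base / pv.base if pv.base != 0 else 1.0
    pv.low, pv.base, pv.high = pv.low * ratio, new_base, pv.high * ratio
    if pv.dist.family == "gamma":
        pv.dist = DistributionSpec(
            "gamma",
            {"shape": pv.dist.params["shape"], "scale": pv.dist.params["scale"] * ratio},
        )
    elif pv.dist.family == "lognormal":
        pv.dist = DistributionSpec(
            "lognormal",
            {"mu": float(np.log(new_base)), "sigma": pv.dist.params["sigma"]},
        )
    elif pv.dist.family == "beta":
        a, b = pv.dist.params["alpha"], pv.dist.params["beta"]
        total = a + b  # keep the effective sample size, move the mean
        pv.dist = DistributionSpec(
            "beta", {"alpha": new_base * total, "beta": (1.0 - new_base) * total}
        )


def _scenario_base_case(inputs: ModelInputs) -> ModelInputs:
    return inputs.copy()


def _scenario_flaura(inputs: ModelInputs) -> ModelInputs:
    out = inputs.copy()
    _rescale_param(out.arm("osimertinib").hrs.os_hr, FLAURA_UPDATED_OS_HR)
    return out


def _scenario_alt_utilities(inputs: ModelInputs) -> ModelInputs:
    out = inputs.copy()
    for key, val in ALT_UTILITIES[out.country].items():
        _rescale_param(out.utilities[key], val)
    return out


def _scenario_bnf_prices(inputs: ModelInputs) -> ModelInputs:
    if inputs.country != "UK":
        raise ValueError("BNF price scenario applies to the UK setting only")
    out = inputs.copy()
    for name, price in BNF_PRICE_OVERRIDES_UK["oral"].items():
        _rescale_param(out.arm(name).schedule.oral_cost_per_week, price)
    for name, price in BNF_PRICE_OVERRIDES_UK["infusion"].items():
        _rescale_param(out.arm(name).schedule.infusion_cost_per_week, price)
    for key, price in BNF_PRICE_OVERRIDES_UK["second_line"].items():
        _rescale_param(out.second_line_costs[key], price)
    return out


def _scenario_t790m(inputs: ModelInputs) -> ModelInputs:
    out = inputs.copy()
    osi_weekly = out.arm("osimertinib").schedule.oral_cost_per_week.base
    osi_weekly += out.admin_costs["tki_per_week"].base
    pbct_weekly = (
        out.arm("pbct").schedule.infusion_cost_per_week.base
        + out.admin_costs["infusion_per_week"].base
    )
    override = {}
    for name in _EARLY_GEN_TKI_ARMS:
        if name not in [a.name for a in out.arms]:
            continue
        override[name] = [
            (T790M_UPTAKE, [(osi_weekly, OSI_SECOND_LINE_WEEKS)]),
            (1.0 - T790M_UPTAKE, [(pbct_weekly, 12)]),
        ]
    out.metadata = dict(out.metadata)
    out.metadata["pd_pathway_override"] = override
    return out


SCENARIOS = {
    "base_case": _scenario_base_case,
    "flaura_os_update": _scenario_flaura,
    "alt_utilities": _scenario_alt_utilities,
    "bnf_prices_uk": _scenario_bnf_prices,
    "t790m_osimertinib_second_line": _scenario_t790m,
}


def scenario_inputs(inputs: ModelInputs, scenario_id: str) -> ModelInputs:
    """Return a copy of the inputs with the scenario's overrides applied."""
    if scenario_id not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; registered: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[scenario_id](inputs)


def run_scenario(inputs: ModelInputs, scenario_id: str) -> list[CEResult]:
    """Apply a registered override set and re-run all arms."""
    return run_all(scenario_inputs(inputs, scenario_id))


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------


def sample_params(
    inputs: ModelInputs, rng_seed: int | np.random.Generator
) -> ModelInputs:
    """One joint parameter draw: a new :class:`ModelInputs` for a PSA iteration.

    Scalar parameters are drawn independently from their distributions; each
    reference Weibull (scale, shape) pair is drawn jointly on the log scale
    via its Cholesky factor.  The life table is held fixed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out = inputs.copy()
    for _, pv in iter_params(out):
        pv.base = pv.sample(rng)
    out.pfs_ref = out.pfs_ref.sample(rng)
    out.os_ref = out.os_ref.sample(rng)
    return out


@dataclass
class PSASample:
    """One PSA iteration: per-arm discounted (cost, QALY)."""

    iteration: int
    seed: int
    results: dict[str, tuple[float, float]]


def run_psa(inputs: ModelInputs, n: int, seed: int) -> list[PSASample]:
    """Second-order Monte Carlo: ``n`` sampled-parameter model runs.

    Bitwise reproducible for a fixed master seed; each iteration's substream
    seed is recorded in the sample for replay.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=n)
    samples = []
    for i, s in enumerate(iter_seeds):
        drawn = sample_params(inputs, int(s))
        results = {r.arm: (r.cost, r.qaly) for r in run_all(drawn)}
        samples.append(PSASample(iteration=i, seed=int(s), results=results))
    return samples


def psa_to_frame(samples: list[PSASample]) -> pd.DataFrame:
    rows = [
        {"iteration": s.iteration, "seed": s.seed, "arm": arm, "cost": c, "qaly": q}
        for s in samples
        for arm, (c, q) in s.results.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class CEACCurve:
    """Probability of each arm being cost-effective across WTP thresholds."""

    thresholds: np.ndarray
    probabilities: pd.DataFrame  # index: threshold, columns: arm

    def to_long_frame(self) -> pd.DataFrame:
        return (
            self.probabilities.reset_index(names="threshold")
            .melt(id_vars="threshold", var_name="arm", value_name="probability")
        )


def ceac(samples: list[PSASample], thresholds) -> CEACCurve:
    """Fraction of iterations in which each arm has maximal net monetary
    benefit, per threshold; exact ties split equally."""
    if not samples:
        raise ValueError("no PSA samples supplied")
    thresholds = np.asarray(thresholds, dtype=float)
    arms = list(samples[0].results)
    cost = np.array([[s.results[a][0] for a in arms] for s in samples])
    qaly = np.array([[s.results[a][1] for a in arms] for s in samples])
    probs = np.zeros((len(thresholds), len(arms)))
    for ti, wtp in enumerate(thresholds):
        benefit = wtp * qaly - cost  # (n_samples, n_arms)
        best = benefit.max(axis=1, keepdims=True)
        winners = benefit >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        probs[ti] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(
        thresholds=thresholds,
        probabilities=pd.DataFrame(probs, index=thresholds, columns=arms),
    )
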