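"""Synthetic-data generators for every structure the pipeline consumes.

These generators stand in for inputs that cannot be shipped: reconstructed
pseudo-patient-level survival data (right-censored Weibull event times),
national all-cause life tables (Gompertz-Makeham law), random cost-QALY
planes for stress-testing the frontier algorithm, and fully randomized but
valid model-input sets for end-to-end regression tests.  All generators are
bitwise reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .markov import CEResult
from .params import (
    DistributionSpec,
    HazardRatioPair,
    LifeTable,
    ModelInputs,
    ParamValue,
    RegimenSchedule,
    SAEProfile,
    TreatmentArm,
    WeibullParams,
)
from .survival import SurvivalDataset, weibull_survival

__all__ = [
    "SyntheticSpec",
    "gen_censored_weibull",
    "gen_life_table",
    "gen_ce_plane",
    "gen_inputs",
]


@dataclass
class SyntheticSpec:
    """Configuration for the survival-data generator."""

    seed: int = 0
    n_patients: int = 1000
    weibull: WeibullParams = None
    censoring_fraction: float = 0.2
    n_arms: int = 12

    def __post_init__(self) -> None:
        if self.weibull is None:
            self.weibull = WeibullParams(scale=0.0474, shape=1.5590)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring fraction must be in [0, 1)")


def _censoring_tmax(par: WeibullParams, target: float) -> float:
    """Upper bound of the uniform censoring window hitting the target
    expected censoring fraction: P(censored) = (1/tmax) * int_0^tmax S(t) dt."""

    def frac(tmax: float) -> float:
        grid = np.linspace(0.0, tmax, 4096)
        return float(np.trapezoid(weibull_survival(par, grid), grid)) / tmax

    # frac is decreasing in tmax from 1 to 0; bracket and solve
    hi = 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket censoring window")
    return brentq(lambda x: frac(x) - target, hi / 2.0, hi, xtol=1e-6 * hi)


def gen_censored_weibull(spec: SyntheticSpec) -> SurvivalDataset:
    """Right-censored Weibull event times (months), uniform censoring."""
    rng = np.random.default_rng(spec.seed)
    par = spec.weibull
    u = rng.uniform(size=spec.n_patients)
    event_times = (-np.log(u) / par.scale) ** (1.0 / par.shape)
    if spec.censoring_fraction == 0.0:
        return SurvivalDataset(event_times, np.ones(spec.n_patients, dtype=int))
    tmax = _censoring_tmax(par, spec.censoring_fraction)
    censor_times = rng.uniform(0.0, tmax, size=spec.n_patients)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    times = np.maximum(times, 1e-9)  # guard against an exact-zero draw
    return SurvivalDataset(times, events)


def gen_life_table(
    a: float = 5e-4,
    b: float = 0.09,
    c: float = 3.31e-5,
    ages=range(40, 101),
) -> LifeTable:
    """Gompertz-Makeham life table: q(age) = 1 - exp(-(a + c*exp(b*age))).

    Defaults give q(71) ~= 0.02, a plausible general-population mortality at
    the UK cohort's start age.  Out-of-range hazards are clipped into [0,1].
    """
    if a < 0 or c < 0 or b <= 0:
        raise ValueError("require a, c >= 0 and b > 0")
    ages = np.asarray(list(ages), dtype=int)
    q = 1.0 - np.exp(-(a + c * np.exp(b * ages)))
    clipped = np.clip(q, 0.0, 1.0)
    table = LifeTable(ages, clipped)
    if np.any(q != clipped):
        import warnings

        warnings.warn("life-table hazard clipped into [0,1]", stacklevel=2)
    return table


def gen_ce_plane(
    n_arms: int,
    seed: int,
    cost_range: tuple[float, float] = (5_000.0, 160_000.0),
    qaly_range: tuple[float, float] = (0.5, 2.5),
) -> list[CEResult]:
    """Random cost/QALY pairs for frontier stress tests."""
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    rng = np.random.default_rng(seed)
    costs = rng.uniform(*cost_range, size=n_arms)
    qalys = rng.uniform(*qaly_range, size=n_arms)
    return [
        CEResult(arm=f"arm_{i}", cost=float(c), qaly=float(q))
        for i, (c, q) in enumerate(zip(costs, qalys))
    ]


def _pv(base: float, cv: float = 0.1) -> ParamValue:
    """Gamma-distributed cost parameter with the table's fixed-CV style."""
    shape = 1.0 / cv**2
    return ParamValue(
        base=base,
        dist=DistributionSpec("gamma", {"shape": shape, "scale": base / shape}),
    )


def _pv_beta(base: float, ess: float = 200.0) -> ParamValue:
    return ParamValue(
        base=base,
        dist=DistributionSpec(
            "beta", {"alpha": base * ess, "beta": (1.0 - base) * ess}
        ),
    )


def _pv_hr(base: float, sigma: float = 0.12) -> ParamValue:
    return ParamValue(
        base=base,
        low=base * 0.8,
        high=base * 1.25,
        dist=DistributionSpec("lognormal", {"mu": float(np.log(base)), "sigma": sigma}),
    )


def gen_inputs(
    seed: int, n_arms: int = 4, horizon_weeks: int = 1043
) -> ModelInputs:
    """A complete, valid, randomized model-input set with known truth values.

    Arm 0 is the reference chemotherapy (4-cycle infusion schedule); the
    others are oral regimens with randomized hazard ratios, costs and SAE
    profiles.  Useful for end-to-end tests where the packaged country
    fixtures would be overkill or where ground truth must be controlled.
    """
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    rng = np.random.default_rng(seed)
    arms = [
        TreatmentArm(
            name="reference_chemo",
            schedule=RegimenSchedule(
                infusion_cost_per_week=_pv(float(rng.uniform(20, 500))),
                infusion_weeks_max=12,
                admin_cost_class="infusion",
            ),
            sae=SAEProfile(
                {"neutropenia": float(rng.uniform(0.1, 0.4)),
                 "nausea_vomiting": float(rng.uniform(0.05, 0.3))}
            ),
            second_line_pathway="docetaxel_only",
        )
    ]
    for i in range(1, n_arms):
        arms.append(
            TreatmentArm(
                name=f"tki_{i}",
                schedule=RegimenSchedule(
                    oral_cost_per_week=_pv(float(rng.uniform(50, 1500))),
                    admin_cost_class="tki_only",
                ),
                sae=SAEProfile(
                    {"rash": float(rng.uniform(0.0, 0.2)),
                     "diarrhoea": float(rng.uniform(0.0, 0.1))}
                ),
                second_line_pathway="pem_platinum_then_docetaxel",
                hrs=HazardRatioPair(
                    pfs_hr=_pv_hr(float(rng.uniform(0.15, 0.7))),
                    os_hr=_pv_hr(float(rng.uniform(0.6, 1.1))),
                ),
            )
        )
    return ModelInputs(
        country="UK",
        arms=arms,
        reference_arm="reference_chemo",
        pfs_ref=WeibullParams.from_ranges(
            0.0474, 1.5590, (0.0359, 0.0625), (1.4404, 1.6874)
        ),
        os_ref=WeibullParams.from_ranges(
            0.0075, 1.3601, (0.0049, 0.0114), (1.2449, 1.4860)
        ),
        utilities={
            "u_pf": _pv_beta(float(rng.uniform(0.7, 0.9))),
            "u_pd": _pv_beta(float(rng.uniform(0.15, 0.5))),
        },
        sae_costs={
            e: _pv(float(rng.uniform(50, 5000)))
            for e in ("neutropenia", "nausea_vomiting", "rash", "diarrhoea")
        },
        sae_disutilities={
            e: _pv_beta(float(rng.uniform(0.02, 0.1)))
            for e in ("neutropenia", "nausea_vomiting", "rash", "diarrhoea")
        },
        management_costs={
            "pf_per_week": _pv(float(rng.uniform(20, 80))),
            "pd_per_week": _pv(float(rng.uniform(20, 80))),
            "bsc_per_week": _pv(float(rng.uniform(50, 150))),
            "terminal_one_off": _pv(float(rng.uniform(1500, 6000))),
        },
        admin_costs={
            "tki_per_week": _pv(3.0),
            "infusion_per_week": _pv(float(rng.uniform(10, 120))),
        },
        second_line_costs={
            "pem_platinum_per_week": _pv(float(rng.uniform(100, 500))),
            "docetaxel_per_week": _pv(float(rng.uniform(5, 100))),
        },
        second_line_uptake=float(rng.uniform(0.4, 0.8)),
        start_age=float(rng.uniform(60, 75)),
        discount_rate_annual=ParamValue(
            base=0.035,
            low=0.0,
            high=0.06,
            dist=DistributionSpec("uniform", {"low": 0.0, "high": 0.06}),
        ),
        wtp_low=20000.0,
        wtp_high=50000.0,
        life_table=gen_life_table(),
        horizon_weeks=horizon_weeks,
    )
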