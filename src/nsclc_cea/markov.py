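"""Weekly-cycle three-state cohort model with cost and QALY accrual.

States are progression-free (PF), progressed disease (PD) and death.  The
cohort trace is derived from the arm's PFS and OS Weibull curves: PF
occupancy tracks the PFS curve, total deaths track 1 - S_OS, the PF->dead
transition is floored at the age-specific background mortality from the
life table, and the PD->dead probability is calibrated each cycle so that
cumulative deaths match the OS curve (clipped to [0,1]; clipping above 5%
of cycles is recorded as a trace warning).

Accrual per cycle: acquisition and administration costs while on treatment
in PF (oral components until progression, infusion components for at most
four 3-week cycles unless given until progression), state management costs
by occupancy, second-line pathway costs by time since progression for the
uptake fraction (and best supportive care for the remainder and after
active lines end), a one-off terminal-care cost per new death, and one-off
incidence-weighted SAE costs and QALY decrements at model entry.  Costs and
QALYs are discounted weekly at the annual rate r via (1+r)^(-k/52.18).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    SAE_EVENTS,
    WEEK_IN_MONTHS,
    WEEKS_PER_YEAR,
    ModelInputs,
    ParamValue,
    SAEProfile,
    TreatmentArm,
)
from .survival import apply_hazard_ratio, weibull_survival

__all__ = ["CohortTrace", "CEResult", "build_trace", "accrue", "sae_burden", "run_all"]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one arm (start-of-cycle convention)."""

    arm: str
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray  # deaths occurring during cycle k
    pd_entries: np.ndarray  # PF->PD transitions during cycle k
    pd_death_prob: np.ndarray  # calibrated PD->dead probability in cycle k
    ages: np.ndarray
    clip_fraction: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pf)

    def occupancy_ok(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.pf + self.pd + self.dead - 1.0) <= tol))


@dataclass
class CEResult:
    """Discounted totals for one arm."""

    arm: str
    cost: float
    qaly: float
    ly: float = 0.0
    sae_qaly_loss: float = 0.0  # stored as a non-positive bookkeeping entry
    sae_cost: float = 0.0


def _arm_curves(arm: TreatmentArm, inputs: ModelInputs):
    if arm.hrs is None:
        return inputs.pfs_ref, inputs.os_ref
    return (
        apply_hazard_ratio(inputs.pfs_ref, arm.hrs.pfs_hr.base),
        apply_hazard_ratio(inputs.os_ref, arm.hrs.os_hr.base),
    )


def build_trace(
    arm: TreatmentArm,
    inputs: ModelInputs,
    background_mortality: bool = True,
) -> CohortTrace:
    """Run the weekly state-transition model for one arm to the horizon.

    ``background_mortality=False`` disables the life-table floor on the
    PF->dead transition (used for validation against the bare OS curve).
    """
    if arm.name not in [a.name for a in inputs.arms]:
        raise ValueError(f"arm {arm.name!r} does not belong to these inputs")
    K = inputs.horizon_weeks
    pfs_par, os_par = _arm_curves(arm, inputs)

    t = np.arange(K + 1) * WEEK_IN_MONTHS  # months at cycle boundaries
    # exact conditional exit probability from the PFS curve, cycle by cycle
    dH = pfs_par.scale * np.diff(t**pfs_par.shape)
    p_pfs_exit = -np.expm1(-dH)
    s_os = weibull_survival(os_par, t)

    ages = inputs.start_age + np.arange(K) / WEEKS_PER_YEAR
    if background_mortality:
        idx = np.clip(
            np.searchsorted(inputs.life_table.ages, np.floor(ages).astype(int), side="right") - 1,
            0,
            len(inputs.life_table.ages) - 1,
        )
        if np.floor(ages[0]) < inputs.life_table.ages[0]:
            raise ValueError("cohort start age below life-table minimum")
        q_annual = inputs.life_table.qx[idx]
        q_week = 1.0 - (1.0 - q_annual) ** (1.0 / WEEKS_PER_YEAR)
    else:
        q_week = np.zeros(K)

    pf = np.empty(K)
    pd_ = np.empty(K)
    dead = np.empty(K)
    new_deaths = np.empty(K)
    pd_entries = np.empty(K)
    pd_death_prob = np.empty(K)

    pf_k, pd_k, dead_k = 1.0, 0.0, 0.0
    clips = 0
    for k in range(K):
        pf[k], pd_[k], dead[k] = pf_k, pd_k, dead_k
        p_exit = max(p_pfs_exit[k], q_week[k])
        d_pf = pf_k * q_week[k]
        to_pd = pf_k * p_exit - d_pf
        target_dead = 1.0 - s_os[k + 1]
        need = target_dead - dead_k - d_pf
        pd_dead = min(max(need, 0.0), pd_k)
        if need < -1e-12 or need > pd_k + 1e-12:
            clips += 1
        pd_death_prob[k] = pd_dead / pd_k if pd_k > 0 else 0.0
        pd_entries[k] = to_pd
        new_deaths[k] = d_pf + pd_dead
        pf_k = pf_k * (1.0 - p_exit)
        pd_k = pd_k + to_pd - pd_dead
        dead_k = dead_k + d_pf + pd_dead

    trace = CohortTrace(
        arm=arm.name,
        pf=pf,
        pd=pd_,
        dead=dead,
        new_deaths=new_deaths,
        pd_entries=pd_entries,
        pd_death_prob=pd_death_prob,
        ages=ages,
        clip_fraction=clips / K,
    )
    if trace.clip_fraction > 0.05:
        trace.warnings.append(
            f"PD mortality calibration clipped on {trace.clip_fraction:.1%} of cycles"
        )
    return trace


def sae_burden(
    profile: SAEProfile,
    costs: dict[str, ParamValue],
    disutilities: dict[str, ParamValue],
) -> tuple[float, float]:
    """Incidence-weighted one-off SAE cost and QALY loss (both >= 0)."""
    cost = 0.0
    qaly_loss = 0.0
    for event, inc in profile.incidence.items():
        if inc == 0.0:
            continue
        if event not in costs:
            raise KeyError(f"no SAE management cost for event {event!r}")
        if event not in disutilities:
            raise KeyError(f"no SAE disutility for event {event!r}")
        cost += inc * costs[event].base
        qaly_loss += inc * disutilities[event].base
    return cost, qaly_loss


# --- second-line pathway costing -------------------------------------------

#: weeks of active treatment per line: four 3-week chemotherapy cycles
_LINE_WEEKS = 12


def _default_pathway_phases(arm: TreatmentArm, inputs: ModelInputs):
    """Post-progression treatment mix: list of (fraction, [(weekly_cost, weeks)]).

    After the listed phases end, best supportive care applies until death.
    """
    adm = inputs.admin_costs["infusion_per_week"].base
    sl = inputs.second_line_costs
    if arm.second_line_pathway == "pem_platinum_then_docetaxel":
        phases = [
            (sl["pem_platinum_per_week"].base + adm, _LINE_WEEKS),
            (sl["docetaxel_per_week"].base + adm, _LINE_WEEKS),
        ]
    else:  # docetaxel_only
        phases = [(sl["docetaxel_per_week"].base + adm, _LINE_WEEKS)]
    return [(1.0, phases)]


def _pd_extra_unit_costs(arm: TreatmentArm, inputs: ModelInputs, K: int) -> np.ndarray:
    """Expected per-week cost in excess of BSC, by PD tenure (weeks since
    progression), for the second-line-uptake fraction of the cohort.

    Best supportive care applies to everyone in PD outside an active
    treatment phase, so the tenure profile is BSC plus a short-lived "extra"
    term during the active second/third-line phases; only that extra part is
    returned (truncated at its last non-zero week).  Scenario analyses may
    override the pathway mix through
    ``inputs.metadata['pd_pathway_override'][arm]``.
    """
    bsc = inputs.management_costs["bsc_per_week"].base
    uptake = inputs.second_line_uptake
    mixes = inputs.metadata.get("pd_pathway_override", {}).get(arm.name)
    if mixes is None:
        mixes = _default_pathway_phases(arm, inputs)
    extra = np.zeros(K)
    last = 0
    for frac, phases in mixes:
        tau = 0
        for weekly_cost, weeks in phases:
            hi = min(tau + weeks, K)
            extra[tau:hi] += uptake * frac * (weekly_cost - bsc)
            tau = hi
        last = max(last, tau)
    return extra[:last]


def _second_line_costs_per_cycle(
    trace: CohortTrace, extra: np.ndarray, bsc: float
) -> np.ndarray:
    """Convolve PD entry cohorts with the tenure cost profile.

    Entrants during cycle j are present in PD from cycle j+1 with tenure
    k-j-1 at cycle k, and survive within PD with the calibrated per-cycle
    PD death probability (shared across tenures).  The constant-BSC part of
    the profile sums to BSC times PD occupancy exactly; only the short
    active-phase excess needs the convolution, which keeps the accrual
    O(K * phase_length).
    """
    K = len(trace)
    logg = np.log(np.clip(1.0 - trace.pd_death_prob, 1e-300, 1.0))
    L = np.concatenate([[0.0], np.cumsum(logg)])  # L[k] = sum_{m<k} log g_m
    cost = bsc * trace.pd
    for tau, delta in enumerate(extra):
        if delta == 0.0:
            continue
        # entrants during cycle k-tau-1, surviving PD cycles k-tau .. k-1
        k = np.arange(tau + 1, K)
        cost[k] += delta * trace.pd_entries[k - tau - 1] * np.exp(L[k] - L[k - tau])
    return cost


def accrue(trace: CohortTrace, arm: TreatmentArm, inputs: ModelInputs) -> CEResult:
    """Accumulate discounted costs, QALYs and LYs over a cohort trace."""
    if trace.arm != arm.name:
        raise ValueError("trace was built for a different arm")
    K = len(trace)
    r = inputs.discount_rate_annual.base
    disc = (1.0 + r) ** (-np.arange(K) / WEEKS_PER_YEAR)

    u_pf = inputs.utilities["u_pf"].base
    u_pd = inputs.utilities["u_pd"].base
    qaly_inc = (u_pf * trace.pf + u_pd * trace.pd) / WEEKS_PER_YEAR
    ly_inc = (trace.pf + trace.pd) / WEEKS_PER_YEAR

    mgmt = inputs.management_costs
    for key in ("pf_per_week", "pd_per_week", "bsc_per_week", "terminal_one_off"):
        if key not in mgmt:
            raise KeyError(f"management_costs missing {key!r}")

    sched = arm.schedule
    pf_weekly = 0.0
    if sched.oral_cost_per_week is not None:
        pf_weekly += sched.oral_cost_per_week.base
        pf_weekly += inputs.admin_costs["tki_per_week"].base
    cost_inc = pf_weekly * trace.pf
    if sched.infusion_cost_per_week is not None:
        active = np.ones(K, dtype=bool)
        if not sched.infusion_until_progression:
            active = np.arange(K) < sched.infusion_weeks_max
        inf_weekly = (
            sched.infusion_cost_per_week.base
            + inputs.admin_costs["infusion_per_week"].base
        )
        cost_inc = cost_inc + inf_weekly * trace.pf * active

    cost_inc = cost_inc + mgmt["pf_per_week"].base * trace.pf
    cost_inc = cost_inc + mgmt["pd_per_week"].base * trace.pd
    extra = _pd_extra_unit_costs(arm, inputs, K)
    cost_inc = cost_inc + _second_line_costs_per_cycle(
        trace, extra, mgmt["bsc_per_week"].base
    )
    cost_inc = cost_inc + mgmt["terminal_one_off"].base * trace.new_deaths

    sae_cost, sae_loss = sae_burden(arm.sae, inputs.sae_costs, inputs.sae_disutilities)

    return CEResult(
        arm=arm.name,
        cost=float(disc @ cost_inc + sae_cost),
        qaly=float(disc @ qaly_inc - sae_loss),
        ly=float(disc @ ly_inc),
        sae_qaly_loss=-sae_loss,
        sae_cost=sae_cost,
    )


def run_all(inputs: ModelInputs, background_mortality: bool = True) -> list[CEResult]:
    """Deterministic base-case run: one :class:`CEResult` per arm."""
    out = []
    for arm in inputs.arms:
        trace = build_trace(arm, inputs, background_mortality=background_mortality)
        out.append(accrue(trace, arm, inputs))
    return out
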