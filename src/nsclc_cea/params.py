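"""Domain types and validated loading of model parameter sets.

The model compares first-line strategies for advanced EGFR-mutated NSCLC in a
three-state (progression-free / progressed / dead) weekly-cycle cohort model.
A complete country-specific parameter set (:class:`ModelInputs`) bundles:

* reference-arm Weibull survival parameters for PFS and OS, with a Cholesky
  factor of the covariance of their logs for probabilistic sampling;
* one :class:`TreatmentArm` per strategy: regimen schedule, PFS/OS hazard
  ratios versus the reference chemotherapy, a grade-3/4 serious-adverse-event
  (SAE) incidence profile, and the subsequent-treatment pathway;
* costs (acquisition, administration, disease management, best supportive
  care, terminal care, SAE management), health-state utilities and SAE
  disutilities, the annual discount rate, and an all-cause life table.

Every uncertain quantity is a :class:`ParamValue`: a base-case value, a
deterministic low/high range, and a sampling distribution for probabilistic
sensitivity analysis.  At load time each distribution's central value is
audited against the base value so transcription errors in the parameter
files are caught early.

Parameter files are YAML (see ``data/uk.yaml`` / ``data/china.yaml`` for the
packaged UK and China sets); life tables are two-column CSV
(age, annual_mortality_probability).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SAE_EVENTS",
    "WEEKS_PER_YEAR",
    "WEEK_IN_MONTHS",
    "CNY_PER_GBP",
    "InputValidationError",
    "DistributionSpec",
    "ParamValue",
    "WeibullParams",
    "HazardRatioPair",
    "SAEProfile",
    "RegimenSchedule",
    "TreatmentArm",
    "LifeTable",
    "ModelInputs",
    "central_value",
    "load_inputs",
    "load_packaged_inputs",
    "write_inputs",
    "iter_params",
    "get_param",
    "set_param_base",
]

#: grade-3/4 serious adverse events tracked by the model
SAE_EVENTS = (
    "neutropenia",
    "hypertension",
    "rash",
    "anaemia",
    "diarrhoea",
    "leukopenia",
    "thrombocytopenia",
    "dermatitis",
    "fatigue",
    "nausea_vomiting",
    "hair_loss",
    "febrile_neutropenia",
)

WEEKS_PER_YEAR = 365.25 / 7.0  # 52.18 weeks
WEEK_IN_MONTHS = 7.0 / 30.4375  # one weekly cycle expressed in months

#: currency conversion constant of the source prices (metadata only; all
#: inputs are stored in 2019 GBP)
CNY_PER_GBP = 8.78

SECOND_LINE_PATHWAYS = ("pem_platinum_then_docetaxel", "docetaxel_only")
ADMIN_COST_CLASSES = ("tki_only", "infusion")


class InputValidationError(ValueError):
    """A parameter file violated the schema or a transcription check."""


# --------------------------------------------------------------------------
# distributions and parameter values
# --------------------------------------------------------------------------

_FAMILIES = ("gamma", "lognormal", "beta", "normal", "uniform", "fixed", "cholesky_mvn")
_PARAM_NAMES = {
    "gamma": ("shape", "scale"),
    "lognormal": ("mu", "sigma"),
    "beta": ("alpha", "beta"),
    "normal": ("mean", "sd"),
    "uniform": ("low", "high"),
    "fixed": (),
    "cholesky_mvn": (),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A named sampling distribution with family-specific parameters.

    Lognormal parameters are on the natural-log scale (``mu``, ``sigma``);
    gamma uses (``shape``, ``scale``).  ``fixed`` marks degenerate
    parameters; ``cholesky_mvn`` marks parameters sampled jointly elsewhere
    (the Weibull scale/shape pairs).
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InputValidationError(f"unknown distribution family {self.family!r}")
        expected = _PARAM_NAMES[self.family]
        missing = [k for k in expected if k not in self.params]
        if missing:
            raise InputValidationError(
                f"{self.family} distribution missing parameters {missing}"
            )
        p = self.params
        if self.family == "gamma" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise InputValidationError("gamma requires shape>0 and scale>0")
        if self.family == "beta" and (p["alpha"] <= 0 or p["beta"] <= 0):
            raise InputValidationError("beta requires alpha>0 and beta>0")
        if self.family == "lognormal" and p["sigma"] < 0:
            raise InputValidationError("lognormal requires sigma>=0")
        if self.family == "normal" and p["sd"] < 0:
            raise InputValidationError("normal requires sd>=0")
        if self.family == "uniform" and p["low"] > p["high"]:
            raise InputValidationError("uniform requires low<=high")

    def central_value(self) -> float:
        """Mean for gamma/beta/normal, median for lognormal, midpoint for uniform."""
        p = self.params
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "lognormal":
            return math.exp(p["mu"])
        if self.family == "normal":
            return p["mean"]
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        raise ValueError(f"no central value defined for family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.family == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "normal":
            return float(rng.normal(p["mean"], p["sd"]))
        if self.family == "uniform":
            return float(rng.uniform(p["low"], p["high"]))
        raise ValueError(f"cannot sample from family {self.family!r}")


def central_value(dist: DistributionSpec) -> float:
    """Module-level alias for :meth:`DistributionSpec.central_value`."""
    return dist.central_value()


def _printed_unit(x: float) -> float:
    """Resolution of the printed source value (1 for 66, 0.001 for 0.883)."""
    for d in range(7):
        if abs(x - round(x, d)) < 1e-9:
            return 10.0 ** (-d)
    return 1e-6


@dataclass
class ParamValue:
    """Base-case value with a deterministic range and a PSA distribution.

    ``low``/``high`` default to base ± 20% when the source gives no range.
    For gamma/beta/normal/lognormal distributions the distribution's central
    value must agree with ``base`` (transcription audit); the tolerance is
    2% or one unit of the printed resolution, whichever is larger.
    """

    base: float
    low: float | None = None
    high: float | None = None
    dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("fixed")
    )

    def __post_init__(self) -> None:
        if self.low is None:
            self.low = self.base - 0.2 * abs(self.base)
        if self.high is None:
            self.high = self.base + 0.2 * abs(self.base)
        if not (self.low <= self.base <= self.high):
            raise InputValidationError(
                f"require low <= base <= high, got ({self.low}, {self.base}, {self.high})"
            )

    def check_transcription(self, name: str = "parameter") -> None:
        """Audit ``dist``'s central value against ``base``."""
        if self.dist.family in ("fixed", "cholesky_mvn", "uniform"):
            return
        central = self.dist.central_value()
        tol = max(0.02 * abs(self.base), _printed_unit(self.base))
        if abs(central - self.base) > tol:
            raise InputValidationError(
                f"{name}: distribution central value {central:.6g} does not match "
                f"base {self.base:.6g} (tolerance {tol:.3g})"
            )

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist.family == "fixed":
            return self.base
        return self.dist.sample(rng)


# --------------------------------------------------------------------------
# survival / clinical types
# --------------------------------------------------------------------------


@dataclass
class WeibullParams:
    """Parameters of the survival curve S(t) = exp(-scale * t**shape).

    Time is measured in months.  ``log_chol`` is the lower-triangular
    Cholesky factor of the covariance of (ln scale, ln shape), used for
    joint probabilistic sampling; ``scale_range``/``shape_range`` hold the
    printed 95% intervals used for deterministic sensitivity analysis.
    """

    scale: float
    shape: float
    log_chol: np.ndarray | None = None
    scale_range: tuple[float, float] | None = None
    shape_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise InputValidationError("Weibull scale and shape must be positive")
        if self.log_chol is not None:
            L = np.asarray(self.log_chol, dtype=float)
            if L.shape != (2, 2) or L[0, 1] != 0:
                raise InputValidationError("log_chol must be 2x2 lower-triangular")
            if L[0, 0] < 0 or L[1, 1] < 0:
                raise InputValidationError("log_chol diagonal must be non-negative")
            self.log_chol = L

    @classmethod
    def from_ranges(
        cls,
        scale: float,
        shape: float,
        scale_range: tuple[float, float],
        shape_range: tuple[float, float],
        log_corr: float = -0.5,
    ) -> "WeibullParams":
        """Build the log-space Cholesky factor from printed 95% intervals.

        Marginal SDs of (ln scale, ln shape) are back-solved so that a
        lognormal marginal reproduces the printed interval; ``log_corr`` is
        the assumed correlation between the two (Weibull fits typically show
        a negative scale/shape correlation).
        """
        s1 = math.log(scale_range[1] / scale_range[0]) / (2 * 1.959964)
        s2 = math.log(shape_range[1] / shape_range[0]) / (2 * 1.959964)
        L = np.array(
            [[s1, 0.0], [log_corr * s2, s2 * math.sqrt(1.0 - log_corr**2)]]
        )
        return cls(scale, shape, log_chol=L, scale_range=tuple(scale_range),
                   shape_range=tuple(shape_range))

    def sample(self, rng: np.random.Generator) -> "WeibullParams":
        """Joint lognormal draw of (scale, shape); identity if no factor stored."""
        if self.log_chol is None:
            return replace(self)
        z = rng.standard_normal(2)
        logs = np.array([math.log(self.scale), math.log(self.shape)]) + self.log_chol @ z
        return replace(self, scale=float(np.exp(logs[0])), shape=float(np.exp(logs[1])))


@dataclass
class HazardRatioPair:
    """PFS and OS hazard ratios of an arm versus the reference chemotherapy."""

    pfs_hr: ParamValue
    os_hr: ParamValue

    def __post_init__(self) -> None:
        if self.pfs_hr.base <= 0 or self.os_hr.base <= 0:
            raise InputValidationError("hazard ratios must be positive")


@dataclass
class SAEProfile:
    """Per-event incidence proportions of grade-3/4 serious adverse events."""

    incidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for event, p in self.incidence.items():
            if event not in SAE_EVENTS:
                raise InputValidationError(f"unknown SAE event {event!r}")
            if not 0.0 <= p <= 1.0:
                raise InputValidationError(
                    f"SAE incidence for {event} must be in [0,1], got {p}"
                )

    def get(self, event: str) -> float:
        return self.incidence.get(event, 0.0)


@dataclass
class RegimenSchedule:
    """Acquisition-cost structure of a first-line regimen.

    Oral components (the EGFR-TKIs) accrue per week until progression or
    death.  Infusion components accrue per week while active: chemotherapy
    components for at most ``infusion_weeks_max`` weeks (12 weeks = four
    3-week cycles), monoclonal-antibody components until progression.
    """

    oral_cost_per_week: ParamValue | None = None
    infusion_cost_per_week: ParamValue | None = None
    infusion_weeks_max: int = 0
    infusion_until_progression: bool = False
    admin_cost_class: str = "tki_only"

    def __post_init__(self) -> None:
        if self.infusion_weeks_max < 0:
            raise InputValidationError("infusion_weeks_max must be >= 0")
        if self.admin_cost_class not in ADMIN_COST_CLASSES:
            raise InputValidationError(
                f"admin_cost_class must be one of {ADMIN_COST_CLASSES}"
            )
        if self.oral_cost_per_week is None and self.infusion_cost_per_week is None:
            raise InputValidationError("schedule needs at least one cost component")


@dataclass
class TreatmentArm:
    """One first-line strategy: schedule, effectiveness, safety, pathway."""

    name: str
    schedule: RegimenSchedule
    sae: SAEProfile
    second_line_pathway: str
    hrs: HazardRatioPair | None = None  # absent for the reference arm

    def __post_init__(self) -> None:
        if self.second_line_pathway not in SECOND_LINE_PATHWAYS:
            raise InputValidationError(
                f"{self.name}: unknown second-line pathway "
                f"{self.second_line_pathway!r}"
            )


@dataclass
class LifeTable:
    """Annual all-cause mortality probability by integer age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.shape != self.qx.shape or self.ages.ndim != 1:
            raise InputValidationError("life table requires matching 1-d columns")
        if not np.all(np.diff(self.ages) > 0):
            raise InputValidationError("life-table ages must be strictly increasing")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise InputValidationError("mortality probabilities must be in [0,1]")

    def annual_q(self, age: float) -> float:
        """Annual mortality at ``age`` (clamped above the last row)."""
        if age < self.ages[0]:
            raise ValueError(f"age {age} below life-table minimum {self.ages[0]}")
        idx = np.searchsorted(self.ages, int(math.floor(age)), side="right") - 1
        return float(self.qx[idx])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        required = {"age", "annual_mortality_probability"}
        if not required.issubset(df.columns):
            raise InputValidationError(
                f"life table {path} must have columns {sorted(required)}"
            )
        return cls(df["age"].to_numpy(), df["annual_mortality_probability"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.ages, "annual_mortality_probability": self.qx}
        ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# full input set
# --------------------------------------------------------------------------


@dataclass
class ModelInputs:
    """Complete country-specific parameter set for the cohort model."""

    country: str
    arms: list[TreatmentArm]
    reference_arm: str
    pfs_ref: WeibullParams
    os_ref: WeibullParams
    utilities: dict[str, ParamValue]
    sae_costs: dict[str, ParamValue]
    sae_disutilities: dict[str, ParamValue]
    management_costs: dict[str, ParamValue]
    admin_costs: dict[str, ParamValue]
    second_line_costs: dict[str, ParamValue]
    second_line_uptake: float
    start_age: float
    discount_rate_annual: ParamValue
    wtp_low: float
    wtp_high: float
    life_table: LifeTable
    horizon_weeks: int = 1043
    extra_params: dict[str, ParamValue] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise InputValidationError("arm names must be unique")
        if self.reference_arm not in names:
            raise InputValidationError(
                f"reference arm {self.reference_arm!r} not among arms"
            )
        if not 0.0 <= self.second_line_uptake <= 1.0:
            raise InputValidationError("second_line_uptake must be in [0,1]")
        if not 0.0 <= self.discount_rate_annual.base <= 0.2:
            raise InputValidationError("discount rate base must be in [0, 0.2]")
        for key in ("u_pf", "u_pd"):
            if key not in self.utilities:
                raise InputValidationError(f"utilities missing {key!r}")
            if not 0.0 <= self.utilities[key].base <= 1.0:
                raise InputValidationError(f"{key} must be in [0,1]")
        for label, pv in iter_params(self):
            if ("cost" in label or "terminal" in label) and pv.base < 0:
                raise InputValidationError(f"{label}: costs must be >= 0")

    def arm(self, name: str) -> TreatmentArm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}")

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)

    def audit_transcription(self) -> None:
        for label, pv in iter_params(self):
            pv.check_transcription(label)


# --------------------------------------------------------------------------
# parameter traversal (used by DSA and PSA)
# --------------------------------------------------------------------------


def iter_params(inputs: ModelInputs) -> Iterator[tuple[str, ParamValue]]:
    """Yield (dotted path, ParamValue) for every uncertain scalar parameter."""
    yield "discount_rate_annual", inputs.discount_rate_annual
    for group in (
        "utilities",
        "management_costs",
        "admin_costs",
        "second_line_costs",
        "sae_costs",
        "sae_disutilities",
        "extra_params",
    ):
        for key, pv in getattr(inputs, group).items():
            yield f"{group}.{key}", pv
    for arm in inputs.arms:
        if arm.schedule.oral_cost_per_week is not None:
            yield f"arms[{arm.name}].schedule.oral_cost_per_week", arm.schedule.oral_cost_per_week
        if arm.schedule.infusion_cost_per_week is not None:
            yield f"arms[{arm.name}].schedule.infusion_cost_per_week", arm.schedule.infusion_cost_per_week
        if arm.hrs is not None:
            yield f"arms[{arm.name}].hrs.pfs_hr", arm.hrs.pfs_hr
            yield f"arms[{arm.name}].hrs.os_hr", arm.hrs.os_hr


_WEIBULL_PSEUDO = ("pfs_ref.scale", "pfs_ref.shape", "os_ref.scale", "os_ref.shape")


def iter_dsa_params(inputs: ModelInputs) -> Iterator[tuple[str, ParamValue]]:
    """Like :func:`iter_params` plus the reference Weibull scale/shape.

    The Weibull parameters carry a joint sampling distribution rather than a
    marginal one, so they are wrapped as fixed-distribution pseudo-parameters
    whose low/high come from the printed intervals.
    """
    yield from iter_params(inputs)
    for path in _WEIBULL_PSEUDO:
        ref = inputs.pfs_ref if path.startswith("pfs") else inputs.os_ref
        attr = path.split(".")[1]
        rng_ = ref.scale_range if attr == "scale" else ref.shape_range
        base = getattr(ref, attr)
        low, high = rng_ if rng_ is not None else (0.8 * base, 1.2 * base)
        yield path, ParamValue(base=base, low=low, high=high)


def get_param(inputs: ModelInputs, path: str) -> ParamValue:
    for label, pv in iter_dsa_params(inputs):
        if label == path:
            return pv
    raise KeyError(f"unknown parameter id {path!r}")


def set_param_base(inputs: ModelInputs, path: str, value: float) -> None:
    """Set the base-case value of the parameter addressed by ``path`` in place."""
    if path in _WEIBULL_PSEUDO:
        ref = inputs.pfs_ref if path.startswith("pfs") else inputs.os_ref
        setattr(ref, path.split(".")[1], float(value))
        return
    for label, pv in iter_params(inputs):
        if label == path:
            pv.base = float(value)
            return
    raise KeyError(f"unknown parameter id {path!r}")


# --------------------------------------------------------------------------
# YAML I/O
# --------------------------------------------------------------------------


def _parse_dist(node) -> DistributionSpec:
    if node is None:
        return DistributionSpec("fixed")
    if isinstance(node, str):
        return DistributionSpec(node)
    if isinstance(node, dict):
        family = node["family"]
        params = {k: float(v) for k, v in node.items() if k != "family"}
        return DistributionSpec(family, params)
    family, *vals = node
    names = _PARAM_NAMES.get(family)
    if names is None:
        raise InputValidationError(f"unknown distribution family {family!r}")
    if len(vals) != len(names):
        raise InputValidationError(
            f"{family} distribution expects {len(names)} parameters, got {len(vals)}"
        )
    return DistributionSpec(family, dict(zip(names, map(float, vals))))


def _parse_param(node, name: str) -> ParamValue:
    if isinstance(node, (int, float)):
        return ParamValue(base=float(node))
    try:
        base = float(node["base"])
    except (KeyError, TypeError) as exc:
        raise InputValidationError(f"{name}: expected a mapping with 'base'") from exc
    low = high = None
    if "range" in node and node["range"] is not None:
        low, high = (float(x) for x in node["range"])
    pv = ParamValue(base=base, low=low, high=high, dist=_parse_dist(node.get("dist")))
    pv.check_transcription(name)
    return pv


def _parse_param_map(node: dict, name: str) -> dict[str, ParamValue]:
    if node is None:
        return {}
    return {k: _parse_param(v, f"{name}.{k}") for k, v in node.items()}


def _parse_weibull(node: dict, name: str) -> WeibullParams:
    try:
        scale, shape = float(node["scale"]), float(node["shape"])
    except (KeyError, TypeError) as exc:
        raise InputValidationError(f"{name}: expected scale and shape") from exc
    if "scale_range" in node and "shape_range" in node:
        return WeibullParams.from_ranges(
            scale,
            shape,
            tuple(float(x) for x in node["scale_range"]),
            tuple(float(x) for x in node["shape_range"]),
            log_corr=float(node.get("log_corr", -0.5)),
        )
    return WeibullParams(scale, shape)


def _parse_arm(node: dict) -> TreatmentArm:
    name = node["name"]
    sched = node.get("schedule") or {}
    schedule = RegimenSchedule(
        oral_cost_per_week=(
            _parse_param(sched["oral_cost_per_week"], f"{name}.oral_cost_per_week")
            if "oral_cost_per_week" in sched
            else None
        ),
        infusion_cost_per_week=(
            _parse_param(
                sched["infusion_cost_per_week"], f"{name}.infusion_cost_per_week"
            )
            if "infusion_cost_per_week" in sched
            else None
        ),
        infusion_weeks_max=int(sched.get("infusion_weeks_max", 0)),
        infusion_until_progression=bool(sched.get("infusion_until_progression", False)),
        admin_cost_class=sched.get("admin_cost_class", "tki_only"),
    )
    hrs = None
    if node.get("hrs") is not None:
        hrs = HazardRatioPair(
            pfs_hr=_parse_param(node["hrs"]["pfs_hr"], f"{name}.pfs_hr"),
            os_hr=_parse_param(node["hrs"]["os_hr"], f"{name}.os_hr"),
        )
    sae = SAEProfile({k: float(v) for k, v in (node.get("sae") or {}).items()})
    return TreatmentArm(
        name=name,
        schedule=schedule,
        sae=sae,
        second_line_pathway=node.get("second_line_pathway", "docetaxel_only"),
        hrs=hrs,
    )


def load_inputs(path: str | Path, country: str | None = None) -> ModelInputs:
    """Load and validate a :class:`ModelInputs` from a YAML parameter file.

    ``country``, if given, must match the file's own country field (guards
    against passing the wrong fixture).  Raises
    :class:`InputValidationError` naming the offending field on schema or
    transcription-check failures.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if country is not None and doc.get("country", "").lower() != country.lower():
        raise InputValidationError(
            f"requested country {country!r} but file declares {doc.get('country')!r}"
        )
    try:
        life_table = LifeTable.from_csv(path.parent / doc["life_table"])
        inputs = ModelInputs(
            country=doc["country"],
            arms=[_parse_arm(a) for a in doc["arms"]],
            reference_arm=doc["reference_arm"],
            pfs_ref=_parse_weibull(doc["pfs_reference_weibull"], "pfs_reference_weibull"),
            os_ref=_parse_weibull(doc["os_reference_weibull"], "os_reference_weibull"),
            utilities=_parse_param_map(doc["utilities"], "utilities"),
            sae_costs=_parse_param_map(doc["sae_costs"], "sae_costs"),
            sae_disutilities=_parse_param_map(
                doc["sae_disutilities"], "sae_disutilities"
            ),
            management_costs=_parse_param_map(
                doc["management_costs"], "management_costs"
            ),
            admin_costs=_parse_param_map(doc["admin_costs"], "admin_costs"),
            second_line_costs=_parse_param_map(
                doc["second_line_costs"], "second_line_costs"
            ),
            second_line_uptake=float(doc["second_line_uptake"]),
            start_age=float(doc["start_age"]),
            discount_rate_annual=_parse_param(
                doc["discount_rate_annual"], "discount_rate_annual"
            ),
            wtp_low=float(doc["wtp_low"]),
            wtp_high=float(doc["wtp_high"]),
            life_table=life_table,
            horizon_weeks=int(doc.get("horizon_weeks", 1043)),
            extra_params=_parse_param_map(doc.get("extra_params"), "extra_params"),
            metadata={
                k: doc[k]
                for k in ("currency", "price_year", "cny_per_gbp")
                if k in doc
            },
        )
    except KeyError as exc:
        raise InputValidationError(f"parameter file missing field {exc}") from exc
    return inputs


def load_packaged_inputs(country: str) -> ModelInputs:
    """Load the packaged UK or China parameter set."""
    key = country.strip().lower()
    if key not in ("uk", "china"):
        raise ValueError("country must be 'UK' or 'China'")
    data_dir = resources.files("nsclc_cea").joinpath("data")
    with resources.as_file(data_dir.joinpath(f"{key}.yaml")) as p:
        return load_inputs(p)


# ---- writing ----


def _dump_dist(dist: DistributionSpec):
    if dist.family in ("fixed", "cholesky_mvn"):
        return dist.family
    return [dist.family] + [dist.params[k] for k in _PARAM_NAMES[dist.family]]


def _dump_param(pv: ParamValue):
    return {
        "base": pv.base,
        "range": [pv.low, pv.high],
        "dist": _dump_dist(pv.dist),
    }


def _dump_weibull(w: WeibullParams):
    out = {"scale": w.scale, "shape": w.shape}
    if w.scale_range is not None:
        out["scale_range"] = list(w.scale_range)
        out["shape_range"] = list(w.shape_range)
    if w.log_chol is not None and w.scale_range is not None:
        # recover the correlation used to build the factor
        L = w.log_chol
        norm = math.hypot(L[1, 0], L[1, 1])
        out["log_corr"] = float(L[1, 0] / norm) if norm > 0 else 0.0
    return out


def write_inputs(inputs: ModelInputs, path: str | Path) -> None:
    """Write a :class:`ModelInputs` back to YAML (+ life-table CSV alongside)."""
    path = Path(path)
    lt_name = f"{path.stem}_life_table.csv"
    inputs.life_table.to_csv(path.parent / lt_name)
    doc = {
        "country": inputs.country,
        **inputs.metadata,
        "start_age": inputs.start_age,
        "horizon_weeks": inputs.horizon_weeks,
        "second_line_uptake": inputs.second_line_uptake,
        "wtp_low": inputs.wtp_low,
        "wtp_high": inputs.wtp_high,
        "discount_rate_annual": _dump_param(inputs.discount_rate_annual),
        "life_table": lt_name,
        "reference_arm": inputs.reference_arm,
        "pfs_reference_weibull": _dump_weibull(inputs.pfs_ref),
        "os_reference_weibull": _dump_weibull(inputs.os_ref),
        "utilities": {k: _dump_param(v) for k, v in inputs.utilities.items()},
        "management_costs": {
            k: _dump_param(v) for k, v in inputs.management_costs.items()
        },
        "admin_costs": {k: _dump_param(v) for k, v in inputs.admin_costs.items()},
        "second_line_costs": {
            k: _dump_param(v) for k, v in inputs.second_line_costs.items()
        },
        "sae_costs": {k: _dump_param(v) for k, v in inputs.sae_costs.items()},
        "sae_disutilities": {
            k: _dump_param(v) for k, v in inputs.sae_disutilities.items()
        },
        "extra_params": {k: _dump_param(v) for k, v in inputs.extra_params.items()},
        "arms": [],
    }
    for arm in inputs.arms:
        node = {
            "name": arm.name,
            "second_line_pathway": arm.second_line_pathway,
            "schedule": {"admin_cost_class": arm.schedule.admin_cost_class},
            "sae": dict(arm.sae.incidence),
        }
        sched = node["schedule"]
        if arm.schedule.oral_cost_per_week is not None:
            sched["oral_cost_per_week"] = _dump_param(arm.schedule.oral_cost_per_week)
        if arm.schedule.infusion_cost_per_week is not None:
            sched["infusion_cost_per_week"] = _dump_param(
                arm.schedule.infusion_cost_per_week
            )
            sched["infusion_weeks_max"] = arm.schedule.infusion_weeks_max
            sched["infusion_until_progression"] = arm.schedule.infusion_until_progression
        if arm.hrs is not None:
            node["hrs"] = {
                "pfs_hr": _dump_param(arm.hrs.pfs_hr),
                "os_hr": _dump_param(arm.hrs.os_hr),
            }
        doc["arms"].append(node)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
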