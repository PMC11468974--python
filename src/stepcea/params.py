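"""Parameter schema, validation and per-parameter uncertainty distributions.

A :class:`ParameterSet` is a complete instantiation of the cohort model:
demography (age bands and their population fractions), epidemiology
(baseline disease and PA prevalence, age-specific incidence, complication
incidence and all-cause mortality), relative risks by PA level, state
utilities, unit costs, program economics, and one
:class:`DistributionSpec` per uncertain parameter for the probabilistic
and one-way sensitivity analyses.

Uncertain parameters are addressed by dotted paths into the parameter set
(e.g. ``rr_incidence.diabetes.low``, ``cost_inpatient.diabetes_cvd``,
``program_cost_annual``), which is how the sensitivity-analysis machinery
reads and writes them.
"""

from __future__ import annotations

import math
from typing import Literal, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .states import COMPLICATION_PARENT, COMPLICATIONS, DISEASES, PA_GROUPS, PA_LEVELS

_LEVELS = tuple(l.value for l in PA_LEVELS)
_SUM_TOL = 1e-9


class SchemaError(ValueError):
    """A configuration violates the parameter schema or its invariants."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AgeBand(_StrictModel):
    """Closed age interval ``[lower, upper]`` (``upper`` omitted for the open top band)."""

    label: str
    lower: int = Field(ge=17)
    upper: int | None = None
    fraction: float = Field(ge=0.0, le=1.0)

    @property
    def width(self) -> float:
        return math.inf if self.upper is None else self.upper - self.lower + 1

    @model_validator(mode="after")
    def _ordered(self) -> "AgeBand":
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"age band {self.label}: upper < lower")
        return self


class CohortSpec(_StrictModel):
    """Closed-cohort size: registrants scaled by the completion fraction."""

    n_registered: float = Field(gt=0)
    completion_fraction: float = Field(ge=0.0, le=1.0)

    @property
    def size(self) -> float:
        return self.n_registered * self.completion_fraction


class DistributionSpec(_StrictModel):
    """Sampling distribution and one-way range rule for one uncertain parameter.

    ``range_rule`` selects the bounds used by the one-way deterministic
    sensitivity analysis: ``ci95`` takes the 2.5/97.5 quantiles of the
    distribution, ``iqr`` the 25/75 quantiles, ``pm30`` the base value
    scaled by 0.7 and 1.3. ``psa_exclude`` keeps a parameter (the time
    horizon) out of the probabilistic analysis while still giving it a
    one-way range.
    """

    family: Literal["beta", "gamma", "lognormal", "uniform", "degenerate"]
    parameters: dict[str, float]
    range_rule: Literal["ci95", "iqr", "pm30"] = "ci95"
    psa_exclude: bool = False

    _REQUIRED = {
        "beta": ("alpha", "beta"),
        "gamma": ("shape", "scale"),
        "lognormal": ("mu", "sigma"),
        "uniform": ("low", "high"),
        "degenerate": ("value",),
    }

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        req = self._REQUIRED[self.family]
        missing = [k for k in req if k not in self.parameters]
        if missing:
            raise ValueError(f"{self.family} distribution missing parameters {missing}")
        p = self.parameters
        if self.family == "beta" and (p["alpha"] <= 0 or p["beta"] <= 0):
            raise ValueError("beta distribution requires alpha, beta > 0")
        if self.family == "gamma" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise ValueError("gamma distribution requires shape, scale > 0")
        if self.family == "lognormal" and p["sigma"] <= 0:
            raise ValueError("lognormal distribution requires sigma > 0")
        if self.family == "uniform" and p["low"] >= p["high"]:
            raise ValueError("uniform distribution requires low < high")
        return self

    @property
    def is_degenerate(self) -> bool:
        return self.family == "degenerate"

    def _frozen(self):
        p = self.parameters
        if self.family == "beta":
            return stats.beta(p["alpha"], p["beta"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "uniform":
            return stats.uniform(p["low"], p["high"] - p["low"])
        raise AssertionError(self.family)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.is_degenerate:
            return np.full(n, self.parameters["value"])
        return np.asarray(self._frozen().rvs(size=n, random_state=rng), dtype=float)

    def ppf(self, q: float) -> float:
        if self.is_degenerate:
            return self.parameters["value"]
        return float(self._frozen().ppf(q))

    def mean(self) -> float:
        if self.is_degenerate:
            return self.parameters["value"]
        return float(self._frozen().mean())


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Beta spec by method of moments; requires 0 < mean < 1 and feasible sd."""
    if not 0.0 < mean < 1.0:
        raise SchemaError(f"beta mean must be in (0,1), got {mean}")
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise SchemaError("sd too large for a beta distribution with this mean")
    return DistributionSpec(
        family="beta", parameters={"alpha": mean * nu, "beta": (1 - mean) * nu}
    )


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    if mean <= 0 or sd <= 0:
        raise SchemaError("gamma mean and sd must be positive")
    return DistributionSpec(
        family="gamma",
        parameters={"shape": (mean / sd) ** 2, "scale": sd**2 / mean},
    )


def lognormal_from_median_sigma(median: float, sigma: float) -> DistributionSpec:
    if median <= 0:
        raise SchemaError("lognormal median must be positive")
    return DistributionSpec(
        family="lognormal", parameters={"mu": math.log(median), "sigma": sigma}
    )


def _check_level_map(name: str, m: dict[str, float], lo=0.0, hi=None) -> None:
    if set(m) != set(_LEVELS):
        raise ValueError(f"{name}: keys must be exactly {_LEVELS}, got {sorted(m)}")
    for k, v in m.items():
        if v < lo or (hi is not None and v > hi):
            raise ValueError(f"{name}.{k} = {v} outside [{lo}, {hi}]")


class ParameterSet(_StrictModel):
    """Everything the model needs for one deterministic evaluation.

    Rates are annual (events per person-year); costs are SGD per person-year
    except ``program_cost_annual`` which is SGD per year for the whole
    program; utilities are on the 0 (dead) to 1 (perfect health) scale.
    """

    age_bands: list[AgeBand]
    cohort: CohortSpec
    pa_prevalence: dict[str, dict[str, float]]
    disease_prevalence: dict[str, dict[str, float]]
    incidence: dict[str, dict[str, float]]
    complication_incidence: dict[str, dict[str, float]]
    mortality: dict[str, float]
    rr_incidence: dict[str, dict[str, float]]
    rr_mortality: dict[str, Union[dict[str, float], float]]
    utilities: dict[str, Union[dict[str, float], float]]
    cost_inpatient: dict[str, float]
    cost_outpatient: dict[str, float]
    inpatient_proportion: dict[str, float]
    pa_cost_multiplier: dict[str, float] = Field(
        default_factory=lambda: {l: 1.0 for l in _LEVELS}
    )
    direct_indirect_ratio: dict[str, float]
    program_cost_annual: float = Field(ge=0)
    compliance: float = Field(ge=0.0, le=1.0)
    intervention_pa_shift: list[list[float]]
    control_pa_shift: list[list[float]]
    discount_rate: float = Field(ge=0.0)
    horizon_years: int = Field(ge=1)
    cycle_length: float = 1.0
    discounting: Literal["end_of_cycle", "mid_cycle"] = "end_of_cycle"
    wtp_grid: list[float] = Field(default_factory=lambda: [0.0, 5000.0, 10000.0])
    distributions: dict[str, DistributionSpec] = Field(default_factory=dict)

    # -- validation -------------------------------------------------------

    @model_validator(mode="after")
    def _invariants(self) -> "ParameterSet":
        try:
            self._check_invariants()
        except ValueError as e:
            raise ValueError(str(e)) from e
        return self

    def _check_invariants(self) -> None:
        if not self.age_bands:
            raise ValueError("age_bands: at least one band required")
        labels = [b.label for b in self.age_bands]
        if len(set(labels)) != len(labels):
            raise ValueError("age_bands: duplicate labels")
        total = sum(b.fraction for b in self.age_bands)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"age_bands: fractions sum to {total}, expected 1")
        for i in range(len(self.age_bands) - 1):
            if self.age_bands[i].upper is None:
                raise ValueError("age_bands: only the last band may be open-ended")
            if self.age_bands[i + 1].lower != self.age_bands[i].upper + 1:
                raise ValueError("age_bands: bands must be contiguous and ascending")

        if set(self.pa_prevalence) != set(PA_GROUPS):
            raise ValueError(f"pa_prevalence: keys must be {PA_GROUPS}")
        for g, m in self.pa_prevalence.items():
            _check_level_map(f"pa_prevalence.{g}", m, 0.0, 1.0)
            s = sum(m.values())
            if abs(s - 1.0) > _SUM_TOL:
                raise ValueError(f"pa_prevalence.{g}: sums to {s}, expected 1")

        band_set = set(labels)
        for field in ("disease_prevalence", "incidence", "complication_incidence"):
            table = getattr(self, field)
            if set(table) != band_set:
                raise ValueError(f"{field}: keys must match age band labels")
        if set(self.mortality) != band_set:
            raise ValueError("mortality: keys must match age band labels")

        for lbl, m in self.disease_prevalence.items():
            extra = set(m) - set(PA_GROUPS) - set(COMPLICATIONS)
            if extra:
                raise ValueError(f"disease_prevalence.{lbl}: unknown groups {sorted(extra)}")
        for lbl in labels:
            m = self.disease_prevalence[lbl]
            for g in PA_GROUPS:
                if g not in m:
                    raise ValueError(f"disease_prevalence.{lbl}: missing group {g}")
            vals = list(m.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ValueError(f"disease_prevalence.{lbl}: fractions outside [0,1]")
            s = sum(vals)
            if abs(s - 1.0) > _SUM_TOL:
                raise ValueError(f"disease_prevalence.{lbl}: sums to {s}, expected 1")
            for d in DISEASES:
                if self.incidence[lbl].get(d, -1.0) < 0:
                    raise ValueError(f"incidence.{lbl}.{d}: missing or negative")
                if self.complication_incidence[lbl].get(d, -1.0) < 0:
                    raise ValueError(f"complication_incidence.{lbl}.{d}: missing or negative")
            if self.mortality[lbl] < 0:
                raise ValueError(f"mortality.{lbl}: negative rate")

        if set(self.rr_incidence) != set(DISEASES):
            raise ValueError(f"rr_incidence: keys must be {DISEASES}")
        for d, m in self.rr_incidence.items():
            _check_level_map(f"rr_incidence.{d}", m, 0.0)
            if m["inactive"] != 1.0:
                raise ValueError(f"rr_incidence.{d}.inactive must be exactly 1")

        if set(self.rr_mortality) != set(PA_GROUPS) | set(COMPLICATIONS):
            raise ValueError("rr_mortality: keys must be the living groups plus complications")
        for g in PA_GROUPS:
            m = self.rr_mortality[g]
            if not isinstance(m, dict):
                raise ValueError(f"rr_mortality.{g}: must map PA level to relative risk")
            _check_level_map(f"rr_mortality.{g}", m, 0.0)
            if m["inactive"] != 1.0:
                raise ValueError(f"rr_mortality.{g}.inactive must be exactly 1")
        for c in COMPLICATIONS:
            v = self.rr_mortality[c]
            if not isinstance(v, (int, float)) or v < 0:
                raise ValueError(f"rr_mortality.{c}: must be a nonnegative multiplier")

        if set(self.utilities) != set(PA_GROUPS) | set(COMPLICATIONS):
            raise ValueError("utilities: keys must be the living groups plus complications")
        for g in PA_GROUPS:
            m = self.utilities[g]
            if not isinstance(m, dict):
                raise ValueError(f"utilities.{g}: must map PA level to utility")
            _check_level_map(f"utilities.{g}", m, 0.0, 1.0)
        for c, parent in COMPLICATION_PARENT.items():
            u = self.utilities[c]
            if not isinstance(u, (int, float)) or not 0.0 <= u <= 1.0:
                raise ValueError(f"utilities.{c}: must be a utility in [0,1]")
            if u > min(self.utilities[parent].values()) + _SUM_TOL:
                raise ValueError(
                    f"utilities.{c} exceeds its parent {parent} state utilities"
                )

        if set(self.cost_inpatient) != set(DISEASES) | set(COMPLICATIONS):
            raise ValueError("cost_inpatient: keys must be the disease and complication states")
        if set(self.cost_outpatient) != set(DISEASES):
            raise ValueError(f"cost_outpatient: keys must be {DISEASES}")
        if set(self.inpatient_proportion) != set(DISEASES):
            raise ValueError(f"inpatient_proportion: keys must be {DISEASES}")
        for name in ("cost_inpatient", "cost_outpatient"):
            for k, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}.{k}: negative cost")
        for k, v in self.inpatient_proportion.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"inpatient_proportion.{k} = {v} outside [0,1]")
        _check_level_map("pa_cost_multiplier", self.pa_cost_multiplier, 0.0)
        if set(self.direct_indirect_ratio) != set(DISEASES):
            raise ValueError(f"direct_indirect_ratio: keys must be {DISEASES}")
        for k, v in self.direct_indirect_ratio.items():
            if v <= 0:
                raise ValueError(f"direct_indirect_ratio.{k}: must be positive")

        for name in ("intervention_pa_shift", "control_pa_shift"):
            m = getattr(self, name)
            if len(m) != 3 or any(len(row) != 3 for row in m):
                raise ValueError(f"{name}: must be a 3x3 matrix (rows = from-level)")
            for i, row in enumerate(m):
                if any(p < 0 or p > 1 for p in row):
                    raise ValueError(f"{name}: row {i} has entries outside [0,1]")
                s = sum(row)
                if abs(s - 1.0) > _SUM_TOL:
                    raise ValueError(f"{name}: row {i} sums to {s}, expected 1")

        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if sorted(self.wtp_grid) != list(self.wtp_grid):
            raise ValueError("wtp_grid must be sorted ascending")

        for path in self.distributions:
            self.base_value(path)  # raises on unknown path

    # -- dotted-path access ----------------------------------------------

    def base_value(self, path: str) -> float:
        """Current value of the parameter addressed by ``path``."""
        node = self._navigate(path)
        obj, key = node
        val = obj[key] if isinstance(obj, dict) else getattr(obj, key)
        if not isinstance(val, (int, float)):
            raise SchemaError(f"parameter path {path!r} does not address a scalar")
        return float(val)

    def set_value(self, path: str, value: float) -> None:
        """Set the parameter addressed by ``path`` (no full revalidation)."""
        lo, hi = param_domain(path)
        if value < lo or value > hi:
            raise SchemaError(f"{path} = {value} outside domain [{lo}, {hi}]")
        obj, key = self._navigate(path)
        if key == "horizon_years":
            value = max(1, int(round(value)))
        if isinstance(obj, dict):
            obj[key] = value
        else:
            object.__setattr__(obj, key, value)

    def _navigate(self, path: str):
        parts = path.split(".")
        if not hasattr(self, parts[0]):
            raise SchemaError(f"unknown parameter path {path!r}")
        if len(parts) == 1:
            return self, parts[0]
        obj = getattr(self, parts[0])
        for p in parts[1:-1]:
            if not isinstance(obj, dict) or p not in obj:
                raise SchemaError(f"unknown parameter path {path!r}")
            obj = obj[p]
        if not isinstance(obj, dict) or parts[-1] not in obj:
            raise SchemaError(f"unknown parameter path {path!r}")
        return obj, parts[-1]

    # -- convenience ------------------------------------------------------

    @property
    def band_labels(self) -> list[str]:
        return [b.label for b in self.age_bands]

    def uncertain_parameters(self, include_psa_excluded: bool = True) -> list[str]:
        """Sorted paths of parameters with non-degenerate distributions."""
        return sorted(
            p
            for p, d in self.distributions.items()
            if not d.is_degenerate and (include_psa_excluded or not d.psa_exclude)
        )

    def copy_deep(self) -> "ParameterSet":
        return self.model_copy(deep=True)


def param_domain(path: str) -> tuple[float, float]:
    """Admissible closed domain for a dotted parameter path."""
    head = path.split(".")[0]
    if head in (
        "compliance",
        "inpatient_proportion",
        "utilities",
        "pa_prevalence",
        "disease_prevalence",
        "discount_rate",
    ):
        return (0.0, 1.0)
    if head in ("incidence", "complication_incidence", "mortality"):
        return (0.0, math.inf)
    if head in (
        "rr_incidence",
        "rr_mortality",
        "cost_inpatient",
        "cost_outpatient",
        "program_cost_annual",
        "direct_indirect_ratio",
        "pa_cost_multiplier",
    ):
        return (0.0, math.inf)
    if head == "horizon_years":
        return (1.0, math.inf)
    raise SchemaError(f"no domain rule for parameter path {path!r}")


def config_schema() -> dict:
    """Machine-readable (JSON-schema) description of the configuration format."""
    return ParameterSet.model_json_schema()
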