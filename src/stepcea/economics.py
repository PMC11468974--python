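"""Incremental cost-utility results: ICER, cost-saving rule, CEAC.

The incremental comparison is intervention minus comparator. The ICER is
``(program cost - health-care cost reduction) / QALYs gained``; the
intervention is *cost-saving* when it both gains QALYs and reduces
health-care costs by more than the program costs, in which case the ICER
is negative. Cost-effectiveness probabilities are computed from the net
monetary benefit ``wtp * dQALY - dCost > 0``, which coincides with the
proportion-of-ICERs-below-threshold rule whenever every sample gains
QALYs (the regime all base-case samples fall in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OutcomeSummary, run_situation
from .params import ParameterSet, SchemaError


class UndefinedICER:
    """Sentinel: zero QALYs gained, ICER undefined (fall back to net benefit)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UndefinedICER"


UNDEFINED_ICER = UndefinedICER()


def icer(program_cost: float, cost_reduction: float, qalys_gained: float):
    """Incremental cost-effectiveness ratio in SGD per QALY.

    Returns :data:`UNDEFINED_ICER` when no QALYs are gained; consumers
    should fall back to net-monetary-benefit logic in that case.
    """
    if qalys_gained == 0:
        return UNDEFINED_ICER
    return (program_cost - cost_reduction) / qalys_gained


def societal_cost(direct: dict[str, float], direct_indirect_ratio: dict[str, float]) -> float:
    """Total societal cost: direct plus indirect (= direct / ratio) per disease."""
    total = 0.0
    for d, c in direct.items():
        r = direct_indirect_ratio[d]
        if r <= 0:
            raise SchemaError(f"direct_indirect_ratio.{d} must be positive")
        total += c + c / r
    return total


def classify(qalys_gained: float, program_cost: float, cost_reduction: float) -> str:
    """Decision label for an incremental result.

    ``cost-saving`` — QALYs gained and net cost negative (ICER < 0);
    ``cost-effective?`` — QALYs gained at a positive net cost (compare the
    ICER with the willingness-to-pay); ``dominated`` — QALYs lost at a
    positive net cost; ``undefined`` — no QALY difference.
    """
    net_cost = program_cost - cost_reduction
    if qalys_gained > 0:
        return "cost-saving" if net_cost < 0 else "cost-effective?"
    if qalys_gained < 0:
        return "dominated" if net_cost > 0 else "less-effective-but-cheaper"
    return "undefined"


@dataclass
class IncrementalResult:
    """Intervention-minus-control contrasts over the whole horizon."""

    diabetes_averted: float
    hypertension_averted: float
    complications_averted: float
    deaths_averted: float
    qalys_gained: float
    healthcare_cost_reduction: float
    societal_cost_reduction: float
    program_cost: float

    def cost_reduction(self, perspective: str = "health_system") -> float:
        if perspective == "health_system":
            return self.healthcare_cost_reduction
        if perspective == "societal":
            return self.societal_cost_reduction
        raise ValueError(f"unknown perspective {perspective!r}")

    def icer(self, perspective: str = "health_system"):
        return icer(self.program_cost, self.cost_reduction(perspective), self.qalys_gained)

    def is_cost_saving(self, perspective: str = "health_system") -> bool:
        return (
            self.qalys_gained > 0
            and self.cost_reduction(perspective) > self.program_cost
        )

    def classification(self, perspective: str = "health_system") -> str:
        return classify(self.qalys_gained, self.program_cost, self.cost_reduction(perspective))

    def to_dict(self) -> dict[str, float]:
        d = {
            "diabetes_averted": self.diabetes_averted,
            "hypertension_averted": self.hypertension_averted,
            "complications_averted": self.complications_averted,
            "deaths_averted": self.deaths_averted,
            "qalys_gained": self.qalys_gained,
            "healthcare_cost_reduction": self.healthcare_cost_reduction,
            "societal_cost_reduction": self.societal_cost_reduction,
            "program_cost": self.program_cost,
        }
        ic = self.icer()
        d["icer_health_system"] = float("nan") if isinstance(ic, UndefinedICER) else ic
        return d


def incremental(intervention: OutcomeSummary, control: OutcomeSummary) -> IncrementalResult:
    """Contrast two completed situations (cases averted = control - intervention flows)."""
    ci, cc = intervention.cum_incident, control.cum_incident
    comp_i = ci.get("diabetes_cvd", 0.0) + ci.get("hypertension_stroke", 0.0)
    comp_c = cc.get("diabetes_cvd", 0.0) + cc.get("hypertension_stroke", 0.0)
    return IncrementalResult(
        diabetes_averted=cc["diabetes"] - ci["diabetes"],
        hypertension_averted=cc["hypertension"] - ci["hypertension"],
        complications_averted=comp_c - comp_i,
        deaths_averted=cc["deaths"] - ci["deaths"],
        qalys_gained=intervention.qalys - control.qalys,
        healthcare_cost_reduction=control.direct_cost - intervention.direct_cost,
        societal_cost_reduction=control.societal_cost - intervention.societal_cost,
        program_cost=intervention.program_cost,
    )


@dataclass
class Evaluation:
    """One deterministic model evaluation: both situations plus their contrast."""

    intervention: OutcomeSummary
    control: OutcomeSummary
    incremental: IncrementalResult


def evaluate(params: ParameterSet, n: float | None = None) -> Evaluation:
    """Run intervention and control situations and form the incremental result."""
    _, s_int = run_situation(params, "intervention", n)
    _, s_ctl = run_situation(params, "control", n)
    return Evaluation(intervention=s_int, control=s_ctl, incremental=incremental(s_int, s_ctl))


def ce_probability(
    delta_qalys: np.ndarray, delta_costs: np.ndarray, wtp: float
) -> float:
    """Fraction of samples cost-effective at ``wtp`` by net monetary benefit.

    ``delta_costs`` is the incremental cost (program cost minus cost
    reduction); a sample is cost-effective when
    ``wtp * dQALY - dCost > 0``.
    """
    dq = np.asarray(delta_qalys, dtype=float)
    dc = np.asarray(delta_costs, dtype=float)
    if dq.size == 0 or dq.shape != dc.shape:
        raise ValueError("delta_qalys and delta_costs must be equal-length, nonempty")
    return float(np.mean(wtp * dq - dc > 0))


def ceac(
    delta_qalys: np.ndarray, delta_costs: np.ndarray, wtp_grid
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over an ascending WTP grid."""
    grid = list(wtp_grid)
    if grid != sorted(grid):
        raise ValueError("wtp_grid must be sorted ascending")
    probs = [ce_probability(delta_qalys, delta_costs, w) for w in grid]
    return pd.DataFrame(
        {"wtp": grid, "probability": probs, "complement": [1.0 - p for p in probs]}
    )
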