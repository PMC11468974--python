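"""Uncertainty analyses: probabilistic SA, one-way tornado, threshold, scenario.

The probabilistic sensitivity analysis draws every non-degenerate,
non-excluded parameter independently from its distribution, re-runs the
full model (both situations) per draw, and summarizes the samples by
their mean and 2.5/97.5 percentile credible interval, plus the CEAC. Each
parameter gets its own random stream derived from the master seed and the
parameter's name, so adding or removing a parameter never perturbs the
draws of the others.

The one-way analysis moves each parameter alone to the bounds implied by
its range rule (95% CI, IQR, or +/-30%) and records the deterministic
ICER at both ends; the threshold analysis bisects a parameter until the
deterministic ICER crosses zero (break-even).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import UNDEFINED_ICER, Evaluation, ceac, evaluate
from .params import DistributionSpec, ParameterSet, SchemaError, param_domain
from .states import PA_LEVELS

logger = logging.getLogger(__name__)

PERSPECTIVES = ("health_system", "societal")


def _param_rng(master_seed: int, name: str) -> np.random.Generator:
    # one independent stream per parameter, order-invariant
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


@dataclass
class PSAResult:
    """Per-sample incremental outcomes with their PSA summary."""

    samples: pd.DataFrame  # one row per draw
    summary: pd.DataFrame  # index quantity, columns mean/p2.5/p97.5
    ceac: dict[str, pd.DataFrame]  # per perspective
    ce_probability: dict[str, dict[float, float]]  # perspective -> wtp -> prob
    seed: int
    n_samples: int


def run_psa(params: ParameterSet, n_samples: int, seed: int) -> PSAResult:
    """Monte-Carlo propagation of joint parameter uncertainty.

    All parameters with non-degenerate distributions are varied except
    those flagged ``psa_exclude`` (the time horizon). Reproducible:
    identical seeds give identical results.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    names = params.uncertain_parameters(include_psa_excluded=False)
    for name in names:
        params.distributions[name]  # presence guaranteed; validates eagerly on load
    draws = {
        name: params.distributions[name].sample(_param_rng(seed, name), n_samples)
        for name in names
    }

    rows = []
    for i in range(n_samples):
        ps = params.copy_deep()
        for name in names:
            ps.set_value(name, float(draws[name][i]))
        ev = evaluate(ps)
        row = ev.incremental.to_dict()
        row["intervention_qalys"] = ev.intervention.qalys
        row["control_qalys"] = ev.control.qalys
        row["intervention_direct_cost"] = ev.intervention.direct_cost
        row["control_direct_cost"] = ev.control.direct_cost
        rows.append(row)
    samples = pd.DataFrame(rows)

    qcols = [c for c in samples.columns]
    summary = pd.DataFrame(
        {
            "mean": samples[qcols].mean(),
            "p2.5": samples[qcols].quantile(0.025, interpolation="linear"),
            "p97.5": samples[qcols].quantile(0.975, interpolation="linear"),
        }
    )

    curves: dict[str, pd.DataFrame] = {}
    probs: dict[str, dict[float, float]] = {}
    dq = samples["qalys_gained"].to_numpy()
    for persp in PERSPECTIVES:
        red = (
            samples["healthcare_cost_reduction"]
            if persp == "health_system"
            else samples["societal_cost_reduction"]
        ).to_numpy()
        dc = samples["program_cost"].to_numpy() - red
        curve = ceac(dq, dc, params.wtp_grid)
        curves[persp] = curve
        probs[persp] = dict(zip(curve["wtp"], curve["probability"]))
    return PSAResult(
        samples=samples,
        summary=summary,
        ceac=curves,
        ce_probability=probs,
        seed=int(seed),
        n_samples=n_samples,
    )


@dataclass
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float
    clamped: bool = False

    @property
    def bar_width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def dsa_bounds(params: ParameterSet, name: str) -> tuple[float, float, bool]:
    """Low/high one-way bounds for a parameter, clamped to its domain.

    Returns ``(low, high, clamped)``; out-of-domain bounds are clamped
    with a logged warning rather than erroring.
    """
    spec = params.distributions[name]
    base = params.base_value(name)
    if spec.range_rule == "pm30":
        lo, hi = 0.7 * base, 1.3 * base
    elif spec.range_rule == "iqr":
        lo, hi = spec.ppf(0.25), spec.ppf(0.75)
    else:  # ci95
        lo, hi = spec.ppf(0.025), spec.ppf(0.975)
    dom_lo, dom_hi = param_domain(name)
    clo, chi = max(lo, dom_lo), min(hi, dom_hi)
    clamped = (clo, chi) != (lo, hi)
    if clamped:
        logger.warning(
            "one-way bounds for %s clamped from (%g, %g) to (%g, %g)", name, lo, hi, clo, chi
        )
    return clo, chi, clamped


def _icer_value(ev: Evaluation, perspective: str) -> float:
    ic = ev.incremental.icer(perspective)
    return float("nan") if ic is UNDEFINED_ICER else float(ic)


def _evaluate_at(params: ParameterSet, name: str, value: float) -> Evaluation:
    ps = params.copy_deep()
    ps.set_value(name, value)
    return evaluate(ps)


def one_way_dsa(
    params: ParameterSet,
    names: list[str] | None = None,
    perspective: str = "health_system",
) -> pd.DataFrame:
    """Tornado table: deterministic ICER at each parameter's low/high bound.

    All other parameters stay at base values; entries are sorted by
    descending bar width.
    """
    if names is None:
        names = params.uncertain_parameters(include_psa_excluded=True)
    entries = []
    for name in names:
        lo, hi, clamped = dsa_bounds(params, name)
        e_lo = _evaluate_at(params, name, lo)
        e_hi = _evaluate_at(params, name, hi)
        entries.append(
            TornadoEntry(
                parameter=name,
                low_value=lo,
                high_value=hi,
                icer_low=_icer_value(e_lo, perspective),
                icer_high=_icer_value(e_hi, perspective),
                clamped=clamped,
            )
        )
    entries.sort(key=lambda e: (-(e.bar_width if np.isfinite(e.bar_width) else np.inf), e.parameter))
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "bar_width": [e.bar_width for e in entries],
            "clamped": [e.clamped for e in entries],
        }
    )


@dataclass
class ThresholdResult:
    """Break-even value of one parameter (deterministic ICER = 0)."""

    parameter: str
    threshold: float
    direction: str  # "at_least" or "at_most" for cost-saving
    bracket: tuple[float, float]
    tolerance: float
    icer_at_threshold: float


def threshold_search(
    params: ParameterSet,
    name: str,
    bracket: tuple[float, float],
    tol: float | None = None,
    perspective: str = "health_system",
) -> ThresholdResult | None:
    """Bisection for the parameter value at which the ICER crosses zero.

    Returns ``None`` (a no-threshold signal, not an error) when the ICER
    has the same sign at both bracket ends. ``tol`` is the absolute
    bracket width to stop at; default 1e-6 of the initial width.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    if tol is None:
        tol = 1e-6 * (hi - lo)

    def f(x: float) -> float:
        ev = _evaluate_at(params, name, x)
        v = _icer_value(ev, perspective)
        if np.isnan(v):
            # no QALY difference: the decision rests on the net cost alone
            net = ev.incremental.program_cost - ev.incremental.cost_reduction(perspective)
            return math.copysign(math.inf, net) if net != 0 else 0.0
        return v

    f_lo, f_hi = f(lo), f(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    # cost-saving means ICER < 0: if the ICER decreases in the parameter,
    # saving requires the parameter to be at least the threshold
    direction = "at_least" if f_lo > 0 else "at_most"
    a, b, fa = lo, hi, f_lo
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = f(mid)
        if fm == 0.0:
            a = b = mid
            break
        if np.sign(fm) == np.sign(fa):
            a, fa = mid, fm
        else:
            b = mid
    root = 0.5 * (a + b)
    return ThresholdResult(
        parameter=name,
        threshold=root,
        direction=direction,
        bracket=(lo, hi),
        tolerance=tol,
        icer_at_threshold=_icer_value(_evaluate_at(params, name, root), perspective),
    )


def apply_cost_differentiation(params: ParameterSet, delta: float) -> ParameterSet:
    """Scenario: PA-differentiated treatment costs within each disease state.

    Inactive-level annual costs are inflated by ``delta`` and
    moderate-to-high-level costs deflated by ``delta``; the low level and
    the complication states are untouched. Returns a modified copy.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    ps = params.copy_deep()
    mult = dict(ps.pa_cost_multiplier)
    mult[PA_LEVELS[0].value] *= 1.0 + delta
    mult[PA_LEVELS[2].value] *= 1.0 - delta
    ps.pa_cost_multiplier = mult
    return ps
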