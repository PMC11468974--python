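"""Closed-cohort Markov trace and discounted outcome accumulation.

The cohort is distributed over (age band x state) cells. Each one-year
cycle applies the band-specific annual transition (PA shift, onset, death)
and then advances age: a fraction ``1 / band_width`` of every band's
occupancy moves to the next band, the deterministic expected flow of a
population aging one year inside multi-year bands.

Costs and QALYs are accumulated with half-cycle correction — each cycle's
person-years are the mean of state occupancy at its two boundaries — and
discounted at ``discount_rate`` per annum. The default convention indexes
cycle ``t``'s whole flow at the end of the cycle, factor ``(1+r)^-t``;
``discounting: mid_cycle`` uses ``(1+r)^-(t-1/2)`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet, SchemaError
from .states import (
    COMPLICATION_PARENT,
    COMPLICATIONS,
    DEAD,
    DISEASES,
    LIVING,
    N_STATES,
    PA_GROUPS,
    PA_LEVELS,
    STATE_LABELS,
    state_index,
)
from .transitions import build_all_transitions

_LEVELS = tuple(l.value for l in PA_LEVELS)

_HEALTHY_IDX = [state_index("healthy", l) for l in _LEVELS]
_DISEASE_IDX = {d: [state_index(d, l) for l in _LEVELS] for d in DISEASES}
_COMP_IDX = {c: state_index(c) for c in COMPLICATIONS}

INCIDENT_COLUMNS = ("diabetes", "hypertension", "diabetes_cvd", "hypertension_stroke", "deaths")


def estimate_cohort_size(n_registered: float, completion_fraction: float) -> float:
    """Closed-cohort size: registrants scaled by the tracker-completion fraction."""
    if n_registered < 0:
        raise ValueError("n_registered must be nonnegative")
    if not 0.0 <= completion_fraction <= 1.0:
        raise ValueError("completion_fraction must be in [0, 1]")
    return n_registered * completion_fraction


def initialize_cohort(params: ParameterSet, n: float) -> np.ndarray:
    """Initial occupancy, shape ``(n_bands, 12)``.

    ``n`` persons are spread over age bands by the census fractions, over
    disease groups by age-band prevalence and over PA levels by the
    baseline (pre-intervention) PA prevalence of each group. Complication
    states start at their (default zero) prevalence.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    bands = params.age_bands
    occ = np.zeros((len(bands), N_STATES))
    for b, band in enumerate(bands):
        prev = params.disease_prevalence[band.label]
        n_band = n * band.fraction
        for g in PA_GROUPS:
            for lvl in _LEVELS:
                occ[b, state_index(g, lvl)] = (
                    n_band * prev[g] * params.pa_prevalence[g][lvl]
                )
        for c in COMPLICATIONS:
            occ[b, _COMP_IDX[c]] = n_band * prev.get(c, 0.0)
    return occ


@dataclass
class CohortTrace:
    """State occupancy at every cycle boundary plus per-cycle incident flows."""

    occupancy: np.ndarray  # (T+1, n_bands, 12) persons
    incident: pd.DataFrame  # index cycle 1..T, columns INCIDENT_COLUMNS
    band_labels: list[str]
    situation: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def by_state(self) -> np.ndarray:
        """Occupancy aggregated over age bands, shape ``(T+1, 12)``."""
        return self.occupancy.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.by_state, columns=list(STATE_LABELS))
        df.index.name = "cycle"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _aging_rates(params: ParameterSet) -> np.ndarray:
    rates = np.array([0.0 if b.upper is None else 1.0 / b.width for b in params.age_bands])
    return rates


def _age_forward(occ: np.ndarray, adv: np.ndarray) -> np.ndarray:
    out = occ * (1.0 - adv)[:, None]
    out[1:] += occ[:-1] * adv[:-1, None]
    return out


def run_markov_trace(
    initial: np.ndarray, params: ParameterSet, situation: str
) -> CohortTrace:
    """Propagate the cohort over ``horizon_years`` one-year cycles."""
    initial = np.asarray(initial, dtype=float)
    n_bands = len(params.age_bands)
    if initial.shape != (n_bands, N_STATES):
        raise ValueError(
            f"initial occupancy must have shape ({n_bands}, {N_STATES}), got {initial.shape}"
        )
    T = params.horizon_years
    trans = build_all_transitions(params, situation)
    S = np.stack([t.pa_shift for t in trans])
    O = np.stack([t.onset for t in trans])
    D = np.stack([t.death for t in trans])
    adv = _aging_rates(params)

    occ = np.zeros((T + 1, n_bands, N_STATES))
    occ[0] = initial
    incident = np.zeros((T, len(INCIDENT_COLUMNS)))
    col = {c: i for i, c in enumerate(INCIDENT_COLUMNS)}

    for t in range(1, T + 1):
        v = occ[t - 1]
        v1 = np.einsum("bs,bst->bt", v, S)
        # incident flows out of the onset factor
        for d in DISEASES:
            flow = sum(
                v1[:, src] * O[:, src, dst]
                for src, dst in zip(_HEALTHY_IDX, _DISEASE_IDX[d])
            )
            incident[t - 1, col[d]] = flow.sum()
        for comp, parent in COMPLICATION_PARENT.items():
            flow = sum(v1[:, src] * O[:, src, _COMP_IDX[comp]] for src in _DISEASE_IDX[parent])
            incident[t - 1, col[comp]] = flow.sum()
        v2 = np.einsum("bs,bst->bt", v1, O)
        incident[t - 1, col["deaths"]] = float((v2[:, list(LIVING)] * D[:, list(LIVING), DEAD]).sum())
        v3 = np.einsum("bs,bst->bt", v2, D)
        occ[t] = _age_forward(v3, adv)

    inc = pd.DataFrame(incident, index=pd.RangeIndex(1, T + 1, name="cycle"), columns=list(INCIDENT_COLUMNS))
    return CohortTrace(occupancy=occ, incident=inc, band_labels=params.band_labels, situation=situation)


def half_cycle_effective(occ_start: np.ndarray, occ_end: np.ndarray) -> np.ndarray:
    """Trapezoidal person-years in a cycle: mean of its two boundary occupancies."""
    return 0.5 * (np.asarray(occ_start, dtype=float) + np.asarray(occ_end, dtype=float))


def utility_vector(params: ParameterSet) -> np.ndarray:
    u = np.zeros(N_STATES)
    for g in PA_GROUPS:
        for lvl in _LEVELS:
            u[state_index(g, lvl)] = params.utilities[g][lvl]
    for c in COMPLICATIONS:
        u[_COMP_IDX[c]] = params.utilities[c]
    return u  # dead stays 0


def cost_vectors(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Annual (direct, indirect) SGD per person by state.

    Uncomplicated disease mixes inpatient and outpatient unit costs by the
    inpatient proportion, scaled by the PA-level cost multiplier (scenario
    analysis); complication states are costed entirely as inpatient cases.
    Healthy states carry no treatment cost. Indirect cost is direct cost
    divided by the disease's direct-to-indirect ratio.
    """
    direct = np.zeros(N_STATES)
    indirect = np.zeros(N_STATES)
    for d in DISEASES:
        base = (
            params.inpatient_proportion[d] * params.cost_inpatient[d]
            + (1.0 - params.inpatient_proportion[d]) * params.cost_outpatient[d]
        )
        for lvl in _LEVELS:
            i = state_index(d, lvl)
            direct[i] = base * params.pa_cost_multiplier[lvl]
            indirect[i] = direct[i] / params.direct_indirect_ratio[d]
    for c, parent in COMPLICATION_PARENT.items():
        i = _COMP_IDX[c]
        direct[i] = params.cost_inpatient[c]
        indirect[i] = direct[i] / params.direct_indirect_ratio[parent]
    return direct, indirect


def discount_factors(params: ParameterSet) -> np.ndarray:
    """Per-cycle discount factors for cycles 1..T under the configured convention."""
    r = params.discount_rate
    t = np.arange(1, params.horizon_years + 1, dtype=float)
    if params.discounting == "mid_cycle":
        t = t - 0.5
    return (1.0 + r) ** (-t)


@dataclass
class OutcomeSummary:
    """Discounted totals for one situation over the whole horizon."""

    situation: str
    n_initial: float
    qalys: float
    direct_cost: float
    indirect_cost: float
    program_cost: float
    cum_incident: dict[str, float] = field(default_factory=dict)

    @property
    def societal_cost(self) -> float:
        return self.direct_cost + self.indirect_cost

    def to_frame(self) -> pd.DataFrame:
        row = {
            "situation": self.situation,
            "n_initial": self.n_initial,
            "qalys": self.qalys,
            "direct_cost": self.direct_cost,
            "indirect_cost": self.indirect_cost,
            "societal_cost": self.societal_cost,
            "program_cost": self.program_cost,
        }
        row.update({f"cum_{k}": v for k, v in self.cum_incident.items()})
        return pd.DataFrame([row])


def accumulate_outcomes(
    trace: CohortTrace, params: ParameterSet, situation: str | None = None
) -> OutcomeSummary:
    """Half-cycle-corrected, discounted QALYs and costs for one trace.

    The annual program cost accrues (discounted, undiminished by deaths)
    in the intervention situation only and is reported separately from
    health-care costs.
    """
    situation = situation or trace.situation
    u = utility_vector(params)
    if (u < 0).any() or (u > 1).any():
        raise SchemaError("utilities must lie in [0, 1]")
    c_dir, c_ind = cost_vectors(params)
    if (c_dir < 0).any() or (c_ind < 0).any():
        raise SchemaError("costs must be nonnegative")

    occ = trace.by_state  # (T+1, 12)
    py = half_cycle_effective(occ[:-1], occ[1:])  # (T, 12)
    disc = discount_factors(params)
    qalys = float(disc @ (py @ u))
    direct = float(disc @ (py @ c_dir))
    indirect = float(disc @ (py @ c_ind))
    program = float(params.program_cost_annual * disc.sum()) if situation == "intervention" else 0.0
    cum = {c: float(trace.incident[c].sum()) for c in INCIDENT_COLUMNS}
    return OutcomeSummary(
        situation=situation,
        n_initial=float(occ[0].sum()),
        qalys=qalys,
        direct_cost=direct,
        indirect_cost=indirect,
        program_cost=program,
        cum_incident=cum,
    )


def project_prevalence(trace: CohortTrace, year: int) -> dict[str, dict[str, float]]:
    """Disease-group and PA-level fractions among the living at a boundary."""
    if not 0 <= year <= trace.n_cycles:
        raise ValueError(f"year must be in [0, {trace.n_cycles}], got {year}")
    occ = trace.by_state[year]
    living = occ[list(LIVING)].sum()
    if living <= 0:
        raise ValueError("prevalence undefined: no living cohort members")
    disease = {g: sum(occ[state_index(g, l)] for l in _LEVELS) / living for g in PA_GROUPS}
    disease.update({c: occ[_COMP_IDX[c]] / living for c in COMPLICATIONS})
    pa_total = sum(occ[state_index(g, l)] for g in PA_GROUPS for l in _LEVELS)
    pa = {
        l: (sum(occ[state_index(g, l)] for g in PA_GROUPS) / pa_total if pa_total > 0 else float("nan"))
        for l in _LEVELS
    }
    return {"disease": disease, "pa": pa}


def run_situation(
    params: ParameterSet, situation: str, n: float | None = None
) -> tuple[CohortTrace, OutcomeSummary]:
    """Initialize, trace and accumulate one situation end to end."""
    if n is None:
        n = params.cohort.size
    initial = initialize_cohort(params, n)
    trace = run_markov_trace(initial, params, situation)
    return trace, accumulate_outcomes(trace, params, situation)
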