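"""Age-specific one-cycle transition matrices.

Each annual transition is the composition of three row-stochastic factors
applied in a fixed within-cycle order:

1. **PA shift** — PA levels move within each living uncomplicated group.
   Under the intervention, a compliant fraction of the cohort follows the
   intervention shift matrix and the remainder the secular (control) one.
2. **Onset** — healthy members contract diabetes or hypertension at the
   calibrated inactive-reference incidence scaled by the PA-level relative
   risk; uncomplicated disease members develop the disease's complication.
3. **Death** — every living state dies at the all-cause rate scaled by its
   group/PA relative mortality risk (complication states use a per-state
   multiplier on the unadjusted rate).

Relative risks act multiplicatively on the *rate* scale; rates convert to
one-cycle probabilities with ``1 - exp(-rate * cycle)``, which keeps every
probability in [0, 1) for any nonnegative relative risk. Because every
factor is row-stochastic and dead is absorbing in each, the composed
matrix is row-stochastic with dead absorbing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet
from .states import (
    COMPLICATION_PARENT,
    COMPLICATIONS,
    DEAD,
    DISEASES,
    N_STATES,
    PA_GROUPS,
    PA_LEVELS,
    STATE_LABELS,
    state_index,
)

_LEVELS = tuple(l.value for l in PA_LEVELS)


class CalibrationError(ValueError):
    """Prevalence-weighted calibration has no solution."""


class ParameterInconsistencyError(ValueError):
    """Composed per-row probabilities exceed 1; never silently clipped."""


def calibrate_baseline_incidence(
    observed_rate: float, pa_prevalence: dict[str, float], rr: dict[str, float]
) -> float:
    """Inactive-reference rate ``i0`` such that the prevalence-weighted
    average of ``rr[k] * i0`` reproduces the observed population rate.

    The per-level rate is then ``rr[k] * i0``.
    """
    if observed_rate < 0:
        raise ValueError(f"observed rate must be nonnegative, got {observed_rate}")
    denom = sum(pa_prevalence[k] * rr[k] for k in _LEVELS)
    if denom <= 0:
        raise CalibrationError(
            "calibration infeasible: all prevalence mass on levels with zero relative risk"
        )
    return observed_rate / denom


def rate_to_probability(rate: float, cycle: float = 1.0) -> float:
    """Constant-hazard conversion of an annual rate to a one-cycle probability."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if cycle <= 0:
        raise ValueError(f"cycle length must be positive, got {cycle}")
    return -math.expm1(-rate * cycle)


@dataclass(frozen=True)
class AnnualTransition:
    """One-cycle transition for one age band and situation, with its factors."""

    pa_shift: np.ndarray
    onset: np.ndarray
    death: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return self.pa_shift @ self.onset @ self.death

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.full, index=STATE_LABELS, columns=STATE_LABELS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _pa_shift_factor(params: ParameterSet, situation: str) -> np.ndarray:
    shift = np.asarray(params.control_pa_shift, dtype=float)
    if situation == "intervention":
        c = params.compliance
        shift = c * np.asarray(params.intervention_pa_shift, dtype=float) + (1 - c) * shift
    m = np.eye(N_STATES)
    for g in PA_GROUPS:
        idx = [state_index(g, l) for l in PA_LEVELS]
        m[np.ix_(idx, idx)] = shift
    return m


def _onset_factor(params: ParameterSet, band_label: str) -> np.ndarray:
    cyc = params.cycle_length
    m = np.eye(N_STATES)
    # healthy -> disease, by PA level
    for lvl in _LEVELS:
        src = state_index("healthy", lvl)
        probs = {}
        for d in DISEASES:
            i0 = calibrate_baseline_incidence(
                params.incidence[band_label][d],
                params.pa_prevalence["healthy"],
                params.rr_incidence[d],
            )
            probs[d] = rate_to_probability(i0 * params.rr_incidence[d][lvl], cyc)
        total = sum(probs.values())
        if total > 1.0:
            raise ParameterInconsistencyError(
                f"onset probabilities from healthy/{lvl} in band {band_label} "
                f"sum to {total:.4f} > 1"
            )
        m[src, src] = 1.0 - total
        for d, p in probs.items():
            m[src, state_index(d, lvl)] = p
    # uncomplicated disease -> complication; PA protects against complication
    # onset with the same relative risks as against disease onset, calibrated
    # to the disease group's baseline PA mix
    for comp, parent in COMPLICATION_PARENT.items():
        c0 = calibrate_baseline_incidence(
            params.complication_incidence[band_label][parent],
            params.pa_prevalence[parent],
            params.rr_incidence[parent],
        )
        dst = state_index(comp)
        for lvl in _LEVELS:
            p = rate_to_probability(c0 * params.rr_incidence[parent][lvl], cyc)
            src = state_index(parent, lvl)
            m[src, src] = 1.0 - p
            m[src, dst] = p
    return m


def _death_factor(params: ParameterSet, band_label: str) -> np.ndarray:
    cyc = params.cycle_length
    m_rate = params.mortality[band_label]
    # calibrate the census all-cause rate to an inactive reference using the
    # cohort's baseline PA mix (prevalence-weighted across living groups)
    prev = _cohort_pa_mix(params)
    rr_healthy = params.rr_mortality["healthy"]
    m0 = calibrate_baseline_incidence(m_rate, prev, rr_healthy)
    m = np.eye(N_STATES)
    for g in PA_GROUPS:
        for lvl in _LEVELS:
            src = state_index(g, lvl)
            p = rate_to_probability(m0 * params.rr_mortality[g][lvl], cyc)
            m[src, src] = 1.0 - p
            m[src, DEAD] = p
    for comp in COMPLICATIONS:
        src = state_index(comp)
        p = rate_to_probability(m_rate * params.rr_mortality[comp], cyc)
        m[src, src] = 1.0 - p
        m[src, DEAD] = p
    return m


def _cohort_pa_mix(params: ParameterSet) -> dict[str, float]:
    """Baseline PA distribution of the whole cohort (disease-prevalence weighted)."""
    weights = {g: 0.0 for g in PA_GROUPS}
    for band in params.age_bands:
        prev = params.disease_prevalence[band.label]
        for g in PA_GROUPS:
            weights[g] += band.fraction * prev[g]
    total = sum(weights.values())
    mix = {l: 0.0 for l in _LEVELS}
    for g, w in weights.items():
        for l in _LEVELS:
            mix[l] += (w / total) * params.pa_prevalence[g][l]
    return mix


def build_transition_matrix(
    params: ParameterSet, band_label: str, situation: str
) -> AnnualTransition:
    """One-cycle transition for ``band_label`` under ``situation``.

    ``situation`` is ``"intervention"`` (compliant fraction follows the
    intervention PA-shift matrix) or ``"control"``.
    """
    if situation not in ("intervention", "control"):
        raise ValueError(f"situation must be 'intervention' or 'control', got {situation!r}")
    if band_label not in params.band_labels:
        raise ValueError(f"unknown age band {band_label!r}")
    return AnnualTransition(
        pa_shift=_pa_shift_factor(params, situation),
        onset=_onset_factor(params, band_label),
        death=_death_factor(params, band_label),
    )


def build_all_transitions(params: ParameterSet, situation: str) -> list[AnnualTransition]:
    """Transitions for every age band, in band order."""
    return [build_transition_matrix(params, b.label, situation) for b in params.age_bands]
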