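"""Individual-level Monte Carlo oracle for the cohort engine.

Simulates individuals through the identical annual state process — the
same PA-shift/onset/death factor matrices in the same within-cycle order,
and Bernoulli(1/band-width) age-band advancement whose expectation equals
the cohort model's deterministic fractional flow — then averages the same
half-cycle-corrected, discounted outcomes. Because it shares nothing with
the matrix-propagation code path beyond the factor construction, it
serves as an independent check: expected occupancy, QALYs and costs must
agree with the cohort trace within Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    cost_vectors,
    discount_factors,
    initialize_cohort,
    utility_vector,
)
from .params import ParameterSet
from .states import N_STATES
from .transitions import build_all_transitions


@dataclass
class MicrosimResult:
    """Monte-Carlo estimates (totals over the simulated individuals) with SEs."""

    n_individuals: int
    occupancy: np.ndarray  # (T+1, 12) individual counts
    qalys: float
    qalys_se: float
    direct_cost: float
    direct_cost_se: float
    indirect_cost: float
    indirect_cost_se: float
    program_cost: float
    situation: str
    seed: int

    def occupancy_se(self) -> np.ndarray:
        """Binomial standard errors of the occupancy counts."""
        p = self.occupancy / self.n_individuals
        return np.sqrt(self.n_individuals * p * (1.0 - p))


def _sample_rows(rng: np.random.Generator, matrix: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Categorical draw of next states, one row of ``matrix`` per individual."""
    cum = np.cumsum(matrix[states], axis=1)
    u = rng.random(states.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def microsim_oracle(
    params: ParameterSet,
    n_individuals: int,
    seed: int,
    situation: str = "intervention",
) -> MicrosimResult:
    """Simulate ``n_individuals`` through the full state process.

    Totals are directly comparable to a cohort run initialized with
    ``n = n_individuals``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    T = params.horizon_years
    n_bands = len(params.age_bands)

    # initial (band, state) assignment from the same cell probabilities
    cell_p = initialize_cohort(params, 1.0).ravel()
    cells = rng.choice(cell_p.size, size=n_individuals, p=cell_p / cell_p.sum())
    bands = cells // N_STATES
    states = cells % N_STATES

    trans = build_all_transitions(params, situation)
    S = np.stack([t.pa_shift for t in trans])
    O = np.stack([t.onset for t in trans])
    D = np.stack([t.death for t in trans])
    adv = np.array([0.0 if b.upper is None else 1.0 / b.width for b in params.age_bands])

    u = utility_vector(params)
    c_dir, c_ind = cost_vectors(params)
    disc = discount_factors(params)

    occupancy = np.zeros((T + 1, N_STATES))
    np.add.at(occupancy[0], states, 1.0)
    qaly_i = np.zeros(n_individuals)
    dir_i = np.zeros(n_individuals)
    ind_i = np.zeros(n_individuals)

    for t in range(1, T + 1):
        prev = states.copy()
        for b in range(n_bands):
            mask = bands == b
            if not mask.any():
                continue
            s = states[mask]
            s = _sample_rows(rng, S[b], s)
            s = _sample_rows(rng, O[b], s)
            s = _sample_rows(rng, D[b], s)
            states[mask] = s
        # half-cycle credit on this cycle's boundary pair, then discount
        qaly_i += disc[t - 1] * 0.5 * (u[prev] + u[states])
        dir_i += disc[t - 1] * 0.5 * (c_dir[prev] + c_dir[states])
        ind_i += disc[t - 1] * 0.5 * (c_ind[prev] + c_ind[states])
        move = (rng.random(n_individuals) < adv[bands]) & (bands < n_bands - 1)
        bands[move] += 1
        np.add.at(occupancy[t], states, 1.0)

    n = n_individuals
    program = float(params.program_cost_annual * disc.sum()) if situation == "intervention" else 0.0
    return MicrosimResult(
        n_individuals=n,
        occupancy=occupancy,
        qalys=float(qaly_i.sum()),
        qalys_se=float(qaly_i.std(ddof=1) * np.sqrt(n)),
        direct_cost=float(dir_i.sum()),
        direct_cost_se=float(dir_i.std(ddof=1) * np.sqrt(n)),
        indirect_cost=float(ind_i.sum()),
        indirect_cost_se=float(ind_i.std(ddof=1) * np.sqrt(n)),
        program_cost=program,
        situation=situation,
        seed=int(seed),
    )
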