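"""Synthetic parameter sets emulating the published model's input structure.

The real model's inputs live in a supplementary parameter table
(age-specific incidence and mortality, relative risks by PA level,
utilities, unit costs, and a prespecified uncertainty distribution per
parameter). This module generates complete, schema-valid stand-ins with
the same structure: headline economics anchored to the main-text values
(SGD 36 million/year program cost, 38.5% compliance, 3% discount, 10-year
horizon, 1.7 million registrants), epidemiology drawn from documented
plausible ranges with the qualitative shape the analysis assumes
(prevalence, incidence and mortality increasing with age; higher PA
levels carrying lower onset and mortality risk; utilities ordered healthy
>= disease >= complication). Generated values are stand-ins, never the
published table's numbers.

At ``full`` scale exactly 33 parameters carry non-degenerate uncertainty
distributions (the one-way analysis set); the time horizon is flagged
``psa_exclude`` so the probabilistic analysis varies the other 32.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    AgeBand,
    CohortSpec,
    DistributionSpec,
    ParameterSet,
    beta_from_mean_sd,
    gamma_from_mean_sd,
    lognormal_from_median_sigma,
)
from .states import COMPLICATIONS, DISEASES, PA_GROUPS, PA_LEVELS

_LEVELS = tuple(l.value for l in PA_LEVELS)

PROGRAM_COST_ANNUAL = 36e6  # SGD/year
COMPLIANCE = 0.385
DISCOUNT_RATE = 0.03
HORIZON_YEARS = 10
N_REGISTERED = 1.7e6
WTP_GRID = [0.0, 5000.0, 10000.0]


def _band_edges(scale: str) -> list[tuple[int, int | None]]:
    if scale == "toy":
        return [(17, 39), (40, 64), (65, None)]
    if scale == "full":
        return [(17, 19)] + [(a, a + 4) for a in range(20, 85, 5)] + [(85, None)]
    raise ValueError(f"scale must be 'toy' or 'full', got {scale!r}")


def _mid(lo: int, hi: int | None) -> float:
    return 90.0 if hi is None else 0.5 * (lo + hi)


def _logistic(x: float, cap: float, x0: float, width: float) -> float:
    return cap / (1.0 + math.exp(-(x - x0) / width))


def _simplex_jitter(rng: np.random.Generator, probs: list[float], rel: float = 0.05) -> list[float]:
    v = np.asarray(probs) * rng.uniform(1 - rel, 1 + rel, size=len(probs))
    v = v / v.sum()
    return [float(x) for x in v]


def generate_parameter_set(seed: int, scale: str = "full") -> ParameterSet:
    """Deterministic, schema-valid synthetic parameter set.

    ``scale="toy"`` uses 3 coarse age bands for fast exact tests;
    ``scale="full"`` mirrors the real model's dimensionality (15 five-year
    bands from 17-19 to 85+).
    """
    rng = np.random.default_rng(seed)
    edges = _band_edges(scale)

    # age distribution: broadly flat through midlife, declining in old age
    weights = []
    for lo, hi in edges:
        m = _mid(lo, hi)
        w = (hi - lo + 1 if hi is not None else 10) * (
            1.0 if m < 60 else math.exp(-(m - 60) / 18.0)
        )
        weights.append(w * rng.uniform(0.95, 1.05))
    total_w = sum(weights)
    bands = [
        AgeBand(label=(f"{lo}-{hi}" if hi is not None else f"{lo}+"), lower=lo, upper=hi, fraction=w / total_w)
        for (lo, hi), w in zip(edges, weights)
    ]

    # age-curve scale jitters (one factor per curve keeps age-monotonicity)
    j = {k: rng.uniform(0.9, 1.1) for k in (
        "prev_diab", "prev_hyp", "inc_diab", "inc_hyp", "comp_diab", "comp_hyp", "mort"
    )}

    disease_prevalence, incidence, complication_incidence, mortality = {}, {}, {}, {}
    for band in bands:
        m = _mid(band.lower, band.upper)
        p_d = j["prev_diab"] * _logistic(m, 0.30, 62, 12)
        p_h = j["prev_hyp"] * _logistic(m, 0.62, 58, 10)
        disease_prevalence[band.label] = {
            "healthy": 1.0 - p_d - p_h,
            "diabetes": p_d,
            "hypertension": p_h,
        }
        incidence[band.label] = {
            "diabetes": j["inc_diab"] * _logistic(m, 0.025, 50, 15),
            "hypertension": j["inc_hyp"] * _logistic(m, 0.060, 50, 12),
        }
        complication_incidence[band.label] = {
            "diabetes": j["comp_diab"] * _logistic(m, 0.055, 60, 12),
            "hypertension": j["comp_hyp"] * _logistic(m, 0.040, 62, 12),
        }
        mortality[band.label] = min(0.18, j["mort"] * 3e-4 * math.exp(0.085 * (m - 17)))

    pa_prevalence = {
        "healthy": dict(zip(_LEVELS, _simplex_jitter(rng, [0.34, 0.27, 0.39]))),
        "diabetes": dict(zip(_LEVELS, _simplex_jitter(rng, [0.46, 0.26, 0.28]))),
        "hypertension": dict(zip(_LEVELS, _simplex_jitter(rng, [0.44, 0.27, 0.29]))),
    }

    def _rr_pair(low: float, high_protect: float) -> dict[str, float]:
        lo_v = min(0.99, low * rng.uniform(0.96, 1.04))
        hi_v = min(lo_v - 0.01, high_protect * rng.uniform(0.96, 1.04))
        return {"inactive": 1.0, "low": lo_v, "mod_high": hi_v}

    rr_incidence = {
        "diabetes": _rr_pair(0.78, 0.58),
        "hypertension": _rr_pair(0.84, 0.66),
    }
    rr_mortality = {
        "healthy": _rr_pair(0.88, 0.78),
        "diabetes": _rr_pair(0.90, 0.82),
        "hypertension": _rr_pair(0.90, 0.82),
        "diabetes_cvd": 3.0 * rng.uniform(0.92, 1.08),
        "hypertension_stroke": 2.6 * rng.uniform(0.92, 1.08),
    }

    du = rng.uniform(-0.01, 0.01, size=12)
    utilities = {
        "healthy": {
            "inactive": round(min(0.99, 0.94 + du[0]), 4),
            "low": round(min(0.995, 0.96 + du[1]), 4),
            "mod_high": 1.0,
        },
        "diabetes": {
            "inactive": round(0.82 + du[2], 4),
            "low": round(0.84 + du[3], 4),
            "mod_high": round(0.86 + du[4], 4),
        },
        "hypertension": {
            "inactive": round(0.86 + du[5], 4),
            "low": round(0.88 + du[6], 4),
            "mod_high": round(0.90 + du[7], 4),
        },
        "diabetes_cvd": round(0.70 + du[8], 4),
        "hypertension_stroke": round(0.64 + du[9], 4),
    }

    cost_inpatient = {
        "diabetes": round(12000 * rng.uniform(0.9, 1.1), 2),
        "hypertension": round(8000 * rng.uniform(0.9, 1.1), 2),
        "diabetes_cvd": round(28000 * rng.uniform(0.9, 1.1), 2),
        "hypertension_stroke": round(25000 * rng.uniform(0.9, 1.1), 2),
    }
    cost_outpatient = {
        "diabetes": round(3000 * rng.uniform(0.9, 1.1), 2),
        "hypertension": round(1800 * rng.uniform(0.9, 1.1), 2),
    }
    inpatient_proportion = {
        "diabetes": round(0.18 * rng.uniform(0.9, 1.1), 4),
        "hypertension": round(0.15 * rng.uniform(0.9, 1.1), 4),
    }
    direct_indirect_ratio = {
        "diabetes": round(0.45 * rng.uniform(0.95, 1.05), 4),
        "hypertension": round(0.50 * rng.uniform(0.95, 1.05), 4),
    }

    # intervention PA-shift: net upward movement; control: no secular drift
    shift = np.array(
        [
            [0.50, 0.30, 0.20],
            [0.02, 0.65, 0.33],
            [0.01, 0.05, 0.94],
        ]
    )
    shift = shift * rng.uniform(0.97, 1.03, size=shift.shape)
    shift = shift / shift.sum(axis=1, keepdims=True)
    intervention_pa_shift = [[float(x) for x in row] for row in shift]
    control_pa_shift = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]

    ps = ParameterSet(
        age_bands=bands,
        cohort=CohortSpec(n_registered=N_REGISTERED, completion_fraction=COMPLIANCE),
        pa_prevalence=pa_prevalence,
        disease_prevalence=disease_prevalence,
        incidence=incidence,
        complication_incidence=complication_incidence,
        mortality=mortality,
        rr_incidence=rr_incidence,
        rr_mortality=rr_mortality,
        utilities=utilities,
        cost_inpatient=cost_inpatient,
        cost_outpatient=cost_outpatient,
        inpatient_proportion=inpatient_proportion,
        direct_indirect_ratio=direct_indirect_ratio,
        program_cost_annual=PROGRAM_COST_ANNUAL,
        compliance=COMPLIANCE,
        intervention_pa_shift=intervention_pa_shift,
        control_pa_shift=control_pa_shift,
        discount_rate=DISCOUNT_RATE,
        horizon_years=HORIZON_YEARS,
        wtp_grid=list(WTP_GRID),
        distributions=_build_distributions_dict(
            rr_incidence,
            rr_mortality,
            utilities,
            cost_inpatient,
            cost_outpatient,
            inpatient_proportion,
        ),
    )
    return ps


def _with_rule(spec: DistributionSpec, rule: str, psa_exclude: bool = False) -> DistributionSpec:
    return DistributionSpec(
        family=spec.family,
        parameters=spec.parameters,
        range_rule=rule,
        psa_exclude=psa_exclude,
    )


def _build_distributions_dict(
    rr_incidence,
    rr_mortality,
    utilities,
    cost_inpatient,
    cost_outpatient,
    inpatient_proportion,
) -> dict[str, DistributionSpec]:
    dists: dict[str, DistributionSpec] = {}
    # relative risks: lognormal around the base (median), 95% CI range rule
    for d in DISEASES:
        for lvl in ("low", "mod_high"):
            dists[f"rr_incidence.{d}.{lvl}"] = _with_rule(
                lognormal_from_median_sigma(rr_incidence[d][lvl], 0.10), "ci95"
            )
    for g in PA_GROUPS:
        for lvl in ("low", "mod_high"):
            dists[f"rr_mortality.{g}.{lvl}"] = _with_rule(
                lognormal_from_median_sigma(rr_mortality[g][lvl], 0.10), "ci95"
            )
    for c in COMPLICATIONS:
        dists[f"rr_mortality.{c}"] = _with_rule(
            lognormal_from_median_sigma(rr_mortality[c], 0.12), "ci95"
        )
    # utilities: beta, except the perfect-health anchor u(healthy, mod_high) = 1
    for g in PA_GROUPS:
        for lvl in _LEVELS:
            if g == "healthy" and lvl == "mod_high":
                continue
            dists[f"utilities.{g}.{lvl}"] = _with_rule(
                beta_from_mean_sd(utilities[g][lvl], 0.02), "ci95"
            )
    for c in COMPLICATIONS:
        dists[f"utilities.{c}"] = _with_rule(beta_from_mean_sd(utilities[c], 0.02), "ci95")
    # unit costs: gamma, interquartile range rule
    for c, v in cost_inpatient.items():
        dists[f"cost_inpatient.{c}"] = _with_rule(gamma_from_mean_sd(v, 0.25 * v), "iqr")
    for d, v in cost_outpatient.items():
        dists[f"cost_outpatient.{d}"] = _with_rule(gamma_from_mean_sd(v, 0.25 * v), "iqr")
    # inpatient proportions, program cost, compliance: +/-30% range rule
    for d, v in inpatient_proportion.items():
        dists[f"inpatient_proportion.{d}"] = _with_rule(
            beta_from_mean_sd(v, 0.3 * v / 1.96), "pm30"
        )
    dists["program_cost_annual"] = _with_rule(
        gamma_from_mean_sd(PROGRAM_COST_ANNUAL, 0.3 * PROGRAM_COST_ANNUAL / 1.96), "pm30"
    )
    dists["compliance"] = _with_rule(
        beta_from_mean_sd(COMPLIANCE, 0.3 * COMPLIANCE / 1.96), "pm30"
    )
    # time horizon: one-way only (+/-30%, rounded to whole cycles); never in the PSA
    dists["horizon_years"] = DistributionSpec(
        family="uniform",
        parameters={"low": 0.7 * HORIZON_YEARS, "high": 1.3 * HORIZON_YEARS},
        range_rule="pm30",
        psa_exclude=True,
    )
    assert len(dists) == 33
    return dists


def generate_population(seed: int, n: int, age_spec: list[AgeBand]) -> np.ndarray:
    """Multinomial allocation of ``n`` individuals across age bands (ages >= 17)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    fractions = np.array([b.fraction for b in age_spec], dtype=float)
    fractions = fractions / fractions.sum()
    return rng.multinomial(n, fractions)
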