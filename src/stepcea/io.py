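"""Configuration I/O, observed-vs-projected validation, and result reporting."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .economics import UNDEFINED_ICER, Evaluation
from .params import ParameterSet, SchemaError
from .uncertainty import PSAResult


def read_config(path) -> ParameterSet:
    """Parse and eagerly validate a YAML configuration file.

    Unknown keys and domain violations raise :class:`SchemaError` naming
    the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return parse_config(raw)


def parse_config(raw: dict) -> ParameterSet:
    try:
        return ParameterSet.model_validate(raw)
    except ValidationError as e:
        fields = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise SchemaError(f"invalid configuration: {fields}") from e


def config_to_yaml(params: ParameterSet) -> str:
    """Canonical YAML text (sorted keys, so equal parameter sets are byte-identical)."""
    return yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)


def write_config(params: ParameterSet, path) -> None:
    Path(path).write_text(config_to_yaml(params))


def config_hash(params: ParameterSet) -> str:
    """SHA-256 of the canonical configuration text; ties results to exact inputs."""
    return hashlib.sha256(config_to_yaml(params).encode()).hexdigest()


def validate_against_observed(
    projected: dict[str, float], observed: dict[str, float], tolerance: float = 0.05
) -> pd.DataFrame:
    """Compare projected prevalence fractions with an observed vector.

    Categories must match exactly; the table carries absolute and relative
    differences and a flag against ``tolerance`` (absolute difference).
    """
    if set(projected) != set(observed):
        missing = sorted(set(projected) ^ set(observed))
        raise ValueError(f"category labels do not match; unmatched: {missing}")
    cats = sorted(projected)
    rows = []
    for c in cats:
        p, o = projected[c], observed[c]
        diff = p - o
        rows.append(
            {
                "category": c,
                "projected": p,
                "observed": o,
                "abs_diff": abs(diff),
                "rel_diff": diff / o if o != 0 else math.inf,
                "within_tolerance": abs(diff) <= tolerance,
            }
        )
    return pd.DataFrame(rows)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def format_sig(x: float, sig: int = 3) -> str:
    """Headline formatting: 3 significant figures, thousands separators."""
    r = round_sig(x, sig)
    if abs(r) >= 1000:
        return f"{r:,.0f}"
    return f"{r:g}"


def _ci(psa: PSAResult | None, quantity: str, scale: float = 1.0) -> str:
    if psa is None or quantity not in psa.summary.index:
        return ""
    lo = psa.summary.loc[quantity, "p2.5"] * scale
    hi = psa.summary.loc[quantity, "p97.5"] * scale
    return f"({format_sig(lo)} to {format_sig(hi)})"


def summary_table(
    evaluation: Evaluation, psa: PSAResult | None = None, cost_adjustment: str = "equal"
) -> pd.DataFrame:
    """Headline results, one row per perspective (deterministic point estimates,
    PSA credible intervals and CE probabilities when a PSA is supplied)."""
    inc = evaluation.incremental
    rows = []
    for persp in ("health_system", "societal"):
        red = inc.cost_reduction(persp)
        ic = inc.icer(persp)
        row = {
            "perspective": persp,
            "cost_adjustment": cost_adjustment,
            "qalys_gained": inc.qalys_gained,
            "cost_reduction": red,
            "cost_reduction_ci": _ci(
                psa,
                "healthcare_cost_reduction" if persp == "health_system" else "societal_cost_reduction",
            ),
            "program_cost": inc.program_cost,
            "icer": float("nan") if ic is UNDEFINED_ICER else ic,
            "classification": inc.classification(persp),
        }
        if psa is not None:
            for wtp, p in psa.ce_probability[persp].items():
                row[f"prob_ce_wtp_{int(wtp)}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def headline(evaluation: Evaluation, psa: PSAResult | None = None) -> str:
    """Plain-text headline report, rounded to 3 significant figures."""
    inc = evaluation.incremental
    ic = inc.icer()
    icer_txt = (
        "undefined (no QALY difference)"
        if ic is UNDEFINED_ICER
        else f"SGD {format_sig(ic)} per QALY"
    )
    lines = [
        f"Cohort size: {format_sig(evaluation.intervention.n_initial)} participants",
        f"Diabetes cases averted: {format_sig(inc.diabetes_averted)} {_ci(psa, 'diabetes_averted')}".rstrip(),
        f"Hypertension cases averted: {format_sig(inc.hypertension_averted)} {_ci(psa, 'hypertension_averted')}".rstrip(),
        f"Deaths averted: {format_sig(inc.deaths_averted)} {_ci(psa, 'deaths_averted')}".rstrip(),
        f"QALYs gained: {format_sig(inc.qalys_gained)} {_ci(psa, 'qalys_gained')}".rstrip(),
        f"Health-care cost reduction: SGD {format_sig(inc.healthcare_cost_reduction)} {_ci(psa, 'healthcare_cost_reduction')}".rstrip(),
        f"Societal cost reduction: SGD {format_sig(inc.societal_cost_reduction)} {_ci(psa, 'societal_cost_reduction')}".rstrip(),
        f"Program cost (discounted, 10y): SGD {format_sig(inc.program_cost)} {_ci(psa, 'program_cost')}".rstrip(),
        f"ICER (health system): {icer_txt}",
        f"Classification: {inc.classification()}",
    ]
    return "\n".join(lines) + "\n"


def report(
    evaluation: Evaluation,
    out_dir,
    params: ParameterSet,
    psa: PSAResult | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write summary.csv, headline.txt and run metadata; returns the paths.

    All stored values keep full precision; rounding happens only in the
    headline text.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = summary_table(evaluation, psa)
    paths["summary"] = out / "summary.csv"
    table.to_csv(paths["summary"], index=False)
    paths["headline"] = out / "headline.txt"
    paths["headline"].write_text(headline(evaluation, psa))
    meta = {
        "package_version": __version__,
        "config_hash": config_hash(params),
        "seed": seed,
        "currency_note": "all monetary values in SGD; SGD 1 = US $0.73 (2019)",
    }
    paths["metadata"] = out / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2) + "\n")
    if psa is not None:
        paths["psa_samples"] = out / "psa_samples.csv"
        psa.samples.to_csv(paths["psa_samples"], index=False)
        for persp, curve in psa.ceac.items():
            p = out / f"ceac_{persp}.csv"
            curve.to_csv(p, index=False)
            paths[f"ceac_{persp}"] = p
    return paths
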