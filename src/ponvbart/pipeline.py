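"""End-to-end orchestration: cohort -> BART -> sATE -> validation -> report.

A single top-level seed deterministically derives one sub-seed per stage
(simulation, BART, propensity, outcome logistic), so a run manifest plus
the same platform reproduces a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bart import BartConfig, fit_pbart
from .cohort import (
    ColumnDialect,
    apply_inclusion_filters,
    build_feature_matrix,
    load_cohort_detailed,
    summarize_cohort,
)
from .gcomp import absolute_risk_table, build_counterfactual_grid, plot_sate, sate
from .propensity import fit_outcome_logistic, fit_propensity, logistic_sate, or_table
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "report", "format_rr", "RunBundle",
           "validate_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "input": {"kind": "simulate", "n": 2000},
    "seed": 0,
    "model": {"m": 50, "ndpost": 1000, "nskip": 100},
    "validation": {"engine": "logistic", "draws": 1000, "chains": 2},
    "ci_level": 0.95,
    "output_dir": None,
    "figures": False,
    "replicate": None,
}

_ALLOWED_TOP = set(DEFAULT_CONFIG)
_ALLOWED_INPUT = {"kind", "n", "path", "dialect", "sim_config"}


def validate_config(config: dict) -> dict:
    """Merge with defaults; reject unknown or malformed keys by name."""
    bad = [k for k in config if k not in _ALLOWED_TOP]
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    merged = {**DEFAULT_CONFIG, **config}
    inp = merged["input"]
    if not isinstance(inp, dict):
        raise ValueError("config key 'input' must be a mapping")
    bad = [k for k in inp if k not in _ALLOWED_INPUT]
    if bad:
        raise ValueError(f"unknown input key(s): {sorted(bad)}")
    kind = inp.get("kind")
    if kind not in ("simulate", "csv"):
        raise ValueError("input.kind must be 'simulate' or 'csv'")
    if kind == "csv" and "path" not in inp:
        raise ValueError("input.kind 'csv' requires input.path")
    return merged


@dataclass
class RunBundle:
    """All artifacts of one pipeline run."""

    summary: dict
    exclusions: dict
    sate_bart: list
    risk_table: object
    sate_logistic: list
    or_table: object
    truth: object          # SimTruth for simulated inputs, else None
    manifest: dict
    replicate_comparison: dict | None = None


def _derive_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(5) & 0x7FFFFFFF
    return {"simulate": int(state[0]), "bart": int(state[1]),
            "propensity": int(state[2]), "logistic": int(state[3]),
            "replicate": int(state[4])}


def _load_input(inp: dict, sim_seed: int):
    """Return (records, truth-or-None)."""
    if inp["kind"] == "simulate":
        sim_cfg = inp.get("sim_config")
        if sim_cfg is None:
            sim_cfg = SimConfig(n=int(inp.get("n", 2000)), seed=sim_seed)
        records, truth = simulate_cohort(sim_cfg)
        return records, truth
    path = Path(inp["path"])
    if not path.exists():
        raise FileNotFoundError(f"input cohort file not found: {path}")
    dialect = inp.get("dialect")
    if isinstance(dialect, dict):
        dialect = ColumnDialect(**dialect)
    records, errors = load_cohort_detailed(path, dialect)
    if errors:
        logger.warning("%d row(s) rejected while loading %s",
                       len(errors), path)
    return records, None


def _analyse(records, config, seeds):
    """Core analysis on one cohort: encode, fit, sATE, validation arm."""
    kept, tally = apply_inclusion_filters(records)
    features = build_feature_matrix(kept)
    summary = summarize_cohort(kept)

    model = config["model"]
    bart_cfg = BartConfig(m=int(model.get("m", 50)),
                          ndpost=int(model.get("ndpost", 1000)),
                          nskip=int(model.get("nskip", 100)),
                          seed=seeds["bart"])
    fit = fit_pbart(features.X, features.y, bart_cfg)
    grid = build_counterfactual_grid(features)
    results = sate(fit, grid, ci_level=config["ci_level"])

    val = config["validation"]
    propensity = fit_propensity(features, engine=val.get("engine", "logistic"),
                                seed=seeds["propensity"],
                                draws=int(val.get("draws", 1000)),
                                chains=int(val.get("chains", 2)))
    outcome_post = fit_outcome_logistic(features, propensity,
                                        draws=int(val.get("draws", 1000)),
                                        chains=int(val.get("chains", 2)),
                                        seed=seeds["logistic"])
    log_results = logistic_sate(outcome_post, grid,
                                ci_level=config["ci_level"])
    return {"summary": summary, "exclusions": tally, "features": features,
            "fit": fit, "sate": results,
            "risk_table": absolute_risk_table(results),
            "or_table": or_table(outcome_post, config["ci_level"]),
            "sate_logistic": log_results}


def run_pipeline(config) -> RunBundle:
    """Run the full analysis from a config mapping or YAML file path."""
    t0 = time.time()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = validate_config(dict(config))
    seeds = _derive_seeds(int(config["seed"]))

    records, truth = _load_input(config["input"], seeds["simulate"])
    arm = _analyse(records, config, seeds)

    replicate_cmp = None
    if config.get("replicate"):
        rep_inp = dict(config["replicate"])
        rep_seeds = dict(seeds, bart=seeds["replicate"])
        rep_records, _ = _load_input(rep_inp, seeds["replicate"])
        rep_arm = _analyse(rep_records, config, rep_seeds)
        replicate_cmp = {
            "primary": [r.to_dict() for r in arm["sate"]
                        if r.stratum == "pooled"],
            "replicate": [r.to_dict() for r in rep_arm["sate"]
                          if r.stratum == "pooled"],
        }

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: v for k, v in config.items() if k != "input"}
        | {"input": {k: v for k, v in config["input"].items()
                     if k != "sim_config"}},
        "derived_seeds": seeds,
        "wall_time_s": round(time.time() - t0, 3),
    }
    bundle = RunBundle(
        summary=arm["summary"], exclusions=arm["exclusions"],
        sate_bart=arm["sate"], risk_table=arm["risk_table"],
        sate_logistic=arm["sate_logistic"], or_table=arm["or_table"],
        truth=truth, manifest=manifest,
        replicate_comparison=replicate_cmp)

    out_dir = config.get("output_dir")
    if out_dir:
        _write_bundle(bundle, Path(out_dir), figures=config.get("figures"))
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path, figures=False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(json.dumps(bundle.summary, indent=1))
    (out_dir / "exclusions.json").write_text(
        json.dumps(bundle.exclusions, indent=1))
    sate_rows = [r.to_dict() for r in bundle.sate_bart]
    (out_dir / "sate_bart.json").write_text(json.dumps(sate_rows, indent=1))
    import pandas as pd
    pd.DataFrame(sate_rows).to_csv(out_dir / "sate_bart.csv", index=False)
    (out_dir / "sate_logistic.json").write_text(
        json.dumps([r.to_dict() for r in bundle.sate_logistic], indent=1))
    bundle.or_table.to_csv(out_dir / "or_table.csv", index=False)
    (out_dir / "or_table.json").write_text(
        bundle.or_table.to_json(orient="records"))
    bundle.risk_table.to_csv(out_dir / "risk_table.csv", index=False)
    if bundle.truth is not None:
        (out_dir / "truth.json").write_text(
            json.dumps(dataclasses.asdict(bundle.truth), indent=1,
                       default=float))
    if bundle.replicate_comparison is not None:
        (out_dir / "replicate_comparison.json").write_text(
            json.dumps(bundle.replicate_comparison, indent=1))
    (out_dir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1))
    (out_dir / "report.txt").write_text(report(bundle))
    if figures:
        plot_sate(bundle.sate_bart, out_dir, formats=("svg",))


def format_rr(rr_mean, ci_low, ci_high, prob_gt_1, ci_level=0.95) -> str:
    """Render a relative risk in the conventional reporting format."""
    pct = int(round(ci_level * 100))
    return (f"{rr_mean:.2f} ({pct}% CI {ci_low:.2f}–{ci_high:.2f}, "
            f"posterior probability RR > 1 = {prob_gt_1 * 100:.1f}%)")


def report(bundle: RunBundle) -> str:
    """Human-readable summary of a run bundle."""
    lines = ["PONV causal analysis", "=" * 40, ""]
    lines.append("Cohort: n = %d analyzed; any-cannabis prevalence %.1f%%"
                 % (sum(v["n"] for v in bundle.summary["levels"].values()),
                    bundle.summary["any_cannabis"]["pct"]))
    lines.append("")
    lines.append("BART g-computation sATE (relative risk):")
    for r in bundle.sate_bart:
        if r.stratum != "pooled":
            continue
        lines.append("  %-18s %s" % (
            r.contrast.replace("_", " ") + ":",
            format_rr(r.rr_mean, r.rr_ci_low, r.rr_ci_high, r.prob_rr_gt_1)))
        lines.append("    absolute risk change: %.1f%% (95%% CI %.1f–%.1f%%)"
                     % (r.rd_mean * 100, r.rd_ci_low * 100, r.rd_ci_high * 100))
    strata = sorted({r.stratum for r in bundle.sate_bart
                     if r.stratum != "pooled"})
    if strata:
        lines.append("  stratified by Apfel score:")
        for r in bundle.sate_bart:
            if r.stratum == "pooled":
                continue
            lines.append("    Apfel %s, %-18s %s" % (
                r.stratum, r.contrast.replace("_", " ") + ":",
                format_rr(r.rr_mean, r.rr_ci_low, r.rr_ci_high,
                          r.prob_rr_gt_1)))
    lines.append("")
    lines.append("Propensity-adjusted Bayesian logistic validation arm:")
    for r in bundle.sate_logistic:
        if r.stratum != "pooled":
            continue
        lines.append("  %-18s %s" % (
            r.contrast.replace("_", " ") + ":",
            format_rr(r.rr_mean, r.rr_ci_low, r.rr_ci_high, r.prob_rr_gt_1)))
    ot = bundle.or_table
    daily = ot[ot["parameter"].str.startswith("Daily Use")].iloc[0]
    lines.append("  daily-use odds ratio: %.2f (95%% CI %.2f–%.2f)"
                 % (daily["odds_ratio"], daily["ci_low"], daily["ci_high"]))
    if bundle.replicate_comparison:
        lines.append("")
        lines.append("External replication (independent cohort):")
        for side in ("primary", "replicate"):
            for r in bundle.replicate_comparison[side]:
                lines.append("  %-9s %-18s %s" % (
                    side + ":", r["contrast"].replace("_", " ") + ":",
                    format_rr(r["rr_mean"], r["rr_ci_low"], r["rr_ci_high"],
                              r["prob_rr_gt_1"])))
    if bundle.truth is not None:
        lines.append("")
        lines.append("Generator ground truth (brute-force oracle):")
        for contrast, vals in bundle.truth.pooled.items():
            lines.append("  true %-18s RR = %.3f, RD = %.4f"
                         % (contrast.replace("_", " "), vals["rr"],
                            vals["rd"]))
    return "\n".join(lines) + "\n"
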