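"""Counterfactual g-computation of sample average treatment effects.

Every subject is artificially assigned to each cannabis level; the fitted
posterior predicts each subject's outcome probability under each level,
and each retained MCMC draw yields one sample-level contrast: the relative
risk RR_s (ratio of mean predicted probabilities, treated over control)
and the risk difference RD_s.  Across-draw means, equal-tailed credible
intervals, and the posterior probability that RR exceeds 1 summarize the
posterior, pooled and within each Apfel stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["CounterfactualGrid", "SateResult", "build_counterfactual_grid",
           "sate", "sate_from_predictions", "absolute_risk_table", "plot_sate",
           "CONTRASTS"]

LEVELS = ("none", "current", "daily")
CONTRASTS = ("current_vs_none", "daily_vs_none")


@dataclass
class CounterfactualGrid:
    """Per-level copies of the covariate matrix, cannabis columns forced.

    The three matrices are identical except for the two treatment dummies;
    Apfel strata stay at each subject's factual value under every level.
    """

    matrices: dict           # level -> covariate DataFrame
    apfel: np.ndarray        # factual Apfel score per subject

    def __post_init__(self):
        shapes = {lv: m.shape for lv, m in self.matrices.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"counterfactual matrices differ in shape: {shapes}")


def build_counterfactual_grid(features: FeatureMatrix) -> CounterfactualGrid:
    """Force every subject to each treatment level (deterministic)."""
    matrices = {}
    for level in LEVELS:
        X = features.X.copy()
        X["cannabis_current"] = int(level == "current")
        X["cannabis_daily"] = int(level == "daily")
        matrices[level] = X
    return CounterfactualGrid(matrices=matrices, apfel=features.apfel.copy())


@dataclass
class SateResult:
    """Posterior summary of one contrast in one stratum."""

    contrast: str            # "current_vs_none" | "daily_vs_none"
    stratum: object          # Apfel value 0-4 or "pooled"
    rr_mean: float
    rr_ci_low: float
    rr_ci_high: float
    rd_mean: float
    rd_ci_low: float
    rd_ci_high: float
    prob_rr_gt_1: float
    n_draws: int
    n_subjects: int
    p_treated_mean: float = float("nan")   # mean predicted P under treatment
    p_control_mean: float = float("nan")   # mean predicted P under control

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "contrast", "stratum", "rr_mean", "rr_ci_low", "rr_ci_high",
            "rd_mean", "rd_ci_low", "rd_ci_high", "prob_rr_gt_1",
            "n_draws", "n_subjects", "p_treated_mean", "p_control_mean")}


def sate_from_predictions(preds: dict, apfel: np.ndarray,
                          contrasts=CONTRASTS, ci_level: float = 0.95,
                          stratify: bool = True) -> list[SateResult]:
    """Contrast per-draw prediction matrices (level -> draws x n array).

    The pooled per-draw mean probability is the subject-count-weighted
    average of the stratum means by construction (same rows, same draws).
    """
    n = next(iter(preds.values())).shape[1]
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    groups = [("pooled", np.arange(n))]
    if stratify:
        for s in range(5):
            idx = np.where(apfel == s)[0]
            if idx.size == 0:
                logger.info("Apfel stratum %d has no subjects; omitted", s)
                continue
            groups.append((s, idx))

    results = []
    for contrast in contrasts:
        treated_level = contrast.split("_vs_")[0]
        control_level = contrast.split("_vs_")[1]
        for stratum, idx in groups:
            mt = preds[treated_level][:, idx].mean(axis=1)  # per-draw means
            mc = preds[control_level][:, idx].mean(axis=1)
            assert (mc > 0).all(), "control mean probability must be positive"
            rr = mt / mc
            rd = mt - mc
            results.append(SateResult(
                contrast=contrast, stratum=stratum,
                rr_mean=float(rr.mean()),
                rr_ci_low=float(np.quantile(rr, lo_q)),
                rr_ci_high=float(np.quantile(rr, hi_q)),
                rd_mean=float(rd.mean()),
                rd_ci_low=float(np.quantile(rd, lo_q)),
                rd_ci_high=float(np.quantile(rd, hi_q)),
                prob_rr_gt_1=float(np.mean(rr > 1)),   # strict exceedance
                n_draws=len(rr), n_subjects=int(idx.size),
                p_treated_mean=float(mt.mean()),
                p_control_mean=float(mc.mean()),
            ))
    return results


def sate(fit, grid: CounterfactualGrid, contrasts=CONTRASTS,
         strata: np.ndarray | None = None,
         ci_level: float = 0.95) -> list[SateResult]:
    """g-computation through a fitted probit BART posterior.

    ``strata`` defaults to the grid's factual Apfel scores; results include
    every nonempty stratum plus the pooled group, per contrast.
    """
    preds = {lv: fit.predict(X) for lv, X in grid.matrices.items()}
    apfel = grid.apfel if strata is None else np.asarray(strata)
    return sate_from_predictions(preds, apfel, contrasts, ci_level)


def absolute_risk_table(results) -> pd.DataFrame:
    """Risk differences on the percentage scale, raw values preserved."""
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for r in results:
        rows.append({
            "contrast": r.contrast,
            "stratum": r.stratum,
            "risk_increase_pct": f"{r.rd_mean * 100:.1f}%",
            "ci_pct": f"{r.rd_ci_low * 100:.1f}% - {r.rd_ci_high * 100:.1f}%",
            "rd_mean": r.rd_mean,
            "rd_ci_low": r.rd_ci_low,
            "rd_ci_high": r.rd_ci_high,
        })
    return pd.DataFrame(rows)


def plot_sate(results, out_dir, formats=("svg",), prefix="sate"):
    """Forest-style RR panels per contrast and a predicted-probability panel.

    Returns the list of written figure paths; deterministic given inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    contrasts = sorted({r.contrast for r in results})
    fig, axes = plt.subplots(1, len(contrasts), figsize=(5 * len(contrasts), 4),
                             squeeze=False)
    for ax, contrast in zip(axes[0], contrasts):
        rows = [r for r in results if r.contrast == contrast]
        rows.sort(key=lambda r: (r.stratum == "pooled", r.stratum if
                                 r.stratum != "pooled" else -1))
        labels = [str(r.stratum) for r in rows]
        y = np.arange(len(rows))
        means = [r.rr_mean for r in rows]
        lo = [r.rr_mean - r.rr_ci_low for r in rows]
        hi = [r.rr_ci_high - r.rr_mean for r in rows]
        ax.errorbar(means, y, xerr=[lo, hi], fmt="o", capsize=3)
        ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
        ax.set_yticks(y, labels)
        ax.set_ylabel("Apfel score")
        ax.set_xlabel("relative risk of PONV")
        ax.set_title(contrast.replace("_", " "))
        ax.invert_yaxis()
    fig.tight_layout()
    for ext in formats:
        p = out_dir / f"{prefix}_rr.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)

    # predicted-probability panel (treated and control means per group)
    fig, ax = plt.subplots(figsize=(6, 4))
    rows = [r for r in results if r.contrast == contrasts[-1]]
    labels = [str(r.stratum) for r in rows]
    x = np.arange(len(rows))
    ax.plot(x, [r.p_control_mean for r in rows], "o-", label="none")
    for contrast in contrasts:
        sub = [r for r in results if r.contrast == contrast]
        ax.plot(x, [r.p_treated_mean for r in sub], "s--",
                label=contrast.split("_vs_")[0])
    ax.set_xticks(x, labels)
    ax.set_xlabel("Apfel score / pooled")
    ax.set_ylabel("mean predicted P(PONV)")
    ax.legend()
    fig.tight_layout()
    for ext in formats:
        p = out_dir / f"{prefix}_probability.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    return paths
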