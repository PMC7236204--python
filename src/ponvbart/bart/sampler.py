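"""Probit BART: sum-of-trees binary regression via backfitting MCMC.

The model is P(y=1 | x) = Φ(Σ_j g(x; T_j) + offset), fitted with the
latent-normal augmentation of Albert & Chib: each sweep redraws the latent
z_i from a unit-variance normal centred on the current ensemble fit,
truncated to the positive half-line where y_i = 1 and the negative
half-line where y_i = 0; the trees are then updated one at a time against
the partial residual of all other trees, each by a single
Metropolis–Hastings structural proposal followed by a conjugate redraw of
its leaf values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

from . import moves, trees
from .moves import draw_leaf_values, propose_move
from .trees import TreeNode, clone, evaluate, make_cutpoint_grids

__all__ = ["BartConfig", "BartPosterior", "fit_pbart", "sample_truncated_normal"]

_FORMAT_VERSION = 1
# Φ underflows to exactly 0/1 beyond ~|8.3|; the latent sum is clipped there
# so predicted probabilities stay strictly inside (0, 1).
_LATENT_CLIP = 8.2


@dataclass
class BartConfig:
    """Sampler settings.

    Defaults mirror the conventional binary-BART choices: 50 trees, leaf
    prior scale sigma_mu = 3/(k sqrt(m)) with k=2, depth prior
    α(1+d)^(−β) with α=0.95, β=2, and 1000 retained draws after 100
    burn-in sweeps.
    """

    m: int = 50
    k: float = 2.0
    alpha: float = 0.95
    beta: float = 2.0
    ndpost: int = 1000
    nskip: int = 100
    move_probs: tuple = (0.25, 0.25, 0.40, 0.10)  # grow, prune, change, swap
    n_cutpoints: int = 100
    seed: int = 0
    offset: float | None = None  # None -> Phi^{-1}(mean(y))

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.ndpost < 1:
            raise ValueError("ndpost must be >= 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move_probs must sum to 1")

    @property
    def sigma_mu2(self) -> float:
        sigma_mu = 3.0 / (self.k * np.sqrt(self.m))
        return sigma_mu ** 2


def sample_truncated_normal(mean: np.ndarray, positive: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Unit-variance normals truncated to a sign-constrained half-line.

    Rows with ``positive`` True are drawn from N(mean, 1) restricted to
    (0, inf), the rest from (-inf, 0).  Inverse-CDF sampling carried out in
    log space so the far tail (|mean| large with the constraint on the
    unlikely side) stays finite and correctly signed.
    """
    mean = np.asarray(mean, dtype=float)
    log_u = np.log(rng.uniform(size=mean.shape))
    t = np.empty_like(mean)
    pos = np.asarray(positive, dtype=bool)
    # standardized draw t = z - mean; lower bound -mean where y=1, upper where y=0
    t[pos] = -ndtri_exp(log_u[pos] + log_ndtr(mean[pos]))
    t[~pos] = ndtri_exp(log_u[~pos] + log_ndtr(-mean[~pos]))
    return mean + t


class BartPosterior:
    """Retained ensemble states of a fitted probit BART model."""

    def __init__(self, draws, offset, grids, columns, config):
        self.draws = draws            # list (ndpost) of lists (m) of TreeNode
        self.offset = float(offset)
        self.grids = grids
        self.columns = list(columns)
        self.config = config

    @property
    def ndpost(self) -> int:
        return len(self.draws)

    def _coerce(self, Xnew) -> np.ndarray:
        if isinstance(Xnew, pd.DataFrame):
            missing = [c for c in self.columns if c not in Xnew.columns]
            extra = [c for c in Xnew.columns if c not in self.columns]
            if missing or extra:
                raise ValueError(
                    f"covariate columns do not match training columns; "
                    f"missing={missing}, extra={extra}")
            return Xnew[self.columns].to_numpy(dtype=float)
        X = np.asarray(Xnew, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} covariate columns, "
                f"got shape {X.shape}")
        return X

    def predict_latent(self, Xnew) -> np.ndarray:
        """Per-draw latent sums G_s(x) + offset, shape (ndpost, n)."""
        X = self._coerce(Xnew)
        out = np.empty((len(self.draws), X.shape[0]))
        for s, ensemble in enumerate(self.draws):
            g = np.zeros(X.shape[0])
            for tree in ensemble:
                g += evaluate(tree, X, self.grids)
            out[s] = g + self.offset
        return out

    def predict(self, Xnew) -> np.ndarray:
        """Per-draw outcome probabilities Φ(G_s(x) + offset), shape (ndpost, n)."""
        lat = np.clip(self.predict_latent(Xnew), -_LATENT_CLIP, _LATENT_CLIP)
        return ndtr(lat)

    def predict_mean(self, Xnew) -> np.ndarray:
        return self.predict(Xnew).mean(axis=0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        cfg = {k: getattr(self.config, k) for k in
               ("m", "k", "alpha", "beta", "ndpost", "nskip", "n_cutpoints",
                "seed")}
        cfg["move_probs"] = list(self.config.move_probs)
        cfg["offset"] = self.config.offset
        return {
            "format_version": _FORMAT_VERSION,
            "model": "probit-bart",
            "offset": self.offset,
            "columns": self.columns,
            "grids": [g.tolist() for g in self.grids],
            "config": cfg,
            "draws": [[trees.tree_to_dict(t) for t in ens]
                      for ens in self.draws],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BartPosterior":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unrecognized ensemble format version")
        cfg = d["config"]
        config = BartConfig(
            m=cfg["m"], k=cfg["k"], alpha=cfg["alpha"], beta=cfg["beta"],
            ndpost=cfg["ndpost"], nskip=cfg["nskip"],
            move_probs=tuple(cfg["move_probs"]),
            n_cutpoints=cfg["n_cutpoints"], seed=cfg["seed"],
            offset=cfg["offset"])
        draws = [[trees.tree_from_dict(t) for t in ens] for ens in d["draws"]]
        grids = [np.asarray(g) for g in d["grids"]]
        return cls(draws, d["offset"], grids, d["columns"], config)

    @classmethod
    def load(cls, path) -> "BartPosterior":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _validate_inputs(X, y):
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(Xa.shape[1])]
    if Xa.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    bad = np.where(~np.isfinite(Xa).all(axis=0))[0]
    if bad.size:
        raise ValueError(
            f"non-finite covariate values in column(s) "
            f"{[columns[j] for j in bad]}")
    ya = np.asarray(y)
    if ya.shape[0] != Xa.shape[0]:
        raise ValueError("X and y have different lengths")
    if not np.isin(ya, (0, 1)).all():
        raise ValueError("y must be coded 0/1")
    if ya.min() == ya.max():
        raise ValueError(
            "y contains a single class; a probit model needs both outcomes "
            "present — check the outcome coding or the cohort filters")
    return Xa, ya.astype(int), columns


def fit_pbart(X, y, config: BartConfig | None = None) -> BartPosterior:
    """Fit the probit sum-of-trees model by backfitting MCMC.

    Runs ``nskip + ndpost`` sweeps and retains the final ``ndpost``
    ensemble states.  Fully reproducible given ``config.seed``.
    """
    config = config or BartConfig()
    Xa, ya, columns = _validate_inputs(X, y)
    n = Xa.shape[0]
    rng = np.random.default_rng(config.seed)
    grids = make_cutpoint_grids(Xa, config.n_cutpoints)
    offset = (ndtri(ya.mean()) if config.offset is None else config.offset)
    sigma_mu2 = config.sigma_mu2
    move_probs = np.asarray(config.move_probs, dtype=float)

    ensemble = [TreeNode(mu=0.0) for _ in range(config.m)]
    fits = np.zeros((config.m, n))
    total = np.zeros(n)
    positive = ya == 1
    draws = []

    for sweep in range(config.nskip + config.ndpost):
        z = sample_truncated_normal(total + offset, positive, rng)
        for j in range(config.m):
            residual = z - offset - total + fits[j]
            cand, log_a = propose_move(
                ensemble[j], Xa, grids, residual, rng,
                move_probs=move_probs, alpha=config.alpha, beta=config.beta,
                sigma_mu2=sigma_mu2)
            if cand is not ensemble[j] and np.log(rng.uniform()) < log_a:
                ensemble[j] = cand
            new_fit = draw_leaf_values(ensemble[j], Xa, grids, residual,
                                       sigma_mu2, rng)
            total += new_fit - fits[j]
            fits[j] = new_fit
        if sweep >= config.nskip:
            draws.append([clone(t) for t in ensemble])

    return BartPosterior(draws, offset, grids, columns, config)
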