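"""Node dating from a phylogram under a strict clock or penalized likelihood.

Both methods convert branch lengths in expected substitutions per site into
node ages in Ma using an externally supplied substitution rate
(substitutions * site^-1 * yr^-1).  The canonical rate grid pairs three COI
rates (6.5e-9, 7.5e-9, 9.5e-9) and one COI+tRNA+COII rate (11.5e-9) with the
two methods, giving eight dating runs whose per-node mean is the consensus
age estimate.

Penalized likelihood follows the Sanderson-style objective: a Poisson
log-likelihood for the expected number of substitutions on each branch minus
a smoothing penalty on rate differences between parent and child branches.
Absent fossil calibrations, the time scale is pinned by constraining the
tree-wide mean rate (total substitutions / total branch time) to the
configured rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .trees import Phylogeny

__all__ = [
    "COI_RATES",
    "COMBINED_RATE",
    "ClockConfig",
    "DatedNodeAges",
    "default_rate_grid",
    "strict_clock_ages",
    "pl_smooth_ages",
    "mean_ages",
]

# substitutions site^-1 yr^-1
COI_RATES: Tuple[float, ...] = (6.5e-9, 7.5e-9, 9.5e-9)
COMBINED_RATE: float = 11.5e-9  # COI + leu-tRNA + COII


@dataclass(frozen=True)
class ClockConfig:
    method: str  # "strict" | "penalized_likelihood"
    rate: float  # subs site^-1 yr^-1
    marker: str = "COI"
    smoothing: Optional[float] = None  # PL only
    sites: int = 1  # alignment length for PL substitution counts
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("strict", "penalized_likelihood"):
            raise ValueError(f"unknown dating method {self.method!r}")
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.method == "penalized_likelihood":
            if self.smoothing is None or self.smoothing <= 0:
                raise ValueError("penalized likelihood requires smoothing > 0")
            if self.sites < 1:
                raise ValueError("sites must be a positive integer")


@dataclass
class DatedNodeAges:
    """Ages (Ma before present) per post-order node ID, with provenance."""

    ages: np.ndarray  # Ma, tips 0
    config: ClockConfig
    branch_rates: Optional[np.ndarray] = None  # PL only; subs/site/yr per branch
    n_nodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_nodes = len(self.ages)

    def age_of(self, node: int) -> float:
        return float(self.ages[node])


def default_rate_grid() -> List[ClockConfig]:
    """The eight method-by-rate dating configurations."""
    grid: List[ClockConfig] = []
    for method in ("strict", "penalized_likelihood"):
        for rate, marker in [(r, "COI") for r in COI_RATES] + [
            (COMBINED_RATE, "COI+tRNA+COII")
        ]:
            smoothing = 1.0 if method == "penalized_likelihood" else None
            grid.append(ClockConfig(method=method, rate=rate, marker=marker,
                                    smoothing=smoothing))
    return grid


def _check_phylogram(tree: Phylogeny) -> None:
    tree.require_unit("subs/site", "clock dating")
    if np.any(tree.branch_length < 0):
        raise ValueError("negative branch lengths")
    if tree.depths().max() <= 0:
        raise ValueError("zero-depth tree cannot be dated")


def strict_clock_ages(tree: Phylogeny, config: ClockConfig) -> DatedNodeAges:
    """Date nodes by averaging tip-to-node path lengths and dividing by rate.

    For each interior node, the expected substitutions to its tips are averaged
    (which enforces ultrametricity), converted to years via the configured
    rate, and reported in Ma.  Parent >= child order is enforced by clamping
    upward along the post-order pass.
    """
    if config.method != "strict":
        raise ValueError("config.method must be 'strict'")
    _check_phylogram(tree)
    depths = tree.depths()
    below = tree.node_tips()
    ages = np.zeros(tree.n_nodes)
    for node in tree.postorder():
        if tree.is_tip(node):
            continue
        mean_path = float(np.mean([depths[t] - depths[node] for t in below[node]]))
        age = mean_path / config.rate / 1e6
        kids_max = max(ages[c] for c in tree.children[node])
        ages[node] = max(age, kids_max)
    return DatedNodeAges(ages=ages, config=config)


def _pl_objective(theta: np.ndarray, tree: Phylogeny, n_subs: np.ndarray,
                  smoothing: float, total_time: float, sites: int,
                  internal: np.ndarray) -> float:
    """Negative PL objective over (interior node height proportions, log rates)."""
    n_int = len(internal)
    props = 1.0 / (1.0 + np.exp(-theta[:n_int]))  # node height as fraction of parent
    log_r = theta[n_int:]
    ages = _ages_from_props(tree, props, internal)
    # rescale so total branch time is fixed (pins the mean rate)
    tt = _total_time(tree, ages)
    if tt <= 0:
        return 1e12
    ages = ages * (total_time / tt)
    rates = np.exp(log_r)  # subs/site/Ma
    obj = 0.0
    for node in range(tree.n_nodes - 1):  # every non-root branch
        dt = ages[tree.parent[node]] - ages[node]
        mu = rates[node] * max(dt, 1e-12) * sites  # expected substitution count
        obj += n_subs[node] * np.log(mu) - mu
        p = tree.parent[node]
        if tree.parent[p] >= 0:
            obj -= smoothing * (rates[p] - rates[node]) ** 2
        else:
            # root has no branch: penalize differences among root's children
            pass
    kids = tree.children[tree.root]
    for a, b in zip(kids[:-1], kids[1:]):
        obj -= smoothing * (rates[a] - rates[b]) ** 2
    return -obj


def _ages_from_props(tree: Phylogeny, props: np.ndarray,
                     internal: np.ndarray) -> np.ndarray:
    """Map (0,1) proportions to node ages; root fixed at 1, tips at 0."""
    ages = np.zeros(tree.n_nodes)
    pos = {int(n): i for i, n in enumerate(internal)}
    ages[tree.root] = 1.0
    for node in tree.preorder():
        if tree.is_tip(node) or node == tree.root:
            continue
        ages[node] = ages[tree.parent[node]] * props[pos[node]]
    return ages


def _total_time(tree: Phylogeny, ages: np.ndarray) -> float:
    return float(sum(ages[tree.parent[n]] - ages[n] for n in range(tree.n_nodes - 1)))


def pl_smooth_ages(tree: Phylogeny, config: ClockConfig) -> DatedNodeAges:
    """Penalized-likelihood rate smoothing with the mean rate pinned to config.rate.

    Jointly optimizes interior node times and per-branch rates; multi-start
    quasi-Newton on (logit height proportions, log rates).  Raises if no start
    converges.
    """
    if config.method != "penalized_likelihood":
        raise ValueError("config.method must be 'penalized_likelihood'")
    _check_phylogram(tree)
    n_subs = tree.branch_length[: tree.n_nodes - 1] * config.sites
    if np.all(n_subs <= 0):
        raise ValueError("all branch substitution counts are zero")
    n_subs = np.maximum(n_subs, 1e-10)  # guard log(0) for zero-length branches

    internal = np.array([n for n in range(tree.n_nodes)
                         if not tree.is_tip(n) and n != tree.root], dtype=int)
    n_int = len(internal)
    n_branch = tree.n_nodes - 1

    # pin the time scale: total branch time such that mean rate == config.rate
    total_subs = float(np.sum(n_subs)) / config.sites
    total_time_yr = total_subs / config.rate
    total_time = total_time_yr / 1e6  # work in Ma

    # strict-clock solution as the reference start
    strict = strict_clock_ages(tree, ClockConfig("strict", config.rate))
    rng = np.random.default_rng(config.seed)

    best = None
    for start in range(config.restarts):
        if start == 0 and n_int > 0:
            p0 = np.array([
                np.clip(strict.ages[n] / max(strict.ages[tree.parent[n]], 1e-12),
                        1e-3, 1 - 1e-3)
                for n in internal
            ])
            theta0 = np.concatenate([np.log(p0 / (1 - p0)),
                                     np.full(n_branch, np.log(config.rate * 1e6))])
        else:
            theta0 = np.concatenate([
                rng.normal(0, 1, n_int),
                np.log(config.rate * 1e6) + rng.normal(0, 0.5, n_branch),
            ])
        res = minimize(
            _pl_objective, theta0,
            args=(tree, n_subs, config.smoothing, total_time, config.sites, internal),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("penalized-likelihood optimization failed to converge")

    props = 1.0 / (1.0 + np.exp(-best.x[:n_int]))
    ages = _ages_from_props(tree, props, internal)
    ages *= total_time / _total_time(tree, ages)
    rates_ma = np.exp(best.x[n_int:])  # subs/site/Ma
    return DatedNodeAges(ages=ages, config=config, branch_rates=rates_ma / 1e6)


def mean_ages(runs: Sequence[DatedNodeAges], nodes: Iterable[int]) -> pd.DataFrame:
    """Summarize node ages across dating runs: mean, min, max, per-run values."""
    runs = list(runs)
    if not runs:
        raise ValueError("no dating runs given")
    n = runs[0].n_nodes
    if any(r.n_nodes != n for r in runs):
        raise ValueError("dating runs disagree on topology (node counts differ)")
    rows = []
    for node in nodes:
        vals = np.array([r.ages[node] for r in runs])
        row: Dict[str, object] = {
            "node_id": int(node),
            "age_mean": float(vals.mean()),
            "age_min": float(vals.min()),
            "age_max": float(vals.max()),
        }
        for i, r in enumerate(runs):
            row[f"run{i}_{r.config.method}_{r.config.rate:g}"] = float(vals[i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("node_id")
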