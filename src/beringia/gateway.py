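"""Headline analyses at the Beringian gateway.

Combines the dated colonization nodes, their reconstructed thermal-tolerance
ranges and the calibrated paleotemperature curve into two tests:

* a cooling trend — do younger colonizers tolerate colder conditions?
  (exact permutation test of the age/tolerance correlation; with five events
  the exhaustive null has 120 orderings, so the smallest one-sided p is
  1/120 ≈ 0.0083);
* a gateway match — does each ancestor's tolerance interval contain the
  Beringian temperature at its crossing time?

Also provides maximum-parsimony reconstruction of the (unordered,
multistate) hostplant-family character via minimum-change optimization.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .paleo import PaleoCurve
from .trees import Phylogeny

__all__ = [
    "ColonizationEvent",
    "TrendResult",
    "MatchReport",
    "tolerance_trend_test",
    "beringia_match",
    "fitch_mp",
    "plot_gateway",
]


@dataclass
class ColonizationEvent:
    """One Old-World -> New-World crossing: dated node with tolerances."""

    clade: str
    node: int
    age_ma: float
    t_cold: float
    t_warm: float
    ci_cold: Optional[Tuple[float, float]] = None
    ci_warm: Optional[Tuple[float, float]] = None
    route: str = "north_pacific"
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_ma <= 0:
            raise ValueError(f"event {self.clade}: age must be > 0")
        if self.t_cold > self.t_warm:
            warnings.warn(
                f"event {self.clade}: T_cold > T_warm (reported, not fixed)",
                stacklevel=2)


@dataclass
class TrendResult:
    statistic: float  # correlation between age and the chosen character
    p_value: float  # one-sided, direction: younger -> colder
    method: str
    n: int
    character: str

    def summary(self) -> str:
        return (f"trend test on {self.character} (n={self.n}, {self.method}): "
                f"r={self.statistic:.4f}, one-sided p={self.p_value:.5f}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return float("nan")
    return float(xc @ yc) / denom


def tolerance_trend_test(events: Sequence[ColonizationEvent],
                         character: str = "cold",
                         method: str = "exact_permutation",
                         rank_based: bool = False,
                         n_resamples: int = 100_000,
                         seed: int = 0) -> TrendResult:
    """Test whether tolerance declines with colonization recency.

    The statistic is the Pearson correlation between event age and the chosen
    character (``cold``, ``warm`` or ``range_width``); under the "younger
    implies colder" alternative the observed correlation should be large and
    positive.  ``exact_permutation`` enumerates all orderings for n <= 7
    (Monte-Carlo beyond); ``t_test`` uses the asymptotic one-sided t
    distribution of the correlation.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events")
    ages = np.array([e.age_ma for e in events], dtype=float)
    if len(set(ages)) < len(ages):
        raise ValueError("event ages must be distinct")
    if character == "cold":
        vals = np.array([e.t_cold for e in events])
    elif character == "warm":
        vals = np.array([e.t_warm for e in events])
    elif character == "range_width":
        vals = np.array([e.t_warm - e.t_cold for e in events])
    else:
        raise ValueError(f"unknown character {character!r}")

    if rank_based:
        ages = np.argsort(np.argsort(ages)).astype(float)
        vals = np.argsort(np.argsort(vals)).astype(float)

    r_obs = _pearson(ages, vals)
    n = len(events)
    if math.isnan(r_obs):
        warnings.warn("character values are constant; correlation undefined, p=1",
                      stacklevel=2)
        return TrendResult(statistic=float("nan"), p_value=1.0, method=method,
                           n=n, character=character)

    if method == "exact_permutation":
        if n <= 7:
            perms = itertools.permutations(vals)
            count = 0
            total = 0
            for p in perms:
                total += 1
                if _pearson(ages, np.array(p)) >= r_obs - 1e-12:
                    count += 1
            p_value = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 1  # observed ordering counts
            for _ in range(n_resamples):
                if _pearson(ages, rng.permutation(vals)) >= r_obs - 1e-12:
                    count += 1
            p_value = count / (n_resamples + 1)
    elif method == "t_test":
        from scipy.stats import t as tdist
        tstat = r_obs * math.sqrt((n - 2) / max(1 - r_obs ** 2, 1e-12))
        p_value = float(tdist.sf(tstat, n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrendResult(statistic=r_obs, p_value=float(p_value), method=method,
                       n=n, character=character)


@dataclass
class MatchReport:
    clade: str
    age_ma: float
    beringia_temp_c: float
    t_cold: float
    t_warm: float
    match: bool
    distance_c: float  # 0 when inside the tolerance interval


def beringia_match(events: Sequence[ColonizationEvent], curve: PaleoCurve,
                   margin: float = 0.0) -> List[MatchReport]:
    """Does each ancestor's tolerance interval contain the Beringian
    temperature at its crossing time (within `margin` °C)?"""
    out: List[MatchReport] = []
    for e in events:
        try:
            temp = curve.temp_at(e.age_ma)
        except ValueError as exc:
            raise ValueError(
                f"event {e.clade!r} at {e.age_ma} Ma is outside the "
                f"paleocurve span") from exc
        lo, hi = e.t_cold - margin, e.t_warm + margin
        inside = lo <= temp <= hi
        if inside:
            dist = 0.0
        else:
            dist = (lo - temp) if temp < lo else (temp - hi)
        out.append(MatchReport(clade=e.clade, age_ma=e.age_ma,
                               beringia_temp_c=temp, t_cold=e.t_cold,
                               t_warm=e.t_warm, match=inside,
                               distance_c=float(dist)))
    return out


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def fitch_mp(tree: Phylogeny, tip_states: Dict[str, str],
             nodes: Optional[Iterable[int]] = None,
             ) -> Tuple[Dict[int, FrozenSet[str]], int]:
    """Minimum-change (unit-cost) reconstruction of an unordered character.

    Returns ``(state sets, score)`` where each node's set contains exactly
    the states that occur at that node in at least one globally most
    parsimonious assignment (so tips with unambiguous codings map to
    singletons), and `score` is the minimal number of changes.  Polytomies
    are handled exactly by the unit-cost dynamic program.
    """
    missing = set(tree.tip_labels) - set(tip_states)
    if missing:
        raise KeyError(f"tips without character codings: {sorted(missing)}")
    states = sorted(set(tip_states.values()))
    pos = {s: i for i, s in enumerate(states)}
    k = len(states)
    INF = float("inf")
    up = np.full((tree.n_nodes, k), INF)
    for node in tree.postorder():
        if tree.is_tip(node):
            up[node] = INF
            up[node, pos[tip_states[tree.labels[node]]]] = 0.0
        else:
            tot = np.zeros(k)
            for c in tree.children[node]:
                child_min = up[c].min()
                tot += np.minimum(up[c], child_min + 1.0)
            up[node] = tot
    score = int(up[tree.root].min())
    # downward pass: cost of the rest of the tree given the node's state
    down = np.full((tree.n_nodes, k), INF)
    down[tree.root] = 0.0
    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        kids = tree.children[node]
        contrib = {c: np.minimum(up[c], up[c].min() + 1.0) for c in kids}
        # cost at parent-state i excluding child c
        for c in kids:
            others = down[node].copy()
            for s in kids:
                if s != c:
                    others = others + contrib[s]
            # transition from parent state i to child state j costs (i != j)
            best_same = others  # i == j
            best_diff = others.min() + 1.0
            down[c] = np.minimum(best_same, best_diff)
    sets: Dict[int, FrozenSet[str]] = {}
    wanted = list(nodes) if nodes is not None else list(range(tree.n_nodes))
    for node in wanted:
        total = up[node] + down[node]
        best = total.min()
        sets[node] = frozenset(states[i] for i in range(k)
                               if total[i] <= best + 1e-9)
    return sets, score


def plot_gateway(events: Sequence[ColonizationEvent], curve: PaleoCurve,
                 path: str) -> None:
    """Tolerance ranges of the colonizing ancestors against the paleocurve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.age_ma, curve.temp_c, color="crimson", lw=1.5,
            label="Beringia paleotemperature")
    for e in events:
        ax.vlines(e.age_ma, e.t_cold, e.t_warm, color="steelblue", lw=3, alpha=0.8)
        ax.plot([e.age_ma], [(e.t_cold + e.t_warm) / 2], "o", color="navy", ms=4)
        ax.annotate(e.clade, (e.age_ma, e.t_warm), fontsize=7,
                    textcoords="offset points", xytext=(2, 3))
    ax.set_xlabel("age (Ma before present)")
    ax.set_ylabel("mean annual temperature (°C)")
    ax.invert_xaxis()
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
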