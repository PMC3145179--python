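"""Dispersal–extinction–cladogenesis (DEC) ancestral range reconstruction.

The model follows the classic likelihood formulation of range evolution:
anagenetic change along branches is a continuous-time Markov chain over
geographic ranges (subsets of a fixed area list) in which a range expands
into area *a* at rate ``d * sum(multiplier[b][a] for b in range)`` and loses
any one of its areas at rate *e*; at speciation (cladogenesis) the parental
range is partitioned among the daughters under the standard DEC scenarios
(identical inheritance for single-area ranges; single-area sympatric subset
or allopatric vicariance for larger ranges), all scenarios equally weighted.

The default geography is the ten-region system used for Polyommatus blues —
Africa, Australia, Central America–Caribbean, East Nearctic, East
Palaearctic, Northern South America, Oriental, Southern South America, West
Nearctic, West Palaearctic — with dispersal permitted between land
neighbours plus the two transoceanic routes: East Palaearctic <-> West
Nearctic across the north Pacific (Beringia) and West Palaearctic <-> East
Nearctic across the north Atlantic.

``DECModel(tree, tip_ranges).fit()`` returns a :class:`DECResults` carrying
the ML dispersal/extinction rates, per-node marginal range probabilities, the
joint ML range history, and the dispersal events read off that history —
from which Old-World -> New-World crossings are counted.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny, TaxonTable, join_table

__all__ = [
    "DEFAULT_AREAS",
    "OLD_WORLD",
    "NEW_WORLD",
    "AreaSet",
    "DECParams",
    "DispersalEvent",
    "DECModel",
    "DECResults",
    "default_area_set",
    "count_crossings",
]

DEFAULT_AREAS: Tuple[str, ...] = (
    "Africa",
    "Australia",
    "CentralAmerica-Caribbean",
    "EastNearctic",
    "EastPalaearctic",
    "NorthernSouthAmerica",
    "Oriental",
    "SouthernSouthAmerica",
    "WestNearctic",
    "WestPalaearctic",
)

OLD_WORLD: Tuple[str, ...] = (
    "Africa", "Australia", "EastPalaearctic", "Oriental", "WestPalaearctic",
)
NEW_WORLD: Tuple[str, ...] = (
    "CentralAmerica-Caribbean", "EastNearctic", "NorthernSouthAmerica",
    "SouthernSouthAmerica", "WestNearctic",
)

# (area, area, route) — bidirectional
DEFAULT_ROUTES: Tuple[Tuple[str, str, str], ...] = (
    ("WestPalaearctic", "EastPalaearctic", "land-neighbour"),
    ("WestPalaearctic", "Africa", "land-neighbour"),
    ("EastPalaearctic", "Oriental", "land-neighbour"),
    ("Oriental", "Australia", "land-neighbour"),
    ("Africa", "Oriental", "land-neighbour"),
    ("WestNearctic", "EastNearctic", "land-neighbour"),
    ("WestNearctic", "CentralAmerica-Caribbean", "land-neighbour"),
    ("EastNearctic", "CentralAmerica-Caribbean", "land-neighbour"),
    ("CentralAmerica-Caribbean", "NorthernSouthAmerica", "land-neighbour"),
    ("NorthernSouthAmerica", "SouthernSouthAmerica", "land-neighbour"),
    ("EastPalaearctic", "WestNearctic", "north_pacific"),
    ("WestPalaearctic", "EastNearctic", "north_atlantic"),
)


@dataclass
class AreaSet:
    """Ordered area list with a symmetric adjacency and per-edge route tags."""

    areas: Tuple[str, ...] = DEFAULT_AREAS
    routes: Tuple[Tuple[str, str, str], ...] = DEFAULT_ROUTES

    def __post_init__(self) -> None:
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("area names must be unique")
        idx = {a: i for i, a in enumerate(self.areas)}
        n = len(self.areas)
        adj = np.zeros((n, n), dtype=bool)
        route: Dict[Tuple[int, int], str] = {}
        for a, b, tag in self.routes:
            if a not in idx or b not in idx:
                raise ValueError(f"route references unknown area: {(a, b)}")
            i, j = idx[a], idx[b]
            if i == j:
                raise ValueError("self-adjacency is not allowed")
            adj[i, j] = adj[j, i] = True
            route[(i, j)] = route[(j, i)] = tag
        self.index = idx
        self.adjacency = adj
        self.route_of = route

    @property
    def n(self) -> int:
        return len(self.areas)

    def names(self, rng: FrozenSet[int]) -> Tuple[str, ...]:
        return tuple(self.areas[i] for i in sorted(rng))

    @classmethod
    def from_edge_csv(cls, path_or_buf,
                      areas: Tuple[str, ...] = DEFAULT_AREAS) -> "AreaSet":
        df = pd.read_csv(path_or_buf)
        routes = tuple(
            (str(r.area_a), str(r.area_b), str(r.route)) for r in df.itertuples()
        )
        return cls(areas=areas, routes=routes)


def default_area_set() -> AreaSet:
    return AreaSet()


@dataclass
class DECParams:
    """Dispersal and extinction rates (events/Ma) plus the dispersal multipliers."""

    d: float
    e: float
    multiplier: Optional[np.ndarray] = None  # defaults to adjacency as 0/1

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("dispersal and extinction rates must be >= 0")


@dataclass(frozen=True)
class DispersalEvent:
    branch: int  # child-node post-order ID of the branch
    source_area: str
    gained_area: str
    route: str
    parent_age: float
    child_age: float


class _StateSpace:
    """Enumerated range states: non-empty subsets of size <= cap, plus null."""

    def __init__(self, n_areas: int, cap: int,
                 adjacency: Optional[np.ndarray] = None):
        if cap < 1 or cap > n_areas:
            raise ValueError(f"max range size must be in [1, {n_areas}]")
        self.cap = cap
        ranges: List[FrozenSet[int]] = []
        for k in range(1, cap + 1):
            for comb in itertools.combinations(range(n_areas), k):
                ranges.append(frozenset(comb))
        self.ranges = ranges  # observable states
        self.null_index = len(ranges)
        self.n_states = len(ranges) + 1
        self.index = {r: i for i, r in enumerate(ranges)}
        # root prior support: ranges forming a connected subgraph of the
        # dispersal graph (a disjunct range cannot arise by dispersal)
        if adjacency is None:
            self.root_allowed = np.ones(len(ranges), dtype=bool)
        else:
            self.root_allowed = np.array(
                [_connected(r, adjacency) for r in ranges])

    def of(self, rng: FrozenSet[int]) -> int:
        return self.index[rng]


def _connected(rng: FrozenSet[int], adjacency: np.ndarray) -> bool:
    members = sorted(rng)
    if len(members) <= 1:
        return True
    seen = {members[0]}
    frontier = [members[0]]
    while frontier:
        a = frontier.pop()
        for b in members:
            if b not in seen and adjacency[a, b]:
                seen.add(b)
                frontier.append(b)
    return len(seen) == len(members)


def _build_q(space: _StateSpace, areas: AreaSet, params: DECParams) -> np.ndarray:
    mult = params.multiplier
    if mult is None:
        mult = areas.adjacency.astype(float)
    n = space.n_states
    Q = np.zeros((n, n))
    for i, rng in enumerate(space.ranges):
        # contraction (including to null for single-area ranges)
        for a in rng:
            smaller = rng - {a}
            j = space.null_index if not smaller else space.index[smaller]
            Q[i, j] += params.e
        # expansion
        if len(rng) < space.cap:
            for a in range(areas.n):
                if a in rng:
                    continue
                rate = params.d * sum(mult[b, a] for b in rng)
                if rate > 0:
                    Q[i, space.index[rng | {a}]] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_q_matrix(areas: AreaSet, params: DECParams, max_range_size: int) -> np.ndarray:
    """Anagenetic DEC rate matrix over all range states (null last, absorbing)."""
    space = _StateSpace(areas.n, max_range_size, areas.adjacency)
    return _build_q(space, areas, params)


def _cladogenetic_scenarios(rng: FrozenSet[int]) -> List[Tuple[FrozenSet[int], FrozenSet[int]]]:
    """Equal-weight daughter-range pairs for a parental range (classic DEC)."""
    if len(rng) == 1:
        return [(rng, rng)]
    out: List[Tuple[FrozenSet[int], FrozenSet[int]]] = []
    for a in rng:
        single = frozenset({a})
        rest = rng - single
        # allopatric vicariance
        out.append((single, rest))
        out.append((rest, single))
        # sympatric subset: one daughter keeps the full range
        out.append((single, rng))
        out.append((rng, single))
    return out


def _binarize(tree: Phylogeny) -> Phylogeny:
    """Resolve polytomies with zero-length branches; keeps original IDs valid.

    Returns a tree whose first len(tree) post-order slots map one-to-one onto
    the original nodes (guaranteed by inserting the helper nodes as extra
    parents late in post-order via reconstruction)."""
    if all(len(c) <= 2 for c in tree.children):
        return tree
    # rebuild child lists, splitting any polytomy into a left-leaning comb
    new_children: Dict[int, List[int]] = {}
    extra_parent: Dict[int, int] = {}
    next_id = tree.n_nodes
    lengths = list(tree.branch_length)
    orig_parent = list(tree.parent)
    for node in range(tree.n_nodes):
        kids = list(tree.children[node])
        while len(kids) > 2:
            a = kids.pop(0)
            b = kids.pop(0)
            h = next_id
            next_id += 1
            new_children[h] = [a, b]
            lengths.append(0.0)
            orig_parent.append(node)
            extra_parent[a] = h
            extra_parent[b] = h
            kids.insert(0, h)
        new_children[node] = kids
    total = next_id
    parent = np.full(total, -1, dtype=int)
    for node in range(total):
        for c in new_children.get(node, []):
            parent[c] = node
    # re-sort into post-order
    children_map = {n: tuple(new_children.get(n, ())) for n in range(total)}
    order: List[int] = []

    def visit(n: int) -> None:
        for c in children_map[n]:
            visit(c)
        order.append(n)

    root_old = tree.root
    visit(root_old)
    remap = {old: new for new, old in enumerate(order)}
    parent2 = np.full(total, -1, dtype=int)
    lengths2 = np.zeros(total)
    children2: List[Tuple[int, ...]] = [()] * total
    labels2: List[Optional[str]] = [None] * total
    for old in range(total):
        new = remap[old]
        if parent[old] >= 0:
            parent2[new] = remap[parent[old]]
        lengths2[new] = lengths[old]
        children2[new] = tuple(remap[c] for c in children_map[old])
        labels2[new] = tree.labels[old] if old < tree.n_nodes else None
    binar = Phylogeny(parent2, tuple(children2), lengths2, tuple(labels2),
                      tree.length_unit, {})
    binar._orig_map = {remap[old]: old for old in range(tree.n_nodes)}  # type: ignore[attr-defined]
    return binar


def parse_range(text: str, areas: AreaSet) -> FrozenSet[int]:
    parts = [p.strip() for p in str(text).split(";") if p.strip()]
    unknown = [p for p in parts if p not in areas.index]
    if unknown:
        raise ValueError(f"unknown area names: {unknown}")
    if not parts:
        raise ValueError("empty tip range")
    return frozenset(areas.index[p] for p in parts)


class DECModel:
    """ML dispersal–extinction–cladogenesis model on a chronogram.

    Parameters
    ----------
    tree : Phylogeny with branch lengths in Ma.
    tip_ranges : TaxonTable with an ``areas`` column of semicolon-separated
        area names, or a mapping {tip label: iterable of area names}.
    areas : geography (defaults to the ten-region system).
    max_range_size : cap on simultaneous areas per lineage (default 2).
    """

    def __init__(self, tree: Phylogeny, tip_ranges, areas: Optional[AreaSet] = None,
                 max_range_size: int = 2):
        tree.require_unit("Ma", "DEC reconstruction")
        self.areas = areas if areas is not None else default_area_set()
        self.space = _StateSpace(self.areas.n, max_range_size,
                                 self.areas.adjacency)
        self.max_range_size = max_range_size
        self.original_tree = tree
        self.tree = _binarize(tree)

        if isinstance(tip_ranges, TaxonTable):
            frame, _ = join_table(tree, tip_ranges, columns=["areas"], strict=True)
            mapping = {t: parse_range(v, self.areas)
                       for t, v in frame["areas"].items()}
        else:
            mapping = {t: frozenset(self.areas.index[a] for a in v)
                       for t, v in dict(tip_ranges).items()}
        missing = set(tree.tip_labels) - set(mapping)
        if missing:
            raise KeyError(f"tips without range codings: {sorted(missing)}")
        for t, rng in mapping.items():
            if not rng:
                raise ValueError(f"empty range for tip {t!r}")
            if len(rng) > max_range_size:
                raise ValueError(
                    f"tip {t!r} range exceeds max_range_size={max_range_size}")
        self.tip_ranges = mapping

    # -- likelihood machinery ---------------------------------------------
    def _branch_p(self, params: DECParams) -> Dict[int, np.ndarray]:
        Q = _build_q(self.space, self.areas, params)
        mats: Dict[int, np.ndarray] = {}
        cache: Dict[float, np.ndarray] = {}
        for node in range(self.tree.n_nodes - 1):
            t = float(self.tree.branch_length[node])
            if t not in cache:
                cache[t] = expm(Q * t)
            mats[node] = cache[t]
        return mats

    def _tip_vector(self, node: int) -> np.ndarray:
        v = np.zeros(self.space.n_states)
        rng = self.tip_ranges[self.tree.labels[node]]
        v[self.space.of(rng)] = 1.0
        return v

    def _inside(self, P: Dict[int, np.ndarray]) -> np.ndarray:
        """L_below[node, state]: P(data below node | node in state)."""
        tr = self.tree
        n_states = self.space.n_states
        L = np.zeros((tr.n_nodes, n_states))
        branch_up: Dict[int, np.ndarray] = {}
        for node in tr.postorder():
            if tr.is_tip(node):
                L[node] = self._tip_vector(node)
            else:
                kids = tr.children[node]
                assert len(kids) == 2
                bl = {c: P[c] @ L[c] for c in kids}
                branch_up.update(bl)
                for i, rng in enumerate(self.space.ranges):
                    scen = _cladogenetic_scenarios(rng)
                    w = 1.0 / len(scen)
                    tot = 0.0
                    for sl, sr in scen:
                        tot += bl[kids[0]][self.space.of(sl)] * bl[kids[1]][self.space.of(sr)]
                    L[node, i] = w * tot
                # null state contributes nothing at internal nodes
        self._branch_up = branch_up
        return L

    def loglik(self, params: DECParams) -> float:
        """Pruning log-likelihood with a uniform root prior over non-null ranges."""
        P = self._branch_p(params)
        L = self._inside(P)
        n_ranges = len(self.space.ranges)
        allowed = self.space.root_allowed
        lik = float(np.sum(L[self.tree.root, :n_ranges][allowed])) / int(allowed.sum())
        if lik <= 0:
            return -np.inf
        return float(np.log(lik))

    # -- fitting -----------------------------------------------------------
    def fit(self, starts: Sequence[Tuple[float, float]] = ((0.05, 0.05), (0.5, 0.1), (0.01, 0.5)),
            bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((1e-6, 20.0), (1e-6, 20.0)),
            ) -> "DECResults":
        log_bounds = [(np.log(lo), np.log(hi)) for lo, hi in bounds]

        def neg(theta: np.ndarray) -> float:
            p = DECParams(d=float(np.exp(theta[0])), e=float(np.exp(theta[1])))
            ll = self.loglik(p)
            return -ll if np.isfinite(ll) else 1e10  # keep the optimizer in range

        best = None
        for d0, e0 in starts:
            res = minimize(neg, np.log([d0, e0]), method="L-BFGS-B",
                           bounds=log_bounds, options={"maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("DEC rate optimization failed to converge")
        params = DECParams(d=float(np.exp(best.x[0])), e=float(np.exp(best.x[1])))
        return self.reconstruct(params, loglik=-float(best.fun))

    # -- reconstruction ----------------------------------------------------
    def reconstruct(self, params: DECParams, loglik: Optional[float] = None) -> "DECResults":
        P = self._branch_p(params)
        L = self._inside(P)
        marg = self._marginals(P, L)
        node_states, inherited = self._joint_ml(P)
        events = self._events_from_history(node_states, inherited)
        if loglik is None:
            loglik = self.loglik(params)
        return DECResults(model=self, params=params, loglik=loglik,
                          marginals=marg, node_states=node_states,
                          events=events)

    def _marginals(self, P: Dict[int, np.ndarray], L: np.ndarray) -> np.ndarray:
        """Outside pass: marginal P(node range | data) over observable ranges."""
        tr = self.tree
        n_states = self.space.n_states
        n_ranges = len(self.space.ranges)
        out = np.zeros((tr.n_nodes, n_states))
        allowed = self.space.root_allowed
        out[tr.root, :n_ranges][allowed] = 1.0 / int(allowed.sum())
        for node in tr.preorder():
            if tr.is_tip(node):
                continue
            kids = tr.children[node]
            bl = {c: P[c] @ L[c] for c in kids}
            for ci, c in enumerate(kids):
                sib = kids[1 - ci]
                # out-message to the top of c's branch
                top = np.zeros(n_states)
                for i, rng in enumerate(self.space.ranges):
                    if out[node, i] == 0:
                        continue
                    scen = _cladogenetic_scenarios(rng)
                    w = out[node, i] / len(scen)
                    for sl, sr in scen:
                        mine, theirs = (sl, sr) if ci == 0 else (sr, sl)
                        top[self.space.of(mine)] += w * bl[sib][self.space.of(theirs)]
                out[c] = top @ P[c]
        post = out * L
        tot = post.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return post / tot

    def _joint_ml(self, P: Dict[int, np.ndarray]) -> Tuple[Dict[int, FrozenSet[int]], Dict[int, FrozenSet[int]]]:
        """Max-product joint reconstruction.

        Returns (range at each node, range inherited at the top of each
        non-root branch)."""
        tr = self.tree
        n_ranges = len(self.space.ranges)
        best = np.zeros((tr.n_nodes, n_ranges))
        # back[node][i] = (scenario daughters, best child states)
        back: Dict[int, List[Tuple[Tuple[FrozenSet[int], FrozenSet[int]], Tuple[int, int]]]] = {}
        # bb[child][top-state] = best bottom state index
        bb: Dict[int, np.ndarray] = {}
        bscore: Dict[int, np.ndarray] = {}
        for node in tr.postorder():
            if tr.is_tip(node):
                v = self._tip_vector(node)[:n_ranges]
                best[node] = np.log(np.where(v > 0, v, 1e-300))
                continue
            kids = tr.children[node]
            for c in kids:
                M = np.log(np.maximum(P[c][:n_ranges, :n_ranges], 1e-300)) + best[c][None, :]
                bb[c] = np.argmax(M, axis=1)
                bscore[c] = np.max(M, axis=1)
            back[node] = []
            for i, rng in enumerate(self.space.ranges):
                scen = _cladogenetic_scenarios(rng)
                logw = -np.log(len(scen))
                bi, bv = None, -np.inf
                for sl, sr in scen:
                    s = (logw
                         + bscore[kids[0]][self.space.of(sl)]
                         + bscore[kids[1]][self.space.of(sr)])
                    if s > bv:
                        bv, bi = s, (sl, sr)
                best[node, i] = bv
                back[node].append((bi, (self.space.of(bi[0]), self.space.of(bi[1]))))
        root = tr.root
        root_score = np.where(self.space.root_allowed, best[root], -np.inf)
        root_i = int(np.argmax(root_score))
        node_states: Dict[int, FrozenSet[int]] = {root: self.space.ranges[root_i]}
        inherited: Dict[int, FrozenSet[int]] = {}
        stack = [(root, root_i)]
        while stack:
            node, i = stack.pop()
            if tr.is_tip(node):
                continue
            (sl, sr), _ = back[node][i]
            kids = tr.children[node]
            for c, s_top in zip(kids, (sl, sr)):
                inherited[c] = s_top
                j = int(bb[c][self.space.of(s_top)]) if c in bb else self.space.of(s_top)
                node_states[c] = self.space.ranges[j]
                stack.append((c, j))
        return node_states, inherited

    def _events_from_history(self, node_states: Dict[int, FrozenSet[int]],
                             inherited: Dict[int, FrozenSet[int]]) -> List[DispersalEvent]:
        tr = self.tree
        depths = tr.depths()
        height = depths[list(tr.tips)].max()
        orig_map = getattr(tr, "_orig_map", {i: i for i in range(tr.n_nodes)})
        events: List[DispersalEvent] = []
        for node in range(tr.n_nodes - 1):
            start = inherited[node]
            end = node_states[node]
            if start == end:
                continue
            path = self._state_path(start, end)
            cur = start
            for step in path:
                gained = step - cur
                for a in sorted(gained):
                    src, route = self._gain_source(cur, a)
                    events.append(DispersalEvent(
                        branch=orig_map.get(node, node),
                        source_area=self.areas.areas[src],
                        gained_area=self.areas.areas[a],
                        route=route,
                        parent_age=float(height - depths[tr.parent[node]]),
                        child_age=float(height - depths[node]),
                    ))
                cur = step
        return events

    def _gain_source(self, rng: FrozenSet[int], gained: int) -> Tuple[int, str]:
        mult = self.areas.adjacency
        cands = sorted(b for b in rng if mult[b, gained])
        if not cands:
            return (min(rng), "unresolved")
        src = cands[0]
        return (src, self.areas.route_of.get((src, gained), "unresolved"))

    def _state_path(self, start: FrozenSet[int], end: FrozenSet[int]) -> List[FrozenSet[int]]:
        """Shortest single-gain/loss path in range space, adjacency-respecting."""
        if start == end:
            return []
        adj = self.areas.adjacency
        cap = self.max_range_size
        prev: Dict[FrozenSet[int], FrozenSet[int]] = {}
        seen = {start}
        q = deque([start])
        while q:
            cur = q.popleft()
            neigh: List[FrozenSet[int]] = []
            if len(cur) < cap:
                reach = sorted({a for b in cur for a in range(self.areas.n)
                                if adj[b, a] and a not in cur})
                neigh.extend(cur | {a} for a in reach)
            if len(cur) > 1:
                neigh.extend(cur - {a} for a in sorted(cur))
            for nxt in neigh:
                if nxt in seen:
                    continue
                seen.add(nxt)
                prev[nxt] = cur
                if nxt == end:
                    path = [nxt]
                    while path[-1] != start:
                        path.append(prev[path[-1]])
                    return list(reversed(path))[1:]
                q.append(nxt)
        return [end]  # disconnected geography; net change recorded as-is


@dataclass
class DECResults:
    """Fitted DEC reconstruction: rates, per-node ranges, dispersal events."""

    model: DECModel
    params: DECParams
    loglik: float
    marginals: np.ndarray  # [node, state] posterior over ranges (binarized tree)
    node_states: Dict[int, FrozenSet[int]]
    events: List[DispersalEvent] = field(default_factory=list)

    def ml_range(self, node: int) -> Tuple[Tuple[str, ...], float]:
        """ML range (area names) and its relative likelihood at an original node."""
        tr = self.model.tree
        orig_map = getattr(tr, "_orig_map", None)
        if orig_map is not None:
            inv = {v: k for k, v in orig_map.items()}
            node = inv[node]
        n_ranges = len(self.model.space.ranges)
        probs = self.marginals[node, :n_ranges]
        i = int(np.argmax(probs))
        return self.model.areas.names(self.model.space.ranges[i]), float(probs[i])

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.events])

    def summary(self) -> str:
        lines = [
            "DEC ancestral range reconstruction",
            f"  areas: {self.model.areas.n}, max range size: {self.model.max_range_size}",
            f"  dispersal rate d = {self.params.d:.4g} /Ma",
            f"  extinction rate e = {self.params.e:.4g} /Ma",
            f"  log-likelihood = {self.loglik:.4f}",
            f"  dispersal events inferred: {len(self.events)}",
        ]
        for ev in self.events:
            lines.append(
                f"    branch {ev.branch}: {ev.source_area} -> {ev.gained_area}"
                f" via {ev.route}"
            )
        return "\n".join(lines)


def count_crossings(results: DECResults, from_group: Iterable[str],
                    to_group: Iterable[str]) -> Tuple[int, List[DispersalEvent]]:
    """Count dispersal events whose source is in `from_group` and gained area
    in `to_group` (e.g. Old World -> New World)."""
    frm = set(from_group)
    to = set(to_group)
    if not frm or not to:
        raise ValueError("area groups must be non-empty")
    hits = [e for e in results.events
            if e.source_area in frm and e.gained_area in to]
    return len(hits), hits
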