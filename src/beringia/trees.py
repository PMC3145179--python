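"""Rooted phylogenies with stable post-order node IDs, plus taxon-table plumbing.

The package keeps trees in a small array-backed structure rather than passing
dendropy objects around: every downstream stage (dating, range reconstruction,
trait models) addresses nodes by a post-order integer ID that is fixed at parse
time, so results from different stages can be joined without re-matching
topology.  Newick reading/writing is delegated to dendropy; validation that the
pipeline needs (unique tip labels, non-negative branch lengths, a single root)
is layered on top.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TaxonTable",
    "NewickParseError",
    "UnitError",
    "read_newick",
    "write_newick",
    "mrca",
    "join_table",
]


class NewickParseError(ValueError):
    """Raised when a newick string violates the strict dialect accepted here."""


class UnitError(ValueError):
    """Raised when branch-length units do not match what a stage requires."""


VALID_UNITS = ("subs/site", "Ma", "unitless")


@dataclass
class Phylogeny:
    """A rooted tree indexed in post-order.

    Nodes are numbered 0 .. n_nodes-1 in post-order (children before parents,
    root last).  Tips keep their labels; interior newick labels, when present,
    are stored as annotations.

    Attributes
    ----------
    parent : int array, parent[i] = post-order ID of i's parent, -1 for root.
    children : tuple of tuples, children[i] in original (newick) child order.
    branch_length : float array, length of the edge above node i (root: 0.0).
    labels : tuple of str or None per node (tips always labelled).
    length_unit : one of "subs/site", "Ma", "unitless".
    """

    parent: np.ndarray
    children: Tuple[Tuple[int, ...], ...]
    branch_length: np.ndarray
    labels: Tuple[Optional[str], ...]
    length_unit: str = "unitless"
    annotations: Dict[int, str] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tips(self) -> np.ndarray:
        """Post-order IDs of the leaves."""
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def tip_labels(self) -> Tuple[str, ...]:
        return tuple(self.labels[i] for i in self.tips)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def tip_index(self) -> Dict[str, int]:
        return {self.labels[i]: i for i in self.tips}

    # -- metrics -----------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, in the tree's length unit."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            if self.parent[node] >= 0:
                d[node] = d[self.parent[node]] + self.branch_length[node]
        return d

    def node_tips(self) -> List[List[int]]:
        """For each node, the tip IDs in its subtree (post-order accumulation)."""
        below: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for node in self.postorder():
            if self.is_tip(node):
                below[node] = [node]
            else:
                acc: List[int] = []
                for c in self.children[node]:
                    acc.extend(below[c])
                below[node] = acc
        return below

    def ancestors(self, node: int) -> List[int]:
        """Path of ancestors from `node` (exclusive) up to and incl. the root."""
        out = []
        p = self.parent[node]
        while p >= 0:
            out.append(int(p))
            p = self.parent[p]
        return out

    def with_unit(self, unit: str) -> "Phylogeny":
        if unit not in VALID_UNITS:
            raise UnitError(f"unknown length unit {unit!r}; expected one of {VALID_UNITS}")
        return Phylogeny(self.parent, self.children, self.branch_length.copy(),
                         self.labels, unit, dict(self.annotations))

    def require_unit(self, unit: str, context: str = "") -> None:
        if self.length_unit != unit:
            where = f" in {context}" if context else ""
            raise UnitError(
                f"branch lengths are in {self.length_unit!r} but {unit!r} is required{where}"
            )

    def scale_lengths(self, factor: float, unit: Optional[str] = None) -> "Phylogeny":
        out = Phylogeny(self.parent, self.children, self.branch_length * factor,
                        self.labels, unit or self.length_unit, dict(self.annotations))
        return out


def _validate(tree: Phylogeny) -> None:
    labs = [l for l in tree.tip_labels]
    if any(l is None or l == "" for l in labs):
        raise NewickParseError("every tip must carry a non-empty label")
    seen = set()
    for l in labs:
        if l in seen:
            raise NewickParseError(f"duplicate tip label {l!r}")
        seen.add(l)
    neg = np.where(tree.branch_length < 0)[0]
    if neg.size:
        i = int(neg[0])
        name = tree.labels[i] or f"node #{i}"
        raise NewickParseError(
            f"negative branch length {tree.branch_length[i]} above {name}"
        )


def _from_dendropy(dtree: dendropy.Tree, unit: str) -> Phylogeny:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: List[Tuple[int, ...]] = []
    labels: List[Optional[str]] = []
    annotations: Dict[int, str] = {}
    for i, nd in enumerate(order):
        kids = tuple(index[id(c)] for c in nd.child_nodes())
        children.append(kids)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            labels.append(lab)
        else:
            labels.append(None)
            if nd.label:
                annotations[i] = nd.label
    tree = Phylogeny(parent, tuple(children), lengths, tuple(labels), unit, annotations)
    _validate(tree)
    return tree


def read_newick(text: str, unit: str = "unitless") -> Phylogeny:
    """Parse a single rooted newick statement into a :class:`Phylogeny`.

    Polytomies are preserved; interior labels become node annotations;
    comments in ``[...]`` are ignored.  Duplicate tip labels, negative branch
    lengths and malformed newick raise :class:`NewickParseError`.
    """
    if unit not in VALID_UNITS:
        raise UnitError(f"unknown length unit {unit!r}; expected one of {VALID_UNITS}")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree, unit)


def _node_newick(tree: Phylogeny, node: int, fmt: str) -> str:
    if tree.is_tip(node):
        core = tree.labels[node]
    else:
        inner = ",".join(_node_newick(tree, c, fmt) for c in tree.children[node])
        core = f"({inner})" + tree.annotations.get(node, "")
    if tree.parent[node] >= 0:
        return core + ":" + (fmt % tree.branch_length[node])
    return core


def write_newick(tree: Phylogeny, digits: int = 10) -> str:
    """Serialize a :class:`Phylogeny`; lengths rendered to `digits` sig. digits."""
    return _node_newick(tree, tree.root, f"%.{digits}g") + ";"


def mrca(tree: Phylogeny, tips: Iterable[str]) -> int:
    """Most recent common ancestor (post-order ID) of a set of tip labels."""
    labels = list(tips)
    if not labels:
        raise ValueError("mrca of an empty tip set is undefined")
    idx = tree.tip_index()
    missing = [l for l in labels if l not in idx]
    if missing:
        raise KeyError(f"labels not found among tips: {missing}")
    ids = {idx[l] for l in labels}
    if len(ids) == 1:
        return ids.pop()
    # count, for every node, how many target tips lie below it; the MRCA is
    # the smallest post-order ID covering all of them
    count = np.zeros(tree.n_nodes, dtype=int)
    for i in ids:
        count[i] = 1
    for node in tree.postorder():
        for c in tree.children[node]:
            count[node] += count[c]
    k = len(ids)
    for node in tree.postorder():
        if count[node] == k:
            return int(node)
    raise AssertionError("unreachable: root covers all tips")


@dataclass
class TaxonTable:
    """Per-taxon data keyed by tip label, carried as a pandas DataFrame.

    The index holds taxon labels (unique); columns are typed by pandas.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon keys: {dups}")

    @classmethod
    def from_csv(cls, path_or_buf, key: str = "taxon", sep: str = ",") -> "TaxonTable":
        df = pd.read_csv(path_or_buf, sep=sep)
        if key not in df.columns:
            raise ValueError(f"missing key column {key!r}")
        return cls(df.set_index(key))

    @property
    def taxa(self) -> Tuple[str, ...]:
        return tuple(self.data.index)


def join_table(
    tree: Phylogeny,
    table: TaxonTable,
    columns: Optional[Sequence[str]] = None,
    strict: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Align a :class:`TaxonTable` to a tree's tips in post-order.

    Returns ``(frame, report)`` where `frame` has one row per tip in canonical
    (post-order) tip order and `report` lists taxa found only in the table or
    only on the tree.  In strict mode any mismatch raises with the full list.
    """
    tip_order = [tree.labels[i] for i in tree.tips]
    table_keys = set(table.taxa)
    tree_keys = set(tip_order)
    report = {
        "missing_from_table": sorted(tree_keys - table_keys),
        "missing_from_tree": sorted(table_keys - tree_keys),
    }
    if strict and (report["missing_from_table"] or report["missing_from_tree"]):
        raise KeyError(
            "tree/table mismatch: "
            f"tips without rows {report['missing_from_table']}; "
            f"rows without tips {report['missing_from_tree']}"
        )
    cols = list(columns) if columns is not None else list(table.data.columns)
    present = [t for t in tip_order if t in table_keys]
    frame = table.data.loc[present, cols]
    return frame, report
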