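"""Time-calibrated trees and aligned trait tables.

The internal :class:`Phylogeny` is a flat array representation of a rooted
tree: tips occupy node indices ``0 .. n_tips-1`` (in ``tip_labels`` order),
internal nodes follow. Time runs from 0 at the crown root to ``depth`` (T)
at the present; ``node_age`` is time before present.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TraitVector",
    "LineageCountFunction",
    "TreeValidationError",
    "read_tree",
    "write_tree",
    "standardize_depth",
    "lineage_count",
    "extract_midpoint_subclades",
    "read_trait_table",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural or temporal invariant."""


@dataclass
class TraitVector:
    """A continuous trait, one value per tip, aligned to a tree's tip order."""

    values: np.ndarray
    trait_name: str = "trait"
    tip_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trait {self.trait_name!r} contains non-finite values")


class Phylogeny:
    """Rooted, edge-length-annotated phylogeny in flat-array form.

    Parameters
    ----------
    tip_labels:
        Unique species identifiers; tip ``i`` is node ``i``.
    parent:
        Parent node index per node; -1 for the root.
    edge_length:
        Length of the edge subtending each node (0 for the root).
    """

    def __init__(self, tip_labels, parent, edge_length):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        self._validate_topology()
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes):
            if self.parent[node] >= 0:
                self.children[self.parent[node]].append(node)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        # time from the root, per node
        self.node_time = np.zeros(self.n_nodes)
        for node in self._preorder():
            if node != self.root:
                self.node_time[node] = (
                    self.node_time[self.parent[node]] + self.edge_length[node]
                )
        self.depth = float(self.node_time[: self.n_tips].max())

    # -- construction helpers -------------------------------------------------

    def _validate_topology(self):
        if self.n_tips < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeValidationError("duplicate tip labels")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.edge_length < 0):
            raise TreeValidationError("negative edge length")

    def _preorder(self):
        order = []
        stack = [int(np.flatnonzero(self.parent < 0)[0])]
        kids = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes):
            if self.parent[node] >= 0:
                kids[self.parent[node]].append(node)
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(kids[node]))
        return order

    def preorder(self):
        """Node indices root-first; children visited in input order."""
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return order

    def postorder(self):
        return list(reversed(self.preorder()))

    @property
    def node_age(self) -> np.ndarray:
        """Time before present per node (root age = depth on ultrametric trees)."""
        return self.depth - self.node_time

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        tip_times = self.node_time[: self.n_tips]
        return float(tip_times.max() - tip_times.min()) <= rtol * self.depth

    def require_ultrametric(self, what: str = "this operation"):
        if not self.is_ultrametric():
            raise TreeValidationError(f"{what} requires an ultrametric tree")

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # -- queries ---------------------------------------------------------------

    def tip_descendants(self) -> list[np.ndarray]:
        """Per node, the sorted array of descendant tip indices (self for tips)."""
        desc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in self.postorder():
            if node < self.n_tips:
                desc[node] = [node]
            else:
                for child in self.children[node]:
                    desc[node].extend(desc[child])
        return [np.array(sorted(d), dtype=int) for d in desc]

    def shared_time_matrix(self) -> np.ndarray:
        """t_ij: time from the root to the MRCA of tips i and j.

        Diagonal holds each tip's total path time (= depth when ultrametric).
        """
        n = self.n_tips
        t = np.zeros((n, n))
        desc = self.tip_descendants()
        for node in self.preorder():
            if node < self.n_tips:
                t[node, node] = self.node_time[node]
                continue
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    da, db = desc[kids[a]], desc[kids[b]]
                    t[np.ix_(da, db)] = self.node_time[node]
                    t[np.ix_(db, da)] = self.node_time[node]
        return t

    def mrca(self, tips: np.ndarray) -> int:
        """MRCA node index of a set of tip indices."""
        tips = np.asarray(tips)
        desc = self.tip_descendants()
        best, best_size = self.root, self.n_tips + 1
        target = set(tips.tolist())
        for node in range(self.n_nodes):
            d = desc[node]
            if target.issubset(d.tolist()) and len(d) < best_size:
                best, best_size = node, len(d)
        return best

    def total_branch_length(self) -> float:
        return float(self.edge_length.sum())

    # -- transforms ------------------------------------------------------------

    def scaled(self, factor: float) -> "Phylogeny":
        return Phylogeny(self.tip_labels, self.parent.copy(), self.edge_length * factor)

    def extract_subtree(self, node: int) -> "Phylogeny":
        """The clade rooted at ``node`` as a standalone Phylogeny."""
        keep = []
        stack = [node]
        while stack:
            v = stack.pop()
            keep.append(v)
            stack.extend(self.children[v])
        keep_set = set(keep)
        tips = [v for v in sorted(keep_set) if v < self.n_tips]
        internals = [v for v in keep if v >= self.n_tips]
        new_index = {v: i for i, v in enumerate(tips)}
        for v in internals:
            new_index[v] = len(new_index)
        n_new = len(new_index)
        parent = np.full(n_new, -1, dtype=int)
        elen = np.zeros(n_new)
        for v in keep:
            i = new_index[v]
            if v != node:
                parent[i] = new_index[self.parent[v]]
                elen[i] = self.edge_length[v]
        return Phylogeny([self.tip_labels[v] for v in tips], parent, elen)

    def prune_to_tips(self, labels) -> "Phylogeny":
        """Restrict to the given tip labels, suppressing unary nodes."""
        keep_labels = set(labels)
        missing = keep_labels - set(self.tip_labels)
        if missing:
            raise TreeValidationError(f"labels not in tree: {sorted(missing)}")
        keep_tips = {i for i, lab in enumerate(self.tip_labels) if lab in keep_labels}
        if len(keep_tips) < 2:
            raise TreeValidationError("pruning would leave fewer than 2 tips")
        # mark nodes with >=1 kept descendant
        alive = np.zeros(self.n_nodes, dtype=bool)
        for node in self.postorder():
            if node < self.n_tips:
                alive[node] = node in keep_tips
            else:
                alive[node] = any(alive[c] for c in self.children[node])
        # new root: deepest node with >=2 alive children
        def alive_kids(v):
            return [c for c in self.children[v] if alive[c]]

        new_root = self.root
        while len(alive_kids(new_root)) == 1:
            new_root = alive_kids(new_root)[0]
        records = []  # (old_node, parent_old_node_in_new_tree, accumulated_len)

        def walk(v, anchor, acc):
            # anchor: nearest retained ancestor in the new tree
            kids = alive_kids(v)
            if v < self.n_tips or len(kids) >= 2 or v == new_root:
                records.append((v, anchor, acc))
                for c in kids:
                    walk(c, v, self.edge_length[c])
            else:
                walk(kids[0], anchor, acc + self.edge_length[kids[0]])

        walk(new_root, -1, 0.0)
        retained = [r[0] for r in records]
        tips = sorted(v for v in retained if v < self.n_tips)
        internals = [v for v in retained if v >= self.n_tips]
        new_index = {v: i for i, v in enumerate(tips)}
        for v in internals:
            new_index[v] = len(new_index)
        parent = np.full(len(new_index), -1, dtype=int)
        elen = np.zeros(len(new_index))
        for v, anchor, acc in records:
            if anchor >= 0:
                parent[new_index[v]] = new_index[anchor]
                elen[new_index[v]] = acc
        return Phylogeny([self.tip_labels[v] for v in tips], parent, elen)

    # -- serialization ---------------------------------------------------------

    def to_newick(self) -> str:
        def rec(node):
            if node < self.n_tips:
                return f"{self.tip_labels[node]}:{self.edge_length[node]:.17g}"
            inner = ",".join(rec(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{self.edge_length[node]:.17g}"

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<Phylogeny {self.n_tips} tips, depth {self.depth:.4g}>"


@dataclass
class LineageCountFunction:
    """Step function n(t): reconstructed lineages through time, t from the root.

    ``counts[k]`` applies on ``[breakpoints[k], breakpoints[k+1])`` with the
    implicit leading breakpoint 0 and trailing breakpoint T.
    """

    breakpoints: np.ndarray  # interior breakpoints, increasing, within (0, T)
    counts: np.ndarray  # len(breakpoints) + 1 interval counts
    depth: float

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.breakpoints) + 1:
            raise ValueError("counts must have one more entry than breakpoints")

    def count_at(self, t: float) -> int:
        return int(self.counts[np.searchsorted(self.breakpoints, t, side="right")])

    def intervals(self, t0: float = 0.0, t1: float | None = None):
        """(start, end, count) triples covering [t0, t1]."""
        if t1 is None:
            t1 = self.depth
        edges = np.concatenate(([t0], self.breakpoints[(self.breakpoints > t0) & (self.breakpoints < t1)], [t1]))
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            out.append((float(a), float(b), self.count_at(0.5 * (a + b))))
        return out


# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    dtree = dtree.clone(depth=1)
    n_resolved = 0
    for nd in dtree.preorder_node_iter():
        while len(nd._child_nodes) > 2:
            # deterministic, input-order resolution with a zero-length edge
            a = nd._child_nodes[0]
            b = nd._child_nodes[1]
            newn = dendropy.Node()
            newn.edge.length = 0.0
            nd.remove_child(a)
            nd.remove_child(b)
            newn.add_child(a)
            newn.add_child(b)
            nd.insert_child(0, newn)
            n_resolved += 1
    if n_resolved:
        warnings.warn(
            f"resolved {n_resolved} polytomies to binary with zero-length edges",
            stacklevel=3,
        )
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
    if any(lab is None for lab in labels):
        raise TreeValidationError("unlabeled tip")
    if len(set(labels)) != len(labels):
        raise TreeValidationError("duplicate tip labels")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    internal = [nd for nd in dtree.preorder_node_iter() if nd.child_nodes()]
    for nd in internal:
        index[id(nd)] = len(index)
    n_nodes = len(index)
    parent = np.full(n_nodes, -1, dtype=int)
    elen = np.zeros(n_nodes)
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
    return Phylogeny(labels, parent, elen)


def read_tree(source: str, format: str = "newick") -> Phylogeny:
    """Read a tree from a Newick/NEXUS string or file path.

    Polytomies are resolved to binary with zero-length edges (a warning is
    emitted). Tip labels must be unique.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        looks_like_path = "(" not in source and "#" not in source
        if looks_like_path:
            dtree = dendropy.Tree.get(path=source, schema=fmt)
        else:
            dtree = dendropy.Tree.get(data=source, schema=fmt)
    except (dendropy.utility.error.DataParseError, Exception) as exc:
        if isinstance(exc, (TreeValidationError,)):
            raise
        if isinstance(exc, FileNotFoundError):
            raise
        if exc.__class__.__module__.startswith("dendropy"):
            raise ValueError(f"could not parse tree as {format}: {exc}") from exc
        raise
    return _from_dendropy(dtree)


def write_tree(tree: Phylogeny, path: str | None = None) -> str:
    """Serialize to Newick; write to ``path`` when given, return the string."""
    text = tree.to_newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def standardize_depth(tree: Phylogeny, target: float = 1.0) -> Phylogeny:
    """Rescale all edge lengths so the root-to-tip depth equals ``target``."""
    if target <= 0:
        raise ValueError("target depth must be positive")
    if tree.depth <= 0:
        raise TreeValidationError("cannot rescale a zero-depth tree")
    return tree.scaled(target / tree.depth)


def lineage_count(tree: Phylogeny) -> LineageCountFunction:
    """Lineages-through-time step function of an ultrametric tree.

    The count is 2 on [0, first split) — the crown root's two daughters —
    and increases by one at every later internal-node time.
    """
    tree.require_ultrametric("lineage_count")
    internal_times = np.sort(
        tree.node_time[[v for v in range(tree.n_nodes) if v >= tree.n_tips and v != tree.root]]
    )
    counts = np.arange(2, 3 + len(internal_times))
    return LineageCountFunction(internal_times, counts, tree.depth)


def extract_midpoint_subclades(tree: Phylogeny, min_tips: int = 20) -> list[Phylogeny]:
    """Maximal monophyletic subclades younger than the mid-depth time slice.

    A candidate internal node must have crown age < T/2 (strictly younger
    than the slice) and at least ``min_tips`` descendant tips; only the most
    inclusive candidates are kept, so results are disjoint.
    """
    tree.require_ultrametric("extract_midpoint_subclades")
    half = tree.depth / 2.0
    desc = tree.tip_descendants()
    age = tree.node_age
    is_candidate = np.zeros(tree.n_nodes, dtype=bool)
    for node in range(tree.n_tips, tree.n_nodes):
        if age[node] < half and len(desc[node]) >= min_tips:
            is_candidate[node] = True
    keep = []
    for node in tree.preorder():
        if not is_candidate[node]:
            continue
        anc, blocked = tree.parent[node], False
        while anc >= 0:
            if is_candidate[anc]:
                blocked = True
                break
            anc = tree.parent[anc]
        if not blocked:
            keep.append(node)
    return [tree.extract_subtree(v) for v in keep]


def read_trait_table(
    path, tree: Phylogeny, prune: bool = False
) -> tuple[dict[str, TraitVector], Phylogeny]:
    """Read a CSV/TSV trait table and align every numeric column to the tree.

    The table must carry a ``species`` column. Species absent from the tree
    are dropped (logged via a warning). Tips without data raise unless
    ``prune=True``, in which case the pruned tree is returned alongside.
    """
    if isinstance(path, (str,)) and path.endswith((".tsv", ".txt")):
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    df = df.set_index("species")
    extra = [s for s in df.index if s not in set(tree.tip_labels)]
    if extra:
        warnings.warn(f"dropping {len(extra)} species not in tree", stacklevel=2)
        df = df.drop(index=extra)
    missing = [lab for lab in tree.tip_labels if lab not in df.index]
    out_tree = tree
    if missing:
        if not prune:
            raise ValueError(
                f"{len(missing)} tips lack trait data (pass prune=True to drop them)"
            )
        out_tree = tree.prune_to_tips([lab for lab in tree.tip_labels if lab in df.index])
    if len(df) < 2:
        raise TreeValidationError("fewer than 2 species overlap the tree")
    traits = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        aligned = vals.reindex(out_tree.tip_labels).to_numpy(dtype=float)
        traits[col] = TraitVector(aligned, trait_name=col, tip_labels=out_tree.tip_labels)
    return traits, out_tree
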