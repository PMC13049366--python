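"""Tree data model, Newick I/O, edge extraction and tree statistics.

Time runs backwards from the present: tips of an ultrametric tree sit at
time 0 and the root (first division) at ``t_root > 0``.  Every edge ``e``
is described by the interval ``(s_e, t_e)`` where ``t_e > s_e`` is the
older endpoint (the division that created the lineage) and ``s_e`` the
younger one (the next observed division, or 0 at a tip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

try:
    import dendropy
except ImportError:  # pragma: no cover
    dendropy = None

__all__ = [
    "TimeTree",
    "CompleteTree",
    "Forest",
    "read_newick",
    "read_nexus",
    "write_newick",
    "edge_intervals",
    "b1_index",
    "internal_branch_lengths",
    "empirical_estimates",
    "extract_subtree",
]


class TimeTree:
    """Rooted binary ultrametric phylogeny in backward time.

    Nodes are integer indices into parallel arrays.  ``parent[i]`` is -1
    for the root; ``children[i]`` is an empty tuple for tips.  ``times``
    holds backward times (tips at 0).  ``t_or``, if present, is the origin
    of the process (start of the stem lineage above the root).
    """

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[tuple],
        times: Sequence[float],
        labels: Sequence | None = None,
        t_or: float | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [tuple(c) for c in children]
        self.times = np.asarray(times, dtype=float)
        n_nodes = len(self.parent)
        if labels is None:
            labels = [None] * n_nodes
        self.labels = list(labels)
        self.t_or = None if t_or is None else float(t_or)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])

    # -- basic structure ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def n_tips(self) -> int:
        return int(sum(1 for c in self.children if not c))

    @property
    def t_root(self) -> float:
        return float(self.times[self.root])

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def validate(self, tolerance: float | None = None) -> None:
        """Check binarity, ultrametricity and time ordering."""
        for i in range(self.n_nodes):
            if self.children[i] and len(self.children[i]) != 2:
                name = self.labels[i] or f"node {i}"
                raise ValueError(f"non-binary node: {name} has {len(self.children[i])} children")
        tip_times = self.times[self.tip_indices]
        if tolerance is None:
            tolerance = 1e-6 * max(self.t_root, 1.0)
        if np.any(np.abs(tip_times) > tolerance):
            raise ValueError(
                f"not ultrametric: tip time spread {float(np.max(np.abs(tip_times))):g} "
                f"exceeds tolerance {tolerance:g}"
            )
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0 and self.times[p] < self.times[i]:
                raise ValueError(f"node {i} is older than its parent")
        internal_times = [self.times[i] for i in range(self.n_nodes) if self.children[i]]
        if internal_times and not np.isclose(self.t_root, max(internal_times)):
            raise ValueError("root is not the oldest internal node")
        if self.t_or is not None and self.t_or < self.t_root:
            raise ValueError("origin time precedes root time")

    def branch_length(self, i: int) -> float:
        """Length of the branch above node ``i`` (to its parent, or to the
        origin for the root when an origin time is set)."""
        p = self.parent[i]
        if p >= 0:
            return float(self.times[p] - self.times[i])
        if self.t_or is not None:
            return float(self.t_or - self.times[i])
        return 0.0

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), list(self.children), self.times.copy(),
                        list(self.labels), self.t_or)


class CompleteTree(TimeTree):
    """Full population tree from the simulator, including death tips.

    ``events[i]`` is ``"division"`` for internal nodes and ``"death"`` or
    ``"extant"`` for tips; ``sampled[i]`` is True for extant tips included
    in the rho-sample.  Not ultrametric: death tips end before the present.
    """

    def __init__(self, parent, children, times, events, sampled=None,
                 labels=None, t_or=None):
        super().__init__(parent, children, times, labels=labels, t_or=t_or)
        self.events = list(events)
        if sampled is None:
            sampled = np.zeros(self.n_nodes, dtype=bool)
        self.sampled = np.asarray(sampled, dtype=bool)
        for i in range(self.n_nodes):
            expected = {"division"} if self.children[i] else {"death", "extant"}
            if self.events[i] not in expected:
                raise ValueError(f"node {i}: event {self.events[i]!r} invalid here")

    @property
    def extant_tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes)
                         if not self.children[i] and self.events[i] == "extant"])

    def validate(self, tolerance: float | None = None) -> None:
        # death tips break ultrametricity by design; only check structure
        for i in range(self.n_nodes):
            if self.children[i] and len(self.children[i]) != 2:
                raise ValueError(f"non-binary node {i}")
            p = self.parent[i]
            if p >= 0 and self.times[p] < self.times[i]:
                raise ValueError(f"node {i} is older than its parent")


@dataclass
class Forest:
    """A collection of trees assumed to share one tree-generating process.

    ``conditioning`` is "origin" or "root" (applies to every tree); trees
    may carry individual fixed sampling probabilities (e.g. per-colony
    observed sampling fractions), overriding the shared rho.
    """

    trees: list
    conditioning: str = "root"
    rho_per_tree: list | None = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("forest must contain at least one tree")
        if self.conditioning not in ("origin", "root"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.rho_per_tree is not None and len(self.rho_per_tree) != len(self.trees):
            raise ValueError("rho_per_tree length mismatch")

    def __len__(self) -> int:
        return len(self.trees)


# -- Newick / NEXUS I/O -------------------------------------------------


def _from_dendropy(dtree, tolerance: float | None) -> TimeTree:
    if dtree.seed_node is None:
        raise ValueError("empty tree")
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[tuple] = [()] * n
    depth = np.zeros(n)
    labels: list = [None] * n
    for i, nd in enumerate(nodes):
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            name = nd.taxon.label if nd.taxon else (nd.label or f"node {i}")
            raise ValueError(f"non-binary node: {name} has {len(kids)} children")
        children[i] = tuple(index[id(c)] for c in kids)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        for c in kids:
            j = index[id(c)]
            parent[j] = i
            depth[j] = depth[i] + (c.edge.length or 0.0)
    tips = [i for i in range(n) if not children[i]]
    height = float(np.max(depth[tips]))
    if tolerance is None:
        tolerance = 1e-6 * max(height, 1.0)
    spread = float(np.max(depth[tips]) - np.min(depth[tips]))
    if spread > tolerance:
        raise ValueError(f"not ultrametric: tip depth spread {spread:g} > tolerance {tolerance:g}")
    times = height - depth
    times[tips] = 0.0  # snap rounding noise to the present
    stem = dtree.seed_node.edge.length
    t_or = height + stem if stem else None
    tree = TimeTree(parent, children, times, labels, t_or=t_or)
    tree.validate(tolerance)
    return tree


def read_newick(text: str, tolerance: float | None = None) -> TimeTree:
    """Parse a rooted binary ultrametric Newick string into a TimeTree.

    Branch lengths are converted to backward times so tips sit at time 0;
    a tip-depth spread up to ``tolerance`` (default 1e-6 x tree height) is
    flattened, anything larger raises "not ultrametric".  A root (stem)
    edge length, when present, sets the origin time ``t_or``.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True,
                              rooting="force-rooted")
    return _from_dendropy(dtree, tolerance)


def read_nexus(text: str, tolerance: float | None = None) -> list[TimeTree]:
    """Read all trees from a NEXUS trees block."""
    trees = dendropy.TreeList.get(data=text, schema="nexus", rooting="force-rooted")
    return [_from_dendropy(t, tolerance) for t in trees]


def write_newick(tree: TimeTree, include_stem: bool = True) -> str:
    """Serialize a TimeTree to Newick (branch lengths from node times)."""

    def rec(i: int) -> str:
        if tree.is_tip(i):
            body = str(tree.labels[i] if tree.labels[i] is not None else f"t{i}")
        else:
            body = "(" + ",".join(rec(c) for c in tree.children[i]) + ")"
        p = tree.parent[i]
        if p >= 0:
            return f"{body}:{tree.times[p] - tree.times[i]:.17g}"
        if include_stem and tree.t_or is not None:
            return f"{body}:{tree.t_or - tree.times[i]:.17g}"
        return body

    return rec(tree.root) + ";"


# -- edge extraction and statistics ------------------------------------


def edge_intervals(tree: TimeTree) -> tuple[list[tuple], list[tuple]]:
    """Backward-time intervals ``(s_e, t_e)`` of external and internal edges.

    The origin (stem) edge is *not* included; likelihood code appends it
    when conditioning on the origin.  For an n-tip tree this returns n
    external and n - 2 internal intervals.
    """
    external, internal = [], []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        iv = (float(tree.times[i]), float(tree.times[p]))
        (external if tree.is_tip(i) else internal).append(iv)
    return external, internal


def b1_index(tree: TimeTree, normalize: bool = False) -> float:
    """B1 balance index: sum over non-root interior nodes of ``1 / M_i``
    where ``M_i`` is the maximum edge count from node i down to a tip.

    If ``normalize``, the sum is divided by the number of tips.
    """
    if tree.n_tips < 2:
        raise ValueError("B1 requires at least 2 tips")
    m = np.zeros(tree.n_nodes, dtype=int)
    total = 0.0
    for i in tree.postorder():
        if tree.children[i]:
            m[i] = 1 + max(m[c] for c in tree.children[i])
            if i != tree.root:
                total += 1.0 / m[i]
    return total / tree.n_tips if normalize else total


def internal_branch_lengths(tree: TimeTree) -> np.ndarray:
    """Lengths ``t_e - s_e`` of internal edges (stem excluded)."""
    _, internal = edge_intervals(tree)
    return np.array([t - s for s, t in internal])


def empirical_estimates(trees: Iterable[CompleteTree]) -> tuple[float, float]:
    """Direct estimators of mean lifetime and death probability from
    complete population trees.

    ``ell_hat`` averages the lengths of fully observed lifetimes: branches
    ending in a division (internal branches, including the stem when the
    origin is known) and branches ending in a death/dropout.  Censored
    extant branches are excluded.  ``d_hat`` is #death / (#division +
    #death), pooled over all trees.
    """
    lengths: list[float] = []
    n_death = 0
    n_division = 0
    for tree in trees:
        for i in range(tree.n_nodes):
            ev = tree.events[i]
            if ev == "division":
                n_division += 1
            elif ev == "death":
                n_death += 1
            if ev == "extant":
                continue
            if tree.parent[i] >= 0 or tree.t_or is not None:
                lengths.append(tree.branch_length(i))
    if n_division + n_death == 0:
        raise ValueError("no division or death events in forest")
    if not lengths:
        raise ValueError("no fully observed lifetimes in forest")
    return float(np.mean(lengths)), n_death / (n_division + n_death)


def extract_subtree(tree: CompleteTree, keep_tips: Sequence[int]) -> TimeTree:
    """Reconstructed tree induced by a set of tip indices.

    Non-ancestral lineages are removed and single-child nodes suppressed;
    the origin time of the source tree is retained.  Requires >= 2 tips.
    """
    keep = set(int(i) for i in keep_tips)
    if len(keep) < 2:
        raise ValueError("unobservable tree: fewer than 2 sampled tips")
    n_desc = np.zeros(tree.n_nodes, dtype=int)
    for i in tree.postorder():
        if tree.is_tip(i):
            n_desc[i] = 1 if i in keep else 0
        else:
            n_desc[i] = sum(n_desc[c] for c in tree.children[i])

    new_parent: list[int] = []
    new_children: list[list[int]] = []
    new_times: list[float] = []
    new_labels: list = []

    def descend(i: int) -> int:
        # skip pass-through nodes with a single contributing child
        while tree.children[i]:
            live = [c for c in tree.children[i] if n_desc[c] > 0]
            if len(live) != 1:
                break
            i = live[0]
        return i

    stack = [(descend(tree.root), -1)]
    while stack:
        i, parent_new = stack.pop()
        j = len(new_parent)
        new_parent.append(parent_new)
        new_children.append([])
        new_times.append(float(tree.times[i]))
        new_labels.append(tree.labels[i])
        if parent_new >= 0:
            new_children[parent_new].append(j)
        for c in tree.children[i]:
            if n_desc[c] > 0:
                stack.append((descend(c), j))
    out = TimeTree(new_parent, [tuple(c) for c in new_children], new_times,
                   new_labels, t_or=tree.t_or)
    return out
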