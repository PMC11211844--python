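"""Lineage-tree data structure, Newick I/O, and tabular input readers.

The cell lineage tree is a rooted tree whose branch lengths measure time
between consecutive cell divisions.  The root is *unifurcating* (the
progenitor cell needs time before its first division) and every other
internal node is *bifurcating* (cells divide in two).  All sampled cells sit
at the leaves, at a common experiment-end time ``tau_end``, so valid trees
with node times assigned are exactly ultrametric.

Child order is meaningful: the first-listed child of a bifurcation ``u`` is
the "left" daughter and receives displacement sign ``+1`` in the
symmetric-displacement spatial model, the second receives ``-1``.  Order is
preserved through Newick round trips.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LineageTree",
    "NodeTimes",
    "Diagnostics",
    "parse_newick",
    "write_newick",
    "lca",
    "time_from_root",
    "is_ultrametric",
    "apply_node_times",
    "validate_inputs",
    "read_locations",
    "write_locations",
    "read_character_matrix",
    "write_character_matrix",
]

#: sentinel codes used in integer-encoded character matrices
MISSING = -2   # observed "?" (dropout or silenced)
SILENT = -1    # silenced (heritable missing) hidden state; unobservable


class TreeStructureError(ValueError):
    """Tree violates the unifurcating-root / bifurcating-internals contract."""


class LineageTree:
    """Rooted lineage tree with integer node ids and ordered children.

    Nodes are integers ``0..n-1`` with ``root`` id 0 after parsing.  Branch
    lengths (``branch_length[v]`` for non-root ``v``) measure time in the
    same unit as ``tau_end``; they may be unset (``None``) for
    topology-only trees.
    """

    def __init__(self):
        self.root: int = 0
        self.parent: dict[int, int] = {}          # non-root node -> parent
        self.children: dict[int, list[int]] = {}  # node -> ordered children
        self.branch_length: dict[int, float | None] = {}
        self.leaf_name: dict[int, str] = {}       # leaf node -> cell name
        self.label: dict[int, str] = {}           # optional internal labels

    # -- construction -----------------------------------------------------

    @classmethod
    def _empty(cls) -> "LineageTree":
        return cls()

    def _add_node(self, parent: int | None, length: float | None) -> int:
        nid = len(self.children)
        self.children[nid] = []
        if parent is not None:
            self.parent[nid] = parent
            self.children[parent].append(nid)
            self.branch_length[nid] = length
        return nid

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return list(self.children.keys())

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def is_leaf(self, v: int) -> bool:
        return len(self.children[v]) == 0

    def leaves(self) -> list[int]:
        return [v for v in self.preorder() if self.is_leaf(v)]

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.children if not self.children[v])

    def leaf_order(self) -> list[int]:
        """Leaves sorted lexicographically by cell name (declared order of
        all leaf-indexed vectors and matrices)."""
        return sorted(self.leaves(), key=lambda v: self.leaf_name[v])

    def preorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def postorder(self) -> list[int]:
        return list(reversed([v for v in self._rpost()]))

    def _rpost(self):
        # reverse postorder = preorder with children visited right-to-left
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def bifurcations(self) -> list[int]:
        return [v for v in self.preorder() if len(self.children[v]) == 2]

    def copy(self) -> "LineageTree":
        t = LineageTree()
        t.root = self.root
        t.parent = dict(self.parent)
        t.children = {k: list(v) for k, v in self.children.items()}
        t.branch_length = dict(self.branch_length)
        t.leaf_name = dict(self.leaf_name)
        t.label = dict(self.label)
        return t

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Raise if the structural invariants are violated."""
        if len(self.children[self.root]) != 1:
            raise TreeStructureError(
                f"root must have exactly one child, found "
                f"{len(self.children[self.root])}"
            )
        for v in self.preorder():
            nc = len(self.children[v])
            if v != self.root and nc not in (0, 2):
                raise TreeStructureError(
                    f"internal node {self.label.get(v, v)} has {nc} children; "
                    "only bifurcations are allowed below the root"
                )
        names = list(self.leaf_name.values())
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dup}")
        if any(not n for n in names):
            raise ValueError("empty leaf name")
        for v in self.parent:
            bl = self.branch_length.get(v)
            if bl is not None and bl < 0:
                raise ValueError(f"negative branch length on node {v}")

    def has_lengths(self) -> bool:
        return all(self.branch_length.get(v) is not None for v in self.parent)


@dataclass
class NodeTimes:
    """Time since the root for every node, plus the sampling horizon."""

    time: dict[int, float]
    tau_end: float


@dataclass
class Diagnostics:
    """Cross-validation report for a (tree, matrix, locations) triple."""

    missing_in_matrix: list[str] = field(default_factory=list)
    missing_in_locations: list[str] = field(default_factory=list)
    extra_in_matrix: list[str] = field(default_factory=list)
    extra_in_locations: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)
    pruned: bool = False

    def ok(self) -> bool:
        return not (
            self.missing_in_matrix
            or self.missing_in_locations
            or self.extra_in_matrix
            or self.extra_in_locations
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, strict: bool = True) -> LineageTree:
    """Parse a Newick string into a :class:`LineageTree`.

    In strict mode (default) the root must be unifurcating and all other
    internal nodes bifurcating.  With ``strict=False`` a bifurcating root is
    wrapped by a zero-length unifurcation above it (recorded in
    ``tree.label`` as an unlabeled node); any other arity still errors.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (ValueError, TypeError):
        raise
    except Exception as e:  # dendropy reader errors carry line/column info
        raise ValueError(f"malformed Newick: {e}") from None

    tree = LineageTree()

    def build(dnode, parent):
        nid = tree._add_node(parent, dnode.edge.length)
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            tree.leaf_name[nid] = name
        elif dnode.label:
            tree.label[nid] = dnode.label
        for ch in dnode.child_nodes():
            build(ch, nid)

    seed = dtree.seed_node
    if len(seed.child_nodes()) == 2:
        if strict:
            raise TreeStructureError(
                "root is bifurcating; lineage trees require a unifurcating "
                "root (the progenitor's pre-division edge). Re-parse with "
                "strict=False to wrap it in a zero-length unifurcation."
            )
        root = tree._add_node(None, None)
        nid = tree._add_node(root, 0.0)
        if seed.label:
            tree.label[nid] = seed.label
        for ch in seed.child_nodes():
            build(ch, nid)
        tree.label.setdefault(root, "")
    else:
        build(seed, None)
    tree.validate()
    return tree


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: LineageTree, topology_only: bool = False) -> str:
    """Serialize to Newick preserving child order and full float precision."""
    if not topology_only and not tree.has_lengths():
        raise ValueError(
            "tree has unset branch lengths; pass topology_only=True"
        )

    def rec(v: int) -> str:
        if tree.is_leaf(v):
            s = tree.leaf_name[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
            s += tree.label.get(v, "")
        if v != tree.root and not topology_only:
            s += ":" + _fmt_len(tree.branch_length[v])
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Tree queries
# ---------------------------------------------------------------------------

def _check_node(tree: LineageTree, v: int) -> None:
    if v not in tree.children:
        raise KeyError(f"unknown node {v}")


def lca(tree: LineageTree, v: int, w: int) -> int:
    """Deepest common ancestor of ``v`` and ``w`` (either may be an
    ancestor of the other)."""
    _check_node(tree, v)
    _check_node(tree, w)
    anc = set()
    a = v
    while True:
        anc.add(a)
        if a == tree.root:
            break
        a = tree.parent[a]
    a = w
    while a not in anc:
        a = tree.parent[a]
    return a


def time_from_root(tree: LineageTree, v: int) -> float:
    """Sum of branch lengths along the root-to-``v`` path (0 for the root)."""
    _check_node(tree, v)
    t = 0.0
    while v != tree.root:
        bl = tree.branch_length.get(v)
        if bl is None:
            raise ValueError("branch lengths are unset")
        t += bl
        v = tree.parent[v]
    return t


def node_depths(tree: LineageTree) -> dict[int, float]:
    """Times since root for all nodes, in one preorder pass."""
    depth = {tree.root: 0.0}
    for v in tree.preorder():
        if v == tree.root:
            continue
        bl = tree.branch_length.get(v)
        if bl is None:
            raise ValueError("branch lengths are unset")
        depth[v] = depth[tree.parent[v]] + bl
    return depth


def is_ultrametric(
    tree: LineageTree, tau_end: float, tol: float = 1e-6
) -> tuple[bool, float]:
    """Check that every leaf sits at ``tau_end``; returns (ok, max deviation).

    ``tol`` is relative to ``tau_end``.
    """
    depth = node_depths(tree)
    dev = max(abs(depth[v] - tau_end) for v in tree.leaves())
    return dev <= tol * abs(tau_end), dev


def apply_node_times(tree: LineageTree, times: NodeTimes) -> LineageTree:
    """Return a copy with branch lengths set from node times.

    ``times`` must place every child strictly later than its parent and is
    expected to place leaves at ``tau_end``; the result satisfies the
    common-sampling-time constraint exactly whenever the input does.
    """
    t = times.time
    out = tree.copy()
    for v in tree.preorder():
        if v == tree.root:
            continue
        d = t[v] - t[tree.parent[v]]
        if d <= 0:
            raise ValueError(
                f"node-time ordering violated on edge "
                f"({tree.parent[v]} -> {v}): parent at {t[tree.parent[v]]}, "
                f"child at {t[v]}"
            )
        out.branch_length[v] = d
    return out


def prune_to_leaves(tree: LineageTree, keep: set[str]) -> LineageTree:
    """Restrict the tree to the named leaves, collapsing the unifurcations
    this creates (their branch lengths are summed).  The root's own
    unifurcation is preserved."""
    t = tree.copy()
    # drop leaves not kept, repeatedly
    changed = True
    while changed:
        changed = False
        for v in list(t.children):
            if v not in t.children:
                continue
            if t.is_leaf(v) and v != t.root:
                name = t.leaf_name.get(v)
                if name is None or name not in keep:
                    p = t.parent[v]
                    t.children[p].remove(v)
                    for d in (t.children, t.parent, t.branch_length,
                              t.leaf_name, t.label):
                        d.pop(v, None)
                    changed = True
    # collapse internal unifurcations (not the root)
    for v in [n for n in t.preorder() if n != t.root]:
        if v in t.children and len(t.children[v]) == 1:
            c = t.children[v][0]
            p = t.parent[v]
            bl_v = t.branch_length.get(v)
            bl_c = t.branch_length.get(c)
            t.children[p][t.children[p].index(v)] = c
            t.parent[c] = p
            if bl_v is not None and bl_c is not None:
                t.branch_length[c] = bl_v + bl_c
            for d in (t.children, t.parent, t.branch_length, t.label):
                d.pop(v, None)
    t.validate()
    return t


def validate_inputs(
    tree: LineageTree,
    matrix=None,
    locations=None,
    prune: bool = False,
) -> tuple[LineageTree, Diagnostics]:
    """Cross-check leaf names across the tree, character matrix, and
    locations table.

    Returns the (possibly pruned) tree and a :class:`Diagnostics`.  Without
    ``prune`` any name mismatch raises; with ``prune`` the tree is restricted
    to the intersection of the name sets (which must be non-empty) and the
    action is logged in the diagnostics.
    """
    diag = Diagnostics()
    tree_names = {tree.leaf_name[v] for v in tree.leaves()}
    sets = {"tree": tree_names}
    if matrix is not None:
        sets["matrix"] = set(matrix.cells)
    if locations is not None:
        sets["locations"] = set(locations.names)

    common = set.intersection(*sets.values())
    if matrix is not None:
        diag.missing_in_matrix = sorted(tree_names - sets["matrix"])
        diag.extra_in_matrix = sorted(sets["matrix"] - tree_names)
    if locations is not None:
        diag.missing_in_locations = sorted(tree_names - sets["locations"])
        diag.extra_in_locations = sorted(sets["locations"] - tree_names)

    if diag.ok():
        return tree, diag
    if not common:
        raise ValueError("no cell name is shared by all inputs")
    if not prune:
        raise ValueError(
            "leaf-name mismatch across inputs: "
            f"missing in matrix {diag.missing_in_matrix}, "
            f"missing in locations {diag.missing_in_locations}, "
            f"extra in matrix {diag.extra_in_matrix}, "
            f"extra in locations {diag.extra_in_locations}; "
            "pass prune=True to intersect"
        )
    pruned = prune_to_leaves(tree, common)
    diag.pruned = True
    diag.messages.append(
        f"tree pruned from {len(tree_names)} to {len(common)} leaves "
        "(intersection of input name sets)"
    )
    return pruned, diag


# ---------------------------------------------------------------------------
# Tabular inputs: leaf locations and character matrices
# ---------------------------------------------------------------------------

def _read_delimited(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, sep=None, engine="python")


def read_locations(path_or_buf):
    """Read a delimited table with columns (name, x, y) into LeafLocations."""
    from .spatial_sd import LeafLocations

    df = _read_delimited(path_or_buf)
    if df.shape[1] < 3:
        raise ValueError("locations table needs columns: name, x, y")
    names = df.iloc[:, 0].astype(str).tolist()
    x = df.iloc[:, 1].astype(float).to_numpy()
    y = df.iloc[:, 2].astype(float).to_numpy()
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates in locations table")
    return LeafLocations(names=names, x=x, y=y)


def write_locations(locations, path) -> None:
    pd.DataFrame(
        {"name": locations.names, "x": locations.x, "y": locations.y}
    ).to_csv(path, index=False)


def read_character_matrix(path_or_buf, missing_chars=("?", "-")):
    """Read a delimited character matrix (first column: cell name).

    Entries are integers in ``{-1, 0, 1..M(k)}`` or one of ``missing_chars``
    for a missing observation.  Missing is encoded internally as ``-2``;
    observed ``-1`` (silent) is kept and handled at likelihood time.
    Per-site alphabet sizes ``M(k)`` are inferred as the maximum observed
    mutated state (at least 1).
    """
    from .sequence_pmm import CharacterMatrix, SiteAlphabet

    df = _read_delimited(path_or_buf)
    if df.shape[1] < 2:
        raise ValueError("character matrix needs a name column and >=1 site")
    cells = df.iloc[:, 0].astype(str).tolist()
    ncol = df.shape[1] - 1
    data = np.empty((len(cells), ncol), dtype=np.int64)
    for k in range(ncol):
        col = df.iloc[:, k + 1]
        for i, raw in enumerate(col):
            s = str(raw).strip()
            if s in missing_chars:
                data[i, k] = MISSING
            else:
                try:
                    data[i, k] = int(float(s))
                except ValueError:
                    raise ValueError(
                        f"invalid character state {s!r} at cell "
                        f"{cells[i]!r}, site {k}"
                    ) from None
        bad = (data[:, k] < MISSING)
        if bad.any():
            raise ValueError(f"state below -1 in site {k}")
    alphabets = [
        SiteAlphabet(n_states=max(1, int(data[:, k].max(initial=1))))
        for k in range(ncol)
    ]
    return CharacterMatrix(cells=cells, data=data, alphabets=alphabets)


def write_character_matrix(matrix, path, missing_char="?") -> None:
    cols = {"cell": matrix.cells}
    for k in range(matrix.n_sites):
        cols[f"site{k}"] = [
            missing_char if v == MISSING else str(int(v))
            for v in matrix.data[:, k]
        ]
    pd.DataFrame(cols).to_csv(path, index=False)
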