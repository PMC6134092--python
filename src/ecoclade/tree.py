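"""Phylogeny container and tree surgery.

A :class:`PhyloTree` is a rooted tree over uniquely labelled tips (OTUs)
with nonnegative branch lengths.  Internal nodes — the monophyletic
clades that are the unit of analysis throughout this package — carry
deterministic identifiers ``node_0``, ``node_1``, ... assigned by a
preorder traversal in which children are visited in lexicographic order
of their smallest descendant tip label.  The identifiers are therefore a
pure function of topology + tip labels: re-parsing the same tree from
any sibling-reordered newick string yields the same clade_id -> tip-set
mapping.

Newick parsing is delegated to dendropy; everything downstream operates
on this lightweight structure.  Multifurcations are retained (reference
backbone trees contain them); unbranched internal nodes (out-degree 1)
are collapsed on ingest with branch lengths summed, so every internal
node of a canonical tree is a testable clade.  The root itself is part
of the clade universe.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import TreeError

__all__ = [
    "PhyloTree",
    "parse_newick",
]

_EPS = 1e-9


class _Node:
    __slots__ = ("name", "length", "parent", "children", "_min_tip")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Optional[_Node] = None
        self.children: List[_Node] = []
        self._min_tip: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    """Rooted phylogeny with stable clade identifiers.

    Instances are effectively immutable: every operation that changes
    the tree (rooting, pruning) returns a new canonicalised tree.
    """

    def __init__(self, root: _Node):
        self._root = root
        self._canonicalize()

    # ------------------------------------------------------------------
    # construction / serialisation
    # ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a newick string (terminating semicolon required).

        Missing branch lengths are read as 0 with a warning; duplicate
        or empty tip labels raise :class:`TreeError`.
        """
        import dendropy

        if ";" not in text:
            raise TreeError("malformed newick: missing terminating ';'")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed newick: {exc}") from exc

        missing = False

        def convert(dnode) -> _Node:
            nonlocal missing
            length = dnode.edge.length
            if length is None:
                length = 0.0
                if dnode.parent_node is not None:
                    missing = True
            if length < 0:
                raise TreeError(
                    f"negative branch length {length} on edge above "
                    f"{dnode.taxon.label if dnode.taxon else 'internal node'}"
                )
            if dnode.is_leaf():
                if dnode.taxon is None or not str(dnode.taxon.label).strip():
                    raise TreeError("empty tip label in newick input")
                return _Node(str(dnode.taxon.label), length)
            node = _Node(None, length)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dtree.seed_node)
        root.length = 0.0
        if missing:
            warnings.warn(
                "newick input has missing branch lengths; treated as 0",
                stacklevel=2,
            )
        return cls(root)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, internal_labels: bool = True) -> str:
        """Write the canonical newick string (children in canonical order)."""

        def fmt(node: _Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name if internal_labels else ""
            if node is self._root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:g}"

        return fmt(self._root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_subtree(self._root))

    # ------------------------------------------------------------------
    # canonical form
    # ------------------------------------------------------------------

    def _canonicalize(self) -> None:
        root = self._root
        root.parent = None
        root.length = 0.0
        # collapse out-degree-1 internal nodes (branch lengths summed)
        root = _collapse_unifurcations(root)
        self._root = root

        # tip label uniqueness
        labels = [n.name for n in _iter_leaves(root)]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {', '.join(dupes)}")

        # order children by smallest descendant tip label, assign ids
        def annotate(node: _Node) -> str:
            if node.is_leaf:
                node._min_tip = node.name
                return node.name
            mins = [annotate(c) for c in node.children]
            order = sorted(range(len(mins)), key=lambda i: mins[i])
            node.children = [node.children[i] for i in order]
            node._min_tip = mins[order[0]]
            return node._min_tip

        annotate(root)

        counter = 0
        self._nodes: Dict[str, _Node] = {}
        self._clade_ids: List[str] = []
        self._tip_labels: List[str] = []

        def preorder(node: _Node) -> None:
            nonlocal counter
            if node.is_leaf:
                self._tip_labels.append(node.name)
            else:
                node.name = f"node_{counter}"
                counter += 1
                self._clade_ids.append(node.name)
            if node.name in self._nodes:
                raise TreeError(f"node id collision on {node.name!r}")
            self._nodes[node.name] = node
            for child in node.children:
                preorder(child)

        preorder(root)
        self._clade_tips: Dict[str, Tuple[str, ...]] = {}

        def tipsets(node: _Node) -> Tuple[str, ...]:
            if node.is_leaf:
                return (node.name,)
            tips = tuple(t for c in node.children for t in tipsets(c))
            self._clade_tips[node.name] = tips
            return tips

        tipsets(root)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._root.name

    @property
    def tip_labels(self) -> List[str]:
        """Tips in canonical (preorder) order."""
        return list(self._tip_labels)

    @property
    def clade_ids(self) -> List[str]:
        """Internal node ids in preorder; ``node_0`` is the root."""
        return list(self._clade_ids)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def has_node(self, name: str) -> bool:
        return name in self._nodes

    def clade_tips(self, clade_id: str) -> Tuple[str, ...]:
        """Tip labels subtended by a node (a tip subtends itself)."""
        node = self._get(clade_id)
        if node.is_leaf:
            return (node.name,)
        return self._clade_tips[clade_id]

    def parent_id(self, name: str) -> Optional[str]:
        node = self._get(name)
        return node.parent.name if node.parent is not None else None

    def children_ids(self, name: str) -> List[str]:
        return [c.name for c in self._get(name).children]

    def _get(self, name: str) -> _Node:
        try:
            return self._nodes[name]
        except KeyError:
            raise TreeError(f"unknown node id: {name!r}") from None

    def depths(self) -> Dict[str, float]:
        """Root-to-node path lengths for every node."""
        out: Dict[str, float] = {}

        def walk(node: _Node, d: float) -> None:
            out[node.name] = d
            for c in node.children:
                walk(c, d + c.length)

        walk(self._root, 0.0)
        return out

    # ------------------------------------------------------------------
    # distances
    # ------------------------------------------------------------------

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique path between two nodes."""
        na, nb = self._get(a), self._get(b)
        if na is nb:
            return 0.0
        anc: Dict[int, float] = {}
        d = 0.0
        node: Optional[_Node] = na
        while node is not None:
            anc[id(node)] = d
            d += node.length
            node = node.parent
        d = 0.0
        node = nb
        while node is not None:
            if id(node) in anc:
                return anc[id(node)] + d
            d += node.length
            node = node.parent
        raise TreeError("nodes are not in the same tree")  # pragma: no cover

    def patristic_matrix(self, ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """All-pairs patristic distances for the given node ids (default: tips)."""
        if ids is None:
            ids = self.tip_labels
        ids = list(ids)
        for i in ids:
            self._get(i)
        adj: Dict[str, List[Tuple[str, float]]] = {n: [] for n in self._nodes}
        for name, node in self._nodes.items():
            if node.parent is not None:
                adj[name].append((node.parent.name, node.length))
                adj[node.parent.name].append((name, node.length))
        want = set(ids)
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for src in ids:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nxt, w in adj[cur]:
                    if nxt not in dist:
                        dist[nxt] = dist[cur] + w
                        stack.append(nxt)
            for dst in want:
                mat.loc[src, dst] = dist[dst]
        # per-source traversals can differ by float rounding; symmetrize
        vals = (mat.to_numpy() + mat.to_numpy().T) / 2.0
        np.fill_diagonal(vals, 0.0)
        return pd.DataFrame(vals, index=ids, columns=ids)

    # ------------------------------------------------------------------
    # rooting and pruning
    # ------------------------------------------------------------------

    def midpoint_root(self) -> "PhyloTree":
        """Re-root at the midpoint of the longest tip-to-tip path.

        Tip-pair ties are broken by the lexicographically smallest
        (sorted) tip pair, so the result is deterministic.  All
        tip-to-tip patristic distances are preserved.
        """
        if self.n_tips < 2:
            raise TreeError("midpoint rooting needs at least 2 tips")
        dm = self.patristic_matrix()
        tips = self.tip_labels
        best: Optional[Tuple[str, str]] = None
        best_d = -1.0
        for i, a in enumerate(tips):
            for b in tips[i + 1 :]:
                d = dm.loc[a, b]
                pair = tuple(sorted((a, b)))
                if d > best_d + _EPS:
                    best_d, best = d, pair
                elif abs(d - best_d) <= _EPS and pair < best:
                    best = pair
        if best_d <= 0:
            raise TreeError("all branch lengths are zero; midpoint undefined")
        a, b = best

        new = self.copy()
        path = _path_between(new._get(a), new._get(b))
        half = best_d / 2.0
        cum = 0.0
        new_root: Optional[_Node] = None
        for i in range(len(path) - 1):
            u, v = path[i], path[i + 1]
            # edge between u and v; length stored on whichever is the child
            if v.parent is u:
                child, edge_len = v, v.length
            else:
                child, edge_len = u, u.length
            if abs(cum - half) <= _EPS:
                new_root = u
                break
            if cum + edge_len >= half - _EPS:
                # midpoint inside this edge, at (half - cum) from u
                from_child = (
                    edge_len - (half - cum) if child is v else (half - cum)
                )
                new_root = _insert_on_edge(child, from_child)
                break
            cum += edge_len
        else:
            new_root = path[-1]
        _reroot_at(new_root)
        return PhyloTree(new_root)

    def root_with_outgroup(self, outgroup: str) -> "PhyloTree":
        """Re-root on the edge above a tip so that tip is a child of the root."""
        node = self._get(outgroup)
        if not node.is_leaf:
            raise TreeError(f"outgroup {outgroup!r} is not a tip")
        if node.parent is self._root and len(self._root.children) == 2:
            return self.copy()
        new = self.copy()
        tip = new._get(outgroup)
        new_root = _insert_on_edge(tip, tip.length / 2.0)
        _reroot_at(new_root)
        return PhyloTree(new_root)

    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to the given tips, collapsing unbranched nodes.

        Pairwise patristic distances among kept tips are preserved.
        """
        keep = set(keep)
        present = keep & set(self._tip_labels)
        if not present:
            raise TreeError("no tips to keep: intersection with tree is empty")

        def rec(node: _Node) -> Optional[_Node]:
            if node.is_leaf:
                if node.name in present:
                    return _Node(node.name, node.length)
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            out = _Node(None, node.length)
            for k in kids:
                out.add(k)
            return out

        root = rec(self._root)
        assert root is not None
        root.length = 0.0
        return PhyloTree(root)

    # ------------------------------------------------------------------
    # reporting
    # ------------------------------------------------------------------

    def clade_table(self) -> pd.DataFrame:
        """Per-clade summary: parent, size, tip list, depth from root."""
        depths = self.depths()
        rows = []
        for cid in self._clade_ids:
            tips = self._clade_tips[cid]
            rows.append(
                {
                    "clade_id": cid,
                    "parent_id": self.parent_id(cid) or "",
                    "n_tips": len(tips),
                    "tip_list": ",".join(tips),
                    "depth": depths[cid],
                }
            )
        return pd.DataFrame(rows).set_index("clade_id")

    # ------------------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {len(self._clade_ids)} clades>"

    def __eq__(self, other) -> bool:
        """Isomorphism check: identical canonical newick."""
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()

    def __hash__(self):  # pragma: no cover
        return hash(self.to_newick())


# ----------------------------------------------------------------------
# module-level helpers
# ----------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Convenience alias for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text)


def _iter_leaves(node: _Node):
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            yield cur
        else:
            stack.extend(cur.children)


def _collapse_unifurcations(root: _Node) -> _Node:
    while len(root.children) == 1 and not root.is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = 0.0

    def walk(node: _Node) -> None:
        new_children = []
        for child in node.children:
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length += child.length
                grand.parent = node
                child = grand
            child.parent = node
            new_children.append(child)
            walk(child)
        node.children = new_children

    walk(root)
    return root


def _copy_subtree(node: _Node) -> _Node:
    out = _Node(node.name, node.length)
    for child in node.children:
        out.add(_copy_subtree(child))
    return out


def _path_between(a: _Node, b: _Node) -> List[_Node]:
    """Node sequence a..b through their most recent common ancestor."""
    up_a = []
    node: Optional[_Node] = a
    while node is not None:
        up_a.append(node)
        node = node.parent
    seen = {id(n): i for i, n in enumerate(up_a)}
    up_b = []
    node = b
    while id(node) not in seen:
        up_b.append(node)
        node = node.parent
    lca_idx = seen[id(node)]
    return up_a[: lca_idx + 1] + list(reversed(up_b))


def _insert_on_edge(child: _Node, dist_above_child: float) -> _Node:
    """Split the edge above ``child``, returning the new node."""
    parent = child.parent
    if parent is None:
        raise TreeError("cannot insert above the root")
    dist_above_child = min(max(dist_above_child, 0.0), child.length)
    mid = _Node(None, child.length - dist_above_child)
    parent.children[parent.children.index(child)] = mid
    mid.parent = parent
    child.parent = mid
    child.length = dist_above_child
    mid.children = [child]
    return mid


def _reroot_at(new_root: _Node) -> None:
    """Reverse parent pointers so ``new_root`` becomes the root (in place).

    The old root, if left with a single child, is spliced out.
    """
    path = []
    node: Optional[_Node] = new_root
    while node is not None:
        path.append(node)
        node = node.parent
    # reverse each edge along the path, starting nearest the new root
    old_lengths = [n.length for n in path]
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        parent.children.remove(child)
        child.add(parent)
        parent.length = old_lengths[i]
    new_root.parent = None
    new_root.length = 0.0
    # splice out any now-unbranched former root
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        only = old_root.children[0]
        only.length += old_root.length
        gp = old_root.parent
        gp.children[gp.children.index(old_root)] = only
        only.parent = gp
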