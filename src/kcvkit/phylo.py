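"""Distance-based phylogeny: p-distances, neighbor joining, Newick output.

Neighbor joining follows the canonical Saitou-Nei formulation with a
deterministic tie-break (lexicographically smallest joined-pair label) and
nonnegative branch lengths: a negative estimate is clamped to zero and the
deficit moved onto the sibling branch, preserving the pair's total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from kcvkit.msa import GAP, MultipleAlignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance_matrix",
    "neighbor_joining",
    "write_newick",
    "is_monophyletic",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered taxon list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} taxa")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate taxon ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(f"{x:.6g}" for x in self.values[i]) + "\n")


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with a (usually trifurcating) root node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves() if n.name is not None]

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf patristic distances."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name or "", node.branch_length)]
            merged: list[tuple[str, float]] = []
            groups = [below(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi]:
                        for b, db in groups[gj]:
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            for g in groups:
                merged.extend((name, d + node.branch_length) for name, d in g)
            return merged

        below(self.root)
        return dists


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Proportion of differing sites over columns where neither row is a gap."""
    if msa.n_rows < 3:
        raise ValueError("need at least 3 rows")
    rows = [row for _, row in msa.rows]
    n = len(rows)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                comparable += 1
                if a != b:
                    diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"rows {msa.rows[i][0]!r} and {msa.rows[j][0]!r} share no comparable columns"
                )
            vals[i, j] = vals[j, i] = diffs / comparable
    return DistanceMatrix(tuple(msa.ids), vals)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining; exact on additive distance matrices."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    # active nodes: label -> (TreeNode, smallest leaf label under it)
    nodes: dict[str, TreeNode] = {rid: TreeNode(name=rid) for rid in dm.ids}
    anchor: dict[str, str] = {rid: rid for rid in dm.ids}
    labels = list(dm.ids)
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[(a, b)] = float(dm.values[i, j])

    def d(a: str, b: str) -> float:
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    counter = 0
    while len(labels) > 3:
        r = len(labels)
        totals = {a: sum(d(a, b) for b in labels if b != a) for a in labels}
        best: tuple[float, str, str, str, str] | None = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (r - 2) * d(a, b) - totals[a] - totals[b]
                pair_key = tuple(sorted((anchor[a], anchor[b])))
                cand = (q, pair_key[0], pair_key[1], a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        _, _, _, a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        # clamp negatives, moving deficit to the sibling branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)

        counter += 1
        new_label = f"__nj{counter}"
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].branch_length = la
        nodes[b].branch_length = lb
        nodes[new_label] = parent
        anchor[new_label] = min(anchor[a], anchor[b])

        new_d = {}
        for c in labels:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (d(a, c) + d(b, c) - dab)
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        D = {
            (x, y): (d(x, y) if x != new_label and y != new_label else 0.0)
            for i, x in enumerate(labels)
            for y in labels[i + 1 :]
        }
        for c, val in new_d.items():
            key = (c, new_label) if (c, new_label) in D else (new_label, c)
            D[key] = val

    # final trifurcation
    a, b, c = labels
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lbl].branch_length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root)


_NEWICK_SPECIALS = set("();,:[]' \t\n")


def _quote(name: str) -> str:
    if any(c in _NEWICK_SPECIALS for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: Tree) -> str:
    """Serialize with branch lengths; terminated by a semicolon."""

    def fmt(node: TreeNode, with_length: bool = True) -> str:
        if node.is_leaf:
            s = _quote(node.name or "")
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += _quote(node.name)
        if with_length:
            s += f":{node.branch_length:.10g}"
        return s

    return "(" + ",".join(fmt(c) for c in tree.root.children) + ");"


def is_monophyletic(tree: Tree, taxa: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly the given taxa."""
    taxa = frozenset(taxa)
    all_leaves = frozenset(tree.leaf_names())
    unknown = taxa - all_leaves
    if unknown:
        raise ValueError(f"unknown taxa {sorted(unknown)}")
    if taxa == all_leaves:
        return True

    found = False

    def walk(node: TreeNode) -> frozenset[str]:
        nonlocal found
        if node.is_leaf:
            clade = frozenset([node.name or ""])
        else:
            clade = frozenset()
            for c in node.children:
                clade |= walk(c)
        if clade == taxa or (all_leaves - clade) == taxa:
            found = True
        return clade

    walk(tree.root)
    return found
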