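"""Neighbor-joining trees from distance matrices, with newick output.

The agglomeration is the standard Saitou–Nei algorithm.  Determinism is
imposed: when several pairs attain the minimal Q criterion, the pair whose
(sorted) subtree labels are lexicographically smallest is joined.  Negative
branch-length estimates (possible on non-additive inputs such as Fst
matrices) are clamped to zero with the deficit moved to the sister branch,
and logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .popgen import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class Clade:
    """A tree node: leaf (labelled) or internal (label None)."""

    label: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    def leaves(self) -> list["Clade"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating root."""

    root: Clade

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.root.leaves()]


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build an unrooted NJ tree from a symmetric distance matrix."""
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = np.array(dm.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    nodes: list[Clade] = [Clade(label=lab) for lab in labels]
    # canonical key per active node: smallest leaf label in its subtree
    keys: list[str] = list(labels)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or pair_key < best[2])
                ):
                    best_q, best = q, (i, j, pair_key)
        i, j, _ = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, keys[i], keys[j])
        parent = Clade(children=[_with_length(nodes[i], li), _with_length(nodes[j], lj)])
        rest = [k for k in range(n) if k not in (i, j)]
        new_d = np.empty(len(rest))
        for a, k in enumerate(rest):
            new_d[a] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        d = np.vstack([d[np.ix_(rest, rest)], new_d[None, :]])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes = [nodes[k] for k in rest] + [parent]
        keys = [keys[k] for k in rest] + [min(keys[i], keys[j])]

    # join the last three nodes at the trifurcating root
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    lens = [l0, l1, l2]
    for k in range(3):
        if lens[k] < 0:
            logger.warning("clamping negative terminal branch (%s): %g", keys[k], lens[k])
            lens[k] = 0.0
    root = Clade(children=[_with_length(nodes[k], lens[k]) for k in range(3)])
    return Tree(root=root)


def _with_length(node: Clade, length: float) -> Clade:
    node.length = float(length)
    return node


def _clamp_pair(li: float, lj: float, ki: str, kj: str) -> tuple[float, float]:
    if li < 0:
        logger.warning("clamping negative branch toward %s (%g); moved to %s", ki, li, kj)
        lj += li
        li = 0.0
    if lj < 0:
        logger.warning("clamping negative branch toward %s (%g); moved to %s", kj, lj, ki)
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;'[]\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_str(node: Clade, with_length: bool = True) -> str:
    if not node.children:
        s = _quote(node.label or "")
    else:
        s = "(" + ",".join(_newick_str(c, with_length) for c in node.children) + ")"
        if node.label:
            s += _quote(node.label)
    if with_length and node.length is not None:
        s += f":{node.length:.10g}"
    return s


def to_newick(tree: Tree) -> str:
    return (
        "(" + ",".join(_newick_str(c) for c in tree.root.children) + ");"
    )


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_phylip_square(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (taxon count, then rows)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.array(rows))
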