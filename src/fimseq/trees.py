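"""Distance-based tree construction (UPGMA and neighbor-joining) and Newick IO.

Trees are ``skbio.TreeNode`` objects. Both algorithms are implemented with
deterministic tie-breaking (smallest (row, col) cluster-index pair at every
merge) so output is reproducible across runs and platforms. Negative NJ
branch lengths are clamped to zero with a warning. UPGMA returns a rooted
ultrametric tree; NJ returns the conventional unrooted tree, represented
with a trifurcating root.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode


def _min_pair(d: np.ndarray, active: list[int]) -> tuple[int, int]:
    """Index pair (i, j), i<j, minimising d; ties to the smallest pair."""
    best = (np.inf, -1, -1)
    for ai, i in enumerate(active):
        for j in active[ai + 1:]:
            v = d[i, j]
            if v < best[0] - 1e-15:
                best = (v, i, j)
    return best[1], best[2]


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA with arithmetic-mean cluster distances.

    Node heights are half the cluster distance at each merge; the result is
    ultrametric (all root-to-leaf paths equal).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    size = n * 2 - 1
    d = np.full((size, size), np.inf)
    d[:n, :n] = dm.data
    nodes = [TreeNode(name=str(lab)) for lab in dm.ids]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = _min_pair(d, active)
        h = d[i, j] / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        for k in active:
            if k in (i, j):
                continue
            d[nxt, k] = d[k, nxt] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    root = nodes[active[0]]
    root.length = None
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Recovers additive matrices exactly. Negative branch lengths are clamped
    to 0 with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs n >= 3; use upgma for n = 2")
    size = n * 2
    d = np.zeros((size, size))
    d[:n, :n] = dm.data
    nodes = [TreeNode(name=str(lab)) for lab in dm.ids]
    active = list(range(n))
    nxt = n

    def _clamp(x: float) -> float:
        if x < 0:
            warnings.warn(
                f"negative NJ branch length {x:.3e} clamped to 0",
                RuntimeWarning, stacklevel=3,
            )
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = (np.inf, -1, -1)
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            d[nxt, k] = d[k, nxt] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = _clamp(ln)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.length = None
    return root


_NEEDS_QUOTING = set(" (),:;[]'")


def _label(name: str) -> str:
    # newick: unquoted underscores denote spaces; quote anything unsafe
    if set(name) & _NEEDS_QUOTING:
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_str(node: TreeNode) -> str:
    if node.is_tip():
        s = _label(node.name or "")
    else:
        s = "(" + ",".join(_newick_str(c) for c in node.children) + ")"
        if node.name:
            s += _label(node.name)
    if node.length is not None:
        s += f":{node.length:.6f}"
    return s


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise a tree as Newick with 6-decimal branch lengths."""
    Path(path).write_text(_newick_str(tree) + ";\n")


def read_newick(source: str | Path) -> TreeNode:
    """Parse a Newick tree (path or literal string).

    Branch lengths absent from the file are recorded as None, not 0.
    Duplicate leaf names are rejected.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = source
    tree = TreeNode.read(io.StringIO(text), format="newick",
                         convert_underscores=False)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dups = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate leaf names: {dups}")
    return tree


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    return tree.tip_tip_distances()
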