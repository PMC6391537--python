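"""Validation statistics: Robinson-Foulds tree distance, distance-matrix
correlation, and ROC/AUC for intra- vs inter-group discrimination."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from sklearn import metrics as _skm

from .trees import _newick_str


def _to_dendropy(tree: TreeNode, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    t = dendropy.Tree.get(
        data=_newick_str(tree) + ";", schema="newick", taxon_namespace=tns
    )
    t.is_rooted = False
    t.encode_bipartitions()
    return t


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Both trees are treated as unrooted; the distance is the size of the
    symmetric difference of their non-trivial bipartition sets (0 means
    identical topologies).
    """
    l1 = sorted(t.name for t in t1.tips())
    l2 = sorted(t.name for t in t2.tips())
    if l1 != l2:
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    tns = dendropy.TaxonNamespace()
    d1 = _to_dendropy(t1, tns)
    d2 = _to_dendropy(t2, tns)
    return int(dendropy.calculate.treecompare.symmetric_difference(d1, d2))


def matrix_correlation(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation between two distance matrices on the same labels.

    Computed over the strict upper-triangle entries, paired by label
    (dm2 is reordered to dm1's label order).
    """
    ids1, ids2 = set(dm1.ids), set(dm2.ids)
    if ids1 != ids2:
        raise ValueError(
            f"label sets differ: {sorted(ids1 ^ ids2)} not shared"
        )
    n = len(dm1.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa (>= 2 distance pairs)")
    order = [dm2.index(lab) for lab in dm1.ids]
    a = dm1.data
    b = dm2.data[np.ix_(order, order)]
    iu = np.triu_indices(n, k=1)
    x, y = a[iu], b[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a triangle: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, group) tab-separated file without header."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 tab-separated columns: {ln!r}")
        sid, grp = parts[0].strip(), parts[1].strip()
        if sid in out:
            raise ValueError(f"duplicate id {sid!r} in labels file")
        out[sid] = grp
    return out


def roc_auc(
    dm: DistanceMatrix, labels: dict[str, str]
) -> tuple[float, np.ndarray]:
    """ROC analysis of intra- vs inter-group pair discrimination.

    Positives are same-group pairs, negatives different-group pairs; the
    score is the similarity 1 - D. Returns (auc, curve) where curve is an
    array of (fpr, tpr) points at every distinct threshold. AUC equals the
    Mann-Whitney rank statistic with midrank tie handling.
    """
    missing = [lab for lab in dm.ids if lab not in labels]
    if missing:
        raise ValueError(f"ids without a group label: {missing}")
    n = len(dm.ids)
    iu = np.triu_indices(n, k=1)
    groups = np.asarray([labels[lab] for lab in dm.ids])
    y_true = (groups[iu[0]] == groups[iu[1]]).astype(int)
    scores = 1.0 - dm.data[iu]
    if y_true.sum() == 0 or y_true.sum() == y_true.size:
        raise ValueError(
            "need at least one intra-group and one inter-group pair"
        )
    auc = float(_skm.roc_auc_score(y_true, scores))
    fpr, tpr, _ = _skm.roc_curve(y_true, scores)
    return auc, np.column_stack([fpr, tpr])
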