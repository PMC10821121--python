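"""Alpha-diversity estimators and beta-diversity distances.

All metrics are implemented from their defining formulas so they can be
checked against brute-force enumeration and independent reference
implementations. Alpha metrics operate on a single count vector; beta
metrics on pairs of aligned vectors (or on a whole table via
:func:`distance_matrix`).

Conventions: Shannon entropy in nats; Chao1 in its classic
singleton/doubleton form with the F2 = 0 fallback; weighted UniFrac
normalised by default, with similarity = 1 - normalised distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from fmt_engraft.io import AsvTable
from fmt_engraft.preprocess import clr_transform, to_proportions

# ---------------------------------------------------------------- alpha


def chao1(counts: Sequence[int] | np.ndarray, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from a count vector.

    With S observed taxa, F1 singletons and F2 doubletons:
    S + F1^2 / (2 F2) when F2 > 0, else S + F1 (F1 - 1) / 2. The
    bias-corrected variant uses S + F1 (F1 - 1) / (2 (F2 + 1)).
    An all-zero vector yields 0.
    """
    c = _as_counts(counts)
    s = int(np.count_nonzero(c))
    if s == 0:
        return 0.0
    f1 = int(np.count_nonzero(c == 1))
    f2 = int(np.count_nonzero(c == 2))
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0


def shannon(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), over taxa with p_i > 0."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("shannon requires a positive total count")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def gini_simpson(counts: Sequence[float] | np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (one minus Simpson's index)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("gini_simpson requires a positive total count")
    p = c / total
    return float(1.0 - (p * p).sum())


def _as_counts(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if c.size and np.any(np.asarray(c, dtype=float) < 0):
        raise ValueError("counts must be non-negative")
    return np.asarray(c, dtype=np.int64) if c.size else np.zeros(0, dtype=np.int64)


def alpha_diversity_table(table: AsvTable) -> pd.DataFrame:
    """Chao1, Shannon and Gini-Simpson for every sample in a table."""
    rows = {
        sid: {
            "chao1": chao1(table.counts(sid)),
            "shannon": shannon(table.counts(sid)),
            "gini_simpson": gini_simpson(table.counts(sid)),
        }
        for sid in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# ----------------------------------------------------------------- beta


def jaccard_distance(a: set, b: set) -> float:
    """1 - |a n b| / |a u b|; two empty sets are at distance 0 by convention."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on aligned vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"mismatched taxa: {xv.shape} vs {yv.shape}")
    denom = (xv + yv).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(xv - yv).sum() / denom)


def aitchison_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Euclidean distance between CLR-transformed compositions."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"mismatched dimension: {xv.shape} vs {yv.shape}")
    return float(np.sqrt(((xv - yv) ** 2).sum()))


# ------------------------------------------------------------- UniFrac


class TreeBranches:
    """Branch table for UniFrac: per-branch length and descendant-leaf mask.

    Precomputed once per (tree, taxon order) so distance-matrix loops
    reduce to a matrix product. Branches are every non-root node.
    """

    def __init__(self, tree: TreeNode, asv_ids: Sequence[str]):
        self.asv_ids = list(asv_ids)
        col = {a: i for i, a in enumerate(self.asv_ids)}
        leaf_names = {leaf.name for leaf in tree.tips()}
        lengths = []
        masks = []
        membership: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            mask = np.zeros(len(self.asv_ids), dtype=bool)
            if node.is_tip():
                if node.name in col:
                    mask[col[node.name]] = True
            else:
                for child in node.children:
                    mask |= membership[id(child)]
            membership[id(node)] = mask
            if node.parent is not None:  # root contributes no branch
                lengths.append(0.0 if node.length is None else float(node.length))
                masks.append(mask)
        self.lengths = np.asarray(lengths, dtype=float)
        self.mask = np.asarray(masks, dtype=float)  # branches x taxa
        self.missing = [a for a in self.asv_ids if a not in leaf_names]

    def branch_fractions(self, counts: Sequence[float]) -> np.ndarray:
        """Fraction of a sample's reads descending from each branch."""
        c = np.asarray(counts, dtype=float)
        present = [self.asv_ids[i] for i in np.flatnonzero(c) ]
        absent = [a for a in present if a in self.missing]
        if absent:
            raise ValueError(f"taxa with nonzero counts absent from tree: {absent}")
        total = c.sum()
        if total <= 0:
            raise ValueError("sample has no reads")
        return self.mask @ (c / total)


def weighted_unifrac(
    x: Sequence[float],
    y: Sequence[float],
    asv_ids: Sequence[str],
    tree: TreeNode,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two count vectors.

    Both samples are rescaled to relative abundance; with p_b(s) the
    fraction of sample s reads under branch b and l_b its length, the raw
    distance is sum_b l_b |p_b(x) - p_b(y)| and the normalised one divides
    by sum_b l_b (p_b(x) + p_b(y)), bounding it to [0, 1].
    """
    branches = TreeBranches(tree, asv_ids)
    return _unifrac_from_fractions(
        branches.lengths,
        branches.branch_fractions(x),
        branches.branch_fractions(y),
        normalized,
    )


def _unifrac_from_fractions(
    lengths: np.ndarray, px: np.ndarray, py: np.ndarray, normalized: bool
) -> float:
    raw = float((lengths * np.abs(px - py)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (px + py)).sum())
    if denom == 0:
        return 0.0
    return raw / denom


def weighted_unifrac_similarity(
    x: Sequence[float], y: Sequence[float], asv_ids: Sequence[str], tree: TreeNode
) -> float:
    """1 - normalised weighted UniFrac distance."""
    return 1.0 - weighted_unifrac(x, y, asv_ids, tree, normalized=True)


# ------------------------------------------------------- whole tables


def distance_matrix(
    table: AsvTable,
    metric: str,
    tree: TreeNode | None = None,
    pseudocount: float = 0.5,
    normalized: bool = True,
) -> pd.DataFrame:
    """Square symmetric distance matrix over all samples of a table.

    ``metric`` is one of ``jaccard``, ``bray_curtis``, ``aitchison``,
    ``weighted_unifrac`` (the latter requires ``tree``). The result
    carries the metric name in ``.attrs['metric']``.
    """
    ids = table.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    if metric == "jaccard":
        sets = [set(np.asarray(table.asv_ids)[table.counts(s) > 0]) for s in ids]
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = jaccard_distance(sets[i], sets[j])
    elif metric == "bray_curtis":
        props = to_proportions(table).to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(props[i], props[j])
    elif metric == "aitchison":
        clr = clr_transform(table, pseudocount=pseudocount).to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = aitchison_distance(clr[i], clr[j])
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        branches = TreeBranches(tree, table.asv_ids)
        fracs = [branches.branch_fractions(table.counts(s)) for s in ids]
        for i in range(n):
            for j in range(i + 1, n):
                d = _unifrac_from_fractions(
                    branches.lengths, fracs[i], fracs[j], normalized
                )
                out[i, j] = out[j, i] = d
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    df = pd.DataFrame(out, index=ids, columns=ids)
    df.attrs["metric"] = metric
    return df
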