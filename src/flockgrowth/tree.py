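"""Feed-efficiency partitioning by a LogWorth-scored regression tree.

Flocks are split into high- (HE) and low- (LE) feed-efficiency groups by
recursive binary partitioning of 35-d cumulative FCR.  With one unique
flock per value, partitioning the response on a flock identifier is
equivalent to optimal one-dimensional threshold splits on the FCR values
themselves, which is what this module implements.

Each candidate split is the midpoint between consecutive distinct sorted
values; the chosen split maximizes the between-group sum-of-squares gain.
Split significance uses a pooled-variance two-sample test whose p-value is
Bonferroni-adjusted for the number of distinct candidate thresholds at the
node; the split is admissible when its LogWorth, -log10(adjusted p),
exceeds a threshold (default 1.3, i.e. adjusted p < 0.05).  Growth stops at
``max_splits`` or when no admissible split remains.

Leaves are condensed to two groups by ordering them by mean FCR and cutting
at the largest gap between adjacent leaf means: the low-FCR block is HE,
the high-FCR block LE.  An optional stricter rule cuts at the two largest
gaps and leaves the middle leaves unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class TreeError(ValueError):
    """Invalid partitioning request or degenerate tree."""


@dataclass(frozen=True)
class SplitCandidate:
    threshold: float
    ss_reduction: float
    p_raw: float
    p_adj: float
    logworth: float


@dataclass(eq=False)  # identity semantics: nodes hold ndarray members
class TreeNode:
    indices: np.ndarray          # positions into the input value array
    mean: float
    n: int
    depth: int = 0
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None   # values <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class PartitionResult:
    tree: TreeNode
    n_splits: int
    r2: float
    rase: float
    labels: dict[str, str] = field(default_factory=dict)  # flock_id -> HE/LE/unassigned
    leaf_summaries: pd.DataFrame | None = None
    group_means: dict[str, float] = field(default_factory=dict)


def _best_split(values: np.ndarray, idx: np.ndarray, min_leaf: int) -> SplitCandidate | None:
    """Exhaustive scan over midpoints between distinct sorted values.

    Ties in the SS gain are broken toward the lower threshold.  Returns None
    when no candidate satisfies ``min_leaf`` on both sides or all values at
    the node are equal.
    """
    v = values[idx]
    order = np.argsort(v, kind="mergesort")
    v_sorted = v[order]
    n = v_sorted.size
    distinct_steps = np.nonzero(np.diff(v_sorted) > 0)[0]  # split after position i
    n_candidates = distinct_steps.size  # Bonferroni denominator at this node
    if n_candidates == 0:
        return None

    csum = np.cumsum(v_sorted)
    total = csum[-1]
    best: tuple[float, float, int] | None = None  # (ss_red, threshold, n_left)
    for i in distinct_steps:
        n_l = i + 1
        n_r = n - n_l
        if n_l < min_leaf or n_r < min_leaf:
            continue
        mean_l = csum[i] / n_l
        mean_r = (total - csum[i]) / n_r
        ss_red = n_l * n_r / n * (mean_l - mean_r) ** 2
        if best is None or ss_red > best[0]:
            threshold = 0.5 * (v_sorted[i] + v_sorted[i + 1])
            best = (ss_red, threshold, n_l)
    if best is None:
        return None
    ss_red, threshold, n_l = best

    left = v_sorted[:n_l]
    right = v_sorted[n_l:]
    sp2_num = float(((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum())
    df = n - 2
    if df <= 0:
        p_raw = 1.0
    elif sp2_num == 0.0:
        p_raw = 0.0  # perfect separation of two constants
    else:
        sp2 = sp2_num / df
        tstat = (left.mean() - right.mean()) / math.sqrt(sp2 * (1 / n_l + 1 / (n - n_l)))
        p_raw = 2.0 * float(sps.t.sf(abs(tstat), df))
    p_adj = min(1.0, p_raw * n_candidates)
    logworth = math.inf if p_adj == 0.0 else -math.log10(p_adj)
    return SplitCandidate(
        threshold=float(threshold),
        ss_reduction=float(ss_red),
        p_raw=p_raw,
        p_adj=p_adj,
        logworth=logworth,
    )


def grow_tree(
    fcr35,
    max_splits: int = 8,
    min_leaf: int = 15,
    logworth_threshold: float = 1.3,
) -> PartitionResult:
    """Grow the partition tree on 35-d FCR values.

    At each step the admissible split with the largest between-group SS gain
    among *all* current leaves is applied.  All-equal values yield a
    zero-split single-leaf tree (r2 = 0).
    """
    values = np.asarray(fcr35, dtype=float)
    if values.ndim != 1:
        raise TreeError("fcr35 must be a 1-D collection")
    if np.any(~np.isfinite(values)):
        raise TreeError("fcr35 values must be finite")
    if max_splits < 1:
        raise TreeError("max_splits must be >= 1")
    if values.size < 2 * min_leaf:
        raise TreeError(f"need at least 2*min_leaf = {2 * min_leaf} flocks")

    root = TreeNode(
        indices=np.arange(values.size), mean=float(values.mean()), n=values.size
    )
    n_splits = 0
    while n_splits < max_splits:
        leaves = root.leaves()
        candidates: list[tuple[float, int, TreeNode, SplitCandidate]] = []
        for j, leaf in enumerate(leaves):
            cand = _best_split(values, leaf.indices, min_leaf)
            if cand is not None and cand.logworth > logworth_threshold:
                candidates.append((cand.ss_reduction, j, leaf, cand))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, _, leaf, cand = candidates[0]
        mask = values[leaf.indices] <= cand.threshold
        li, ri = leaf.indices[mask], leaf.indices[~mask]
        leaf.split = cand
        leaf.left = TreeNode(li, float(values[li].mean()), li.size, leaf.depth + 1)
        leaf.right = TreeNode(ri, float(values[ri].mean()), ri.size, leaf.depth + 1)
        n_splits += 1

    r2, rase = partition_metrics(values, root)
    return PartitionResult(tree=root, n_splits=n_splits, r2=r2, rase=rase)


def partition_metrics(fcr35, tree: TreeNode) -> tuple[float, float]:
    """(R2, RASE) of the leaf-mean predictor.

    ``R2 = 1 - SS_within / SS_total`` and ``RASE = sqrt(mean squared
    deviation from the leaf means)``; a single-leaf tree has R2 = 0 and
    RASE equal to the population SD.
    """
    values = np.asarray(fcr35, dtype=float)
    ss_total = float(((values - values.mean()) ** 2).sum())
    ss_within = 0.0
    for leaf in tree.leaves():
        v = values[leaf.indices]
        ss_within += float(((v - v.mean()) ** 2).sum())
    r2 = 0.0 if ss_total == 0.0 else 1.0 - ss_within / ss_total
    rase = math.sqrt(ss_within / values.size)
    return r2, rase


def label_groups(
    result: PartitionResult,
    flock_ids,
    fcr35,
    n_boundaries: int = 1,
) -> PartitionResult:
    """Condense leaves into HE/LE labels.

    Leaves are ordered by mean FCR.  With ``n_boundaries = 1`` (default) the
    largest gap between adjacent leaf means is the single HE/LE boundary and
    every flock is labeled.  With ``n_boundaries = 2`` the two largest gaps
    bound extreme blocks and middle leaves become "unassigned".  The HE mean
    FCR is lower than the LE mean by construction.
    """
    values = np.asarray(fcr35, dtype=float)
    ids = list(flock_ids)
    if len(ids) != values.size:
        raise TreeError("flock_ids and fcr35 lengths differ")
    leaves = result.tree.leaves()
    if len(leaves) < 2:
        raise TreeError("no partition: the tree has a single leaf")
    order = np.argsort([leaf.mean for leaf in leaves], kind="mergesort")
    sorted_leaves = [leaves[i] for i in order]
    means = np.array([leaf.mean for leaf in sorted_leaves])
    gaps = np.diff(means)
    if np.all(gaps == 0.0):
        raise TreeError("degenerate partition: all leaf means equal")

    if n_boundaries == 1 or len(sorted_leaves) == 2:
        cut = int(np.argmax(gaps))  # ties -> lowest position
        he_leaves = sorted_leaves[: cut + 1]
        le_leaves = sorted_leaves[cut + 1:]
        mid_leaves: list[TreeNode] = []
    elif n_boundaries == 2:
        top_two = np.argsort(-gaps, kind="mergesort")[:2]
        lo_cut, hi_cut = int(top_two.min()), int(top_two.max())
        he_leaves = sorted_leaves[: lo_cut + 1]
        le_leaves = sorted_leaves[hi_cut + 1:]
        mid_leaves = sorted_leaves[lo_cut + 1: hi_cut + 1]
    else:
        raise TreeError("n_boundaries must be 1 or 2")

    labels: dict[str, str] = {}
    for group, grp_leaves in (("HE", he_leaves), ("LE", le_leaves), ("unassigned", mid_leaves)):
        for leaf in grp_leaves:
            for i in leaf.indices:
                labels[ids[i]] = group

    summaries = pd.DataFrame(
        {
            "leaf": range(len(sorted_leaves)),
            "n": [leaf.n for leaf in sorted_leaves],
            "mean_fcr": means,
            "group": [
                "HE" if leaf in he_leaves else ("LE" if leaf in le_leaves else "unassigned")
                for leaf in sorted_leaves
            ],
        }
    )
    group_means = {
        g: float(np.mean([values[i] for leaf in grp for i in leaf.indices]))
        for g, grp in (("HE", he_leaves), ("LE", le_leaves))
    }
    return PartitionResult(
        tree=result.tree,
        n_splits=result.n_splits,
        r2=result.r2,
        rase=result.rase,
        labels=labels,
        leaf_summaries=summaries,
        group_means=group_means,
    )


def partition_flocks(
    flock_ids,
    fcr35,
    max_splits: int = 8,
    min_leaf: int = 15,
    logworth_threshold: float = 1.3,
    n_boundaries: int = 1,
) -> PartitionResult:
    """grow_tree + label_groups in one call."""
    grown = grow_tree(fcr35, max_splits=max_splits, min_leaf=min_leaf,
                      logworth_threshold=logworth_threshold)
    return label_groups(grown, flock_ids, fcr35, n_boundaries=n_boundaries)


def render_tree(result: PartitionResult, fcr35) -> str:
    """Indented text report: per-node n, mean FCR, threshold and LogWorth."""
    values = np.asarray(fcr35, dtype=float)
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str) -> None:
        desc = f"n={node.n} mean={node.mean:.4f}"
        if node.split is not None:
            desc += (
                f" split<= {node.split.threshold:.4f}"
                f" logworth={node.split.logworth:.2f}"
            )
        lines.append(prefix + desc)
        if node.split is not None:
            walk(node.left, prefix + "  ")
            walk(node.right, prefix + "  ")

    walk(result.tree, "")
    return "\n".join(lines)
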