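"""Probability-ranked hierarchical assembly of a binary lineage tree.

Reconstruction starts from singleton clusters at level 1.  At each level the
level-t classifier scores every cell pair; the probability between two
clusters is the maximum over their cross-member cell pairs (complete linkage
on probability).  Cluster pairs are ranked by this probability and greedily
merged — each cluster at most once per level — whenever the probability
exceeds the level's threshold.  Levels increase until one or two clusters
remain, which are joined at the root; the output is always strictly binary.

Determinism: ties in probability are broken lexicographically on the pair's
(smallest member id, then largest member id).  When the level exceeds the
deepest trained model, the deepest model is reused.  If a level produces no
merge while more than two clusters remain, the single highest-probability
pair is force-merged so the assembly always terminates.
"""

from __future__ import annotations

import numpy as np

from .features import all_pair_features, level_pair_labels
from .matrix import BarcodeMatrix
from .model import LevelModel, predict_pair_probability
from .simulate import Colony
from .tree import LineageTree, Node


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores (with the
    convention that a pair is called positive when its score exceeds the
    cutoff).  Falls back to 0.5 when one class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]) - 1e-9
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best_j, best_c = -np.inf, 0.5
    for c in cuts:
        called = scores > c
        tpr = (called & labels).sum() / n_pos
        fpr = (called & ~labels).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_c = j, float(c)
    return best_c


def estimate_level_thresholds(
    models: dict[int, LevelModel],
    validation: list[Colony] | None = None,
) -> dict[int, float]:
    """Per-level merge thresholds.

    With validation colonies, the Youden-optimal cutoff on their pair
    predictions; without, the documented default of 0.5 at every level.
    """
    if not validation:
        return {t: 0.5 for t in models}
    thresholds: dict[int, float] = {}
    for t, model in sorted(models.items()):
        scores, labels = [], []
        for colony in validation:
            pairs, counts = all_pair_features(colony.barcodes)
            probs = predict_pair_probability(
                model, _frame(counts, model.feature_names)
            )
            positives, _ = level_pair_labels(colony.tree, t)
            scores.append(probs)
            labels.append([frozenset(p) in positives for p in pairs])
        thresholds[t] = youden_threshold(
            np.concatenate(scores), np.concatenate([np.asarray(l) for l in labels])
        )
    return thresholds


def _frame(counts: np.ndarray, names: list[str]):
    import pandas as pd

    return pd.DataFrame(counts, columns=names)


DEFAULT_THRESHOLD_GRID = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def tune_merge_threshold(
    models: dict[int, "LevelModel"],
    validation: list[Colony],
    candidates: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> dict[int, float]:
    """Pick the merge cutoff by reconstruction quality on validation colonies.

    Each candidate cutoff (shared across levels) is used to reconstruct every
    validation colony; the candidate with the lowest mean normalized RF score
    against the validation ground truths wins (first on ties).  This targets
    what the threshold actually controls — which ranked merges are committed
    at each level — rather than pair-classification accuracy; on complete
    binary colonies low cutoffs win because every cluster truly merges at
    every level.
    """
    from .scores import rf_score

    usable = [c for c in validation if c.barcodes.n_cells >= 4]
    if not usable:
        return {t: 0.5 for t in models}
    best_c, best_rf = None, np.inf
    for c in candidates:
        mean_rf = float(
            np.mean(
                [
                    rf_score(col.tree, reconstruct_tree(col.barcodes, models, c))
                    for col in usable
                ]
            )
        )
        if mean_rf < best_rf - 1e-12:
            best_c, best_rf = c, mean_rf
    return {t: best_c for t in models}


class _Cluster:
    __slots__ = ("root", "members", "key")

    def __init__(self, root: Node, members: list[str]):
        self.root = root
        self.members = members
        self.key = (min(members), max(members))


def reconstruct_tree(
    barcodes: BarcodeMatrix,
    models: dict[int, LevelModel],
    thresholds: dict[int, float] | float = 0.5,
) -> LineageTree:
    """Assemble a strictly binary tree over the cells of ``barcodes``."""
    n = barcodes.n_cells
    if n < 2:
        raise ValueError("need at least two cells")
    if 1 not in models:
        raise ValueError("a level-1 model is required")
    if isinstance(thresholds, (int, float)):
        thresholds = {t: float(thresholds) for t in models}
    deepest = max(models)

    pairs, counts = all_pair_features(barcodes)
    index = {c: i for i, c in enumerate(barcodes.cell_ids)}
    prob_cache: dict[int, np.ndarray] = {}

    def pair_matrix(level: int) -> np.ndarray:
        key = min(level, deepest)
        if key not in prob_cache:
            model = models[key] if key in models else models[deepest]
            probs = predict_pair_probability(model, _frame(counts, model.feature_names))
            mat = np.zeros((n, n))
            for (a, b), p in zip(pairs, probs):
                mat[index[a], index[b]] = mat[index[b], index[a]] = p
            prob_cache[key] = mat
        return prob_cache[key]

    clusters = [_Cluster(Node(label=c), [c]) for c in barcodes.cell_ids]
    level = 1
    while len(clusters) > 2:
        mat = pair_matrix(level)
        thr = thresholds.get(min(level, deepest), 0.5)
        scored = []
        for i in range(len(clusters)):
            mi = [index[c] for c in clusters[i].members]
            for j in range(i + 1, len(clusters)):
                mj = [index[c] for c in clusters[j].members]
                p = float(mat[np.ix_(mi, mj)].max())
                a, b = sorted([clusters[i].key, clusters[j].key])
                scored.append((-p, a, b, i, j))
        scored.sort()
        merged: set[int] = set()
        new_clusters: list[_Cluster] = []
        for negp, _, _, i, j in scored:
            if -negp <= thr or i in merged or j in merged:
                continue
            merged.update((i, j))
            new_clusters.append(_merge(clusters[i], clusters[j]))
        if not new_clusters:
            negp, _, _, i, j = scored[0]
            merged.update((i, j))
            new_clusters.append(_merge(clusters[i], clusters[j]))
        new_clusters.extend(c for k, c in enumerate(clusters) if k not in merged)
        new_clusters.sort(key=lambda c: c.key)
        clusters = new_clusters
        level += 1
    if len(clusters) == 2:
        clusters = [_merge(clusters[0], clusters[1])]
    return LineageTree(clusters[0].root)


def _merge(a: _Cluster, b: _Cluster) -> _Cluster:
    left, right = sorted([a, b], key=lambda c: c.key)
    parent = Node()
    parent.add_child(left.root)
    parent.add_child(right.root)
    return _Cluster(parent, left.members + right.members)
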