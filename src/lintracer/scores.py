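"""Tree-comparison scores: normalized Robinson-Foulds (RF), triplet (TRP),
quartet (QRT) and clustering-information (CLI).

All four scores lie in [0, 1]; 0 means the trees agree (identical splits /
triplets / quartets / clustering information), larger values mean less
similar.  RF, QRT and CLI treat the trees as unrooted; TRP compares rooted
triplet topologies and is therefore the only one of the four that can detect
a clade re-attached at a different height with the unrooted topology intact.

Triplet and quartet enumeration is exact below the documented cutoffs (512
and 100 leaves) and switches to seeded uniform subsampling above them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tree import LineageTree, Node

TRIPLET_EXACT_MAX = 512
QUARTET_EXACT_MAX = 100
SUBSAMPLE_SIZE = 100_000


class LeafSetMismatch(ValueError):
    pass


def _common_leaves(t1: LineageTree, t2: LineageTree) -> list[str]:
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise LeafSetMismatch(
            f"leaf sets differ: {sorted(l1 ^ l2)[:5]} not shared"
        )
    return sorted(l1)


# -- splits ----------------------------------------------------------------


def _nontrivial_splits(tree: LineageTree, order: list[str]) -> set[frozenset[int]]:
    """Unrooted nontrivial bipartitions as canonical leaf-index sets (the side
    not containing leaf 0)."""
    pos = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    splits: set[frozenset[int]] = set()

    def collect(node: Node) -> set[int]:
        if node.is_leaf:
            return {pos[node.label]}
        below = set()
        for c in node.children:
            below |= collect(c)
        if node.parent is not None and 2 <= len(below) <= n - 2:
            side = below if 0 not in below else set(range(n)) - below
            splits.add(frozenset(side))
        return below

    collect(tree.root)
    return splits


def rf_score(t1: LineageTree, t2: LineageTree) -> float:
    """Normalized RF: splits unique to either tree over the total nontrivial
    split count of both (2(n-3) when both trees are binary)."""
    order = _common_leaves(t1, t2)
    if len(order) < 4:
        raise ValueError("RF needs at least 4 leaves")
    s1 = _nontrivial_splits(t1, order)
    s2 = _nontrivial_splits(t2, order)
    total = len(s1) + len(s2)
    if total == 0:
        return 0.0
    return len(s1 ^ s2) / total


# -- LCA-depth machinery for triplets and quartets -------------------------


def _lca_depth_matrix(tree: LineageTree, order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(leaf depths, n x n matrix of LCA depths) with unit edge lengths."""
    pos = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    lca = np.zeros((n, n), dtype=np.int32)
    depth_of: dict[int, int] = {id(tree.root): 0}
    leaf_depth = np.zeros(n, dtype=np.int32)

    def walk(node: Node, d: int) -> np.ndarray:
        if node.is_leaf:
            i = pos[node.label]
            leaf_depth[i] = d
            lca[i, i] = d
            out = np.zeros(n, dtype=bool)
            out[i] = True
            return out
        sets = [walk(c, d + 1) for c in node.children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ia = np.flatnonzero(sets[a])
                ib = np.flatnonzero(sets[b])
                lca[np.ix_(ia, ib)] = d
                lca[np.ix_(ib, ia)] = d
        acc = sets[0]
        for s in sets[1:]:
            acc = acc | s
        return acc

    walk(tree.root, 0)
    return leaf_depth, lca


def _triplet_cherry(lca: np.ndarray, x, y, z) -> np.ndarray:
    """Status per triplet: 0 = xy cherry, 1 = xz, 2 = yz, 3 = unresolved."""
    dxy, dxz, dyz = lca[x, y], lca[x, z], lca[y, z]
    stacked = np.stack([dxy, dxz, dyz])
    top = stacked.max(axis=0)
    is_top = stacked == top
    n_top = is_top.sum(axis=0)
    out = np.where(n_top > 1, 3, np.argmax(is_top, axis=0))
    return out


def triplet_score(t1: LineageTree, t2: LineageTree, rng=None) -> float:
    """Fraction of leaf triples whose rooted topology differs; exact up to
    512 leaves, seeded uniform subsampling above."""
    order = _common_leaves(t1, t2)
    n = len(order)
    if n < 3:
        raise ValueError("TRP needs at least 3 leaves")
    _, lca1 = _lca_depth_matrix(t1, order)
    _, lca2 = _lca_depth_matrix(t2, order)
    if n <= TRIPLET_EXACT_MAX:
        differ = 0
        total = 0
        pair_idx = np.array(list(itertools.combinations(range(n), 2)), dtype=np.int64)
        for x in range(n - 2):
            rest = pair_idx[(pair_idx[:, 0] > x)]
            y, z = rest[:, 0], rest[:, 1]
            s1 = _triplet_cherry(lca1, x, y, z)
            s2 = _triplet_cherry(lca2, x, y, z)
            differ += int((s1 != s2).sum())
            total += len(y)
        return differ / total
    rng = rng if rng is not None else np.random.default_rng(0)
    samples = np.array(
        [rng.choice(n, size=3, replace=False) for _ in range(SUBSAMPLE_SIZE)]
    )
    x, y, z = samples[:, 0], samples[:, 1], samples[:, 2]
    s1 = _triplet_cherry(lca1, x, y, z)
    s2 = _triplet_cherry(lca2, x, y, z)
    return float((s1 != s2).mean())


def _quartet_pairing(D: np.ndarray, x, y, z, w) -> np.ndarray:
    """Status per quartet: 0 = xy|zw, 1 = xz|yw, 2 = xw|yz, 3 = unresolved,
    by the four-point condition on topological distances."""
    s0 = D[x, y] + D[z, w]
    s1 = D[x, z] + D[y, w]
    s2 = D[x, w] + D[y, z]
    stacked = np.stack([s0, s1, s2])
    lo = stacked.min(axis=0)
    is_lo = stacked == lo
    n_lo = is_lo.sum(axis=0)
    return np.where(n_lo > 1, 3, np.argmin(stacked, axis=0))


@dataclass
class QuartetTally:
    same: int = 0          # resolved identically in both
    different: int = 0     # resolved differently
    one_resolved: int = 0  # resolved in exactly one tree
    unresolved: int = 0    # unresolved in both
    total: int = 0

    def score(self) -> float:
        return (2 * self.different + self.one_resolved) / (2 * self.total)


def quartet_tally(t1: LineageTree, t2: LineageTree, rng=None) -> QuartetTally:
    order = _common_leaves(t1, t2)
    n = len(order)
    if n < 4:
        raise ValueError("QRT needs at least 4 leaves")
    d1, lca1 = _lca_depth_matrix(t1, order)
    d2, lca2 = _lca_depth_matrix(t2, order)
    D1 = d1[:, None] + d1[None, :] - 2 * lca1
    D2 = d2[:, None] + d2[None, :] - 2 * lca2
    tally = QuartetTally()

    def add(x, y, z, w):
        p1 = _quartet_pairing(D1, x, y, z, w)
        p2 = _quartet_pairing(D2, x, y, z, w)
        r1 = p1 != 3
        r2 = p2 != 3
        tally.same += int(((p1 == p2) & r1 & r2).sum())
        tally.different += int(((p1 != p2) & r1 & r2).sum())
        tally.one_resolved += int((r1 ^ r2).sum())
        tally.unresolved += int((~r1 & ~r2).sum())
        tally.total += len(np.atleast_1d(p1))

    if n <= QUARTET_EXACT_MAX:
        pair_idx = np.array(list(itertools.combinations(range(n), 2)), dtype=np.int64)
        for x in range(n - 3):
            for y in range(x + 1, n - 2):
                rest = pair_idx[pair_idx[:, 0] > y]
                add(x, y, rest[:, 0], rest[:, 1])
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        samples = np.array(
            [rng.choice(n, size=4, replace=False) for _ in range(SUBSAMPLE_SIZE)]
        )
        add(samples[:, 0], samples[:, 1], samples[:, 2], samples[:, 3])
    return tally


def quartet_score(t1: LineageTree, t2: LineageTree, rng=None) -> float:
    """Status-weighted quartet disagreement: (2d + r1 + r2) / (2 C(n,4));
    0 for identical binary trees, 0.5 for a binary tree against the star."""
    return quartet_tally(t1, t2, rng=rng).score()


# -- clustering information ------------------------------------------------


def _split_entropy(size_a: int, n: int) -> float:
    p = size_a / n
    if p in (0.0, 1.0):
        return 0.0
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (bits) between two leaf bipartitions from their
    2 x 2 overlap table."""
    n = len(a)
    mi = 0.0
    for sa in (a, ~a):
        for sb in (b, ~b):
            joint = np.sum(sa & sb) / n
            if joint == 0:
                continue
            mi += joint * np.log2(joint / ((sa.sum() / n) * (sb.sum() / n)))
    return mi


def clustering_info_components(
    t1: LineageTree, t2: LineageTree
) -> tuple[float, float, float]:
    """(H1, H2, S): total split entropies of each tree and the matched shared
    information under an optimal one-to-one split pairing."""
    order = _common_leaves(t1, t2)
    n = len(order)
    s1 = [np.array([i in s for i in range(n)]) for s in _nontrivial_splits(t1, order)]
    s2 = [np.array([i in s for i in range(n)]) for s in _nontrivial_splits(t2, order)]
    h1 = sum(_split_entropy(int(a.sum()), n) for a in s1)
    h2 = sum(_split_entropy(int(b.sum()), n) for b in s2)
    if not s1 or not s2:
        return h1, h2, 0.0
    mi = np.zeros((len(s1), len(s2)))
    for i, a in enumerate(s1):
        for j, b in enumerate(s2):
            mi[i, j] = _mutual_info(a, b)
    ri, ci = linear_sum_assignment(mi, maximize=True)
    return h1, h2, float(mi[ri, ci].sum())


def clustering_info_score(t1: LineageTree, t2: LineageTree) -> float:
    """Clustering-information distance (H1 + H2 - 2 S) normalized by the total
    information H1 + H2; 0 when the trees share all splits."""
    if len(_common_leaves(t1, t2)) < 4:
        raise ValueError("CLI needs at least 4 leaves")
    h1, h2, s = clustering_info_components(t1, t2)
    total = h1 + h2
    if total == 0:
        return 0.0
    value = float(np.clip((h1 + h2 - 2 * s) / total, 0.0, 1.0))
    return 0.0 if value < 1e-12 else value  # snap fp residue on shared splits


# -- combined report -------------------------------------------------------


@dataclass
class ScoreReport:
    rf: float
    trp: float
    qrt: float
    cli: float

    def as_dict(self) -> dict[str, float]:
        return {"rf": self.rf, "trp": self.trp, "qrt": self.qrt, "cli": self.cli}


def score_all(truth: LineageTree, pred: LineageTree, rng=None) -> ScoreReport:
    return ScoreReport(
        rf=rf_score(truth, pred),
        trp=triplet_score(truth, pred, rng=rng),
        qrt=quartet_score(truth, pred, rng=rng),
        cli=clustering_info_score(truth, pred),
    )
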