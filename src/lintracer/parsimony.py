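"""Maximum-parsimony baseline: Hamming/UPGMA starting tree, Fitch small
parsimony, and a parsimony-ratchet search over NNI rearrangements.

The ratchet alternates hill climbing on bootstrap-reweighted characters with
hill climbing on the original characters (the classic weighting trick to
escape local optima), accepting an iteration's tree only when it strictly
improves the unweighted score.  The rearrangement move set is
nearest-neighbor interchange only, which keeps the search honest and fast at
the colony sizes this package targets.  Parsimony scores are invariant to
rooting, so the rooted trees used throughout are scored as-is.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .matrix import BarcodeMatrix
from .tree import LineageTree, Node


# -- distances and UPGMA ---------------------------------------------------


def hamming_matrix(barcodes: BarcodeMatrix, chunk: int = 256) -> np.ndarray:
    """N x N matrix of Hamming distances (count of differing units)."""
    codes = barcodes.codes
    n = codes.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = codes[start:stop]
        out[start:stop] = (block[:, None, :] != codes[None, :, :]).sum(axis=2)
    return out


def upgma(dist: np.ndarray, labels: list[str]) -> LineageTree:
    """Average-linkage agglomeration into a rooted binary tree.

    Ties in the minimum distance are broken by the lowest (row, column) index
    pair, scanning row-major, which makes the result deterministic.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two items")
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    nodes: dict[int, Node] = {i: Node(label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        k = int(np.argmin(sub))
        ai, aj = divmod(k, len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        si, sj = sizes[i], sizes[j]
        for other in active:
            if other in (i, j):
                continue
            d[i, other] = d[other, i] = (si * d[i, other] + sj * d[j, other]) / (si + sj)
        nodes[i] = parent
        sizes[i] = si + sj
        active.remove(j)
    return LineageTree(nodes[active[0]])


def hamming_upgma_start(barcodes: BarcodeMatrix) -> LineageTree:
    """Deterministic UPGMA starting tree on barcode Hamming distances."""
    return upgma(hamming_matrix(barcodes), barcodes.cell_ids)


# -- array-coded trees for the jitted kernels ------------------------------


def _tree_to_arrays(
    tree: LineageTree, cell_order: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Encode a binary tree: leaves 0..n-1 (in ``cell_order``), internals
    n..2n-2; returns (child0, child1, root)."""
    if not tree.is_binary():
        raise ValueError("array coding requires a strictly binary tree")
    n = len(cell_order)
    pos = {lab: i for i, lab in enumerate(cell_order)}
    child0 = np.full(2 * n - 1, -1, dtype=np.int64)
    child1 = np.full(2 * n - 1, -1, dtype=np.int64)
    next_internal = [n]

    def assign(node: Node) -> int:
        if node.is_leaf:
            return pos[node.label]
        ids = [assign(c) for c in node.children]
        my = next_internal[0]
        next_internal[0] += 1
        child0[my], child1[my] = ids
        return my

    root = assign(tree.root)
    return child0, child1, root


def _arrays_to_tree(
    child0: np.ndarray, child1: np.ndarray, root: int, cell_order: list[str]
) -> LineageTree:
    n = len(cell_order)

    def build(idx: int) -> tuple[Node, str]:
        if idx < n:
            return Node(label=cell_order[idx]), cell_order[idx]
        a, ra = build(child0[idx])
        b, rb = build(child1[idx])
        node = Node()
        # canonical child order: smaller minimum leaf label first
        if ra <= rb:
            node.add_child(a)
            node.add_child(b)
            return node, ra
        node.add_child(b)
        node.add_child(a)
        return node, rb

    return LineageTree(build(root)[0])


@njit(cache=True)
def _postorder(child0, child1, root):
    n_nodes = len(child0)
    order = np.empty(n_nodes, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)
    top = 0
    stack[top] = root
    top += 1
    out = n_nodes - 1
    while top > 0:
        top -= 1
        node = stack[top]
        order[out] = node
        out -= 1
        if child0[node] >= 0:
            stack[top] = child0[node]
            top += 1
            stack[top] = child1[node]
            top += 1
    return order


@njit(cache=True)
def _fitch(child0, child1, root, leaf_masks, weights):
    """Weighted Fitch parsimony score by bottom-up union/intersection."""
    n_nodes = len(child0)
    n_sites = leaf_masks.shape[1]
    order = _postorder(child0, child1, root)
    masks = np.zeros((n_nodes, n_sites), dtype=np.uint8)
    score = 0.0
    for k in range(n_nodes):
        node = order[k]
        c0 = child0[node]
        if c0 < 0:
            for l in range(n_sites):
                masks[node, l] = leaf_masks[node, l]
        else:
            c1 = child1[node]
            for l in range(n_sites):
                inter = masks[c0, l] & masks[c1, l]
                if inter == 0:
                    masks[node, l] = masks[c0, l] | masks[c1, l]
                    score += weights[l]
                else:
                    masks[node, l] = inter
    return score


@njit(cache=True)
def _parents(child0, child1):
    parent = np.full(len(child0), -1, dtype=np.int64)
    for v in range(len(child0)):
        if child0[v] >= 0:
            parent[child0[v]] = v
            parent[child1[v]] = v
    return parent


@njit(cache=True)
def _replace_child(child0, child1, node, old, new):
    if child0[node] == old:
        child0[node] = new
    else:
        child1[node] = new


@njit(cache=True)
def _nni_hill_climb(child0, child1, root, leaf_masks, weights):
    """First-improvement NNI hill climb; mutates the child arrays in place
    and returns the local-optimum score."""
    parent = _parents(child0, child1)
    best = _fitch(child0, child1, root, leaf_masks, weights)
    improved = True
    while improved:
        improved = False
        for v in range(len(child0)):
            if v == root or child0[v] < 0:
                continue
            u = parent[v]
            w = child1[u] if child0[u] == v else child0[u]
            for which in range(2):
                x = child0[v] if which == 0 else child1[v]
                _replace_child(child0, child1, u, w, x)
                _replace_child(child0, child1, v, x, w)
                parent[x] = u
                parent[w] = v
                s = _fitch(child0, child1, root, leaf_masks, weights)
                if s < best - 1e-9:
                    best = s
                    improved = True
                    w = x  # the swapped-down node is v's sibling-side child now
                else:
                    _replace_child(child0, child1, u, x, w)
                    _replace_child(child0, child1, v, w, x)
                    parent[w] = u
                    parent[x] = v
    return best


def _leaf_masks(barcodes: BarcodeMatrix) -> np.ndarray:
    if barcodes.alphabet.n_states > 8:
        raise ValueError("bitmask coding supports at most 8 states")
    return (np.uint8(1) << barcodes.codes.astype(np.uint8)).astype(np.uint8)


def fitch_score(
    tree: LineageTree, barcodes: BarcodeMatrix, weights: np.ndarray | None = None
) -> float:
    """Minimum number of state changes needed on ``tree`` to explain the
    barcodes (sum over units of the Fitch count; states unordered)."""
    cell_order = barcodes.cell_ids
    if set(tree.leaf_labels()) != set(cell_order):
        raise ValueError("tree leaves and barcode cells differ")
    child0, child1, root = _tree_to_arrays(tree, cell_order)
    masks = _leaf_masks(barcodes)
    if weights is None:
        weights = np.ones(barcodes.n_units)
    score = _fitch(child0, child1, root, masks, np.asarray(weights, dtype=np.float64))
    return float(score)


def ratchet_search(
    start: LineageTree,
    barcodes: BarcodeMatrix,
    iterations: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[LineageTree, float]:
    """Parsimony-ratchet search from ``start``; returns (best tree, score).

    Each iteration reweights the characters by a multinomial bootstrap,
    hill-climbs on the weighted score, then hill-climbs on the unweighted
    score, keeping the tree only if it strictly improves.  Never returns a
    tree worse than the start.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    if rng is None:
        rng = np.random.default_rng()
    cell_order = barcodes.cell_ids
    child0, child1, root = _tree_to_arrays(start, cell_order)
    masks = _leaf_masks(barcodes)
    n_sites = barcodes.n_units
    unit = np.ones(n_sites, dtype=np.float64)

    best0, best1 = child0.copy(), child1.copy()
    best_score = _nni_hill_climb(best0, best1, root, masks, unit)
    for _ in range(iterations):
        w = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites)).astype(np.float64)
        c0, c1 = best0.copy(), best1.copy()
        _nni_hill_climb(c0, c1, root, masks, w)
        s = _nni_hill_climb(c0, c1, root, masks, unit)
        if s < best_score - 1e-9:
            best0, best1, best_score = c0, c1, s
    return _arrays_to_tree(best0, best1, root, cell_order), float(best_score)


def parsimony_reconstruct(
    barcodes: BarcodeMatrix,
    iterations: int = 100,
    rng: np.random.Generator | None = None,
) -> LineageTree:
    """Full baseline: Hamming/UPGMA start then ratchet refinement."""
    start = hamming_upgma_start(barcodes)
    tree, _ = ratchet_search(start, barcodes, iterations=iterations, rng=rng)
    return tree
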