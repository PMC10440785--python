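"""Pairwise barcode features and level-t relationship labels.

Each cell pair is embedded by tallying, position by position, the unordered
pair of state categories observed at each unit.  With the three-state
recorder (ground g, deletion e1, inversion e2) the bins carry their
conventional names:

    F1 = (g, g)    unedited in both cells
    F2 = (g, e1)   single edit, deletion side
    F3 = (g, e2)   single edit, inversion side
    F4 = (e1, e1)  same edit (deletion)
    F5 = (e1, e2)  different edits
    F6 = (e2, e2)  same edit (inversion)

For an alphabet with m = |S| + 1 categories there are m*(m+1)/2 unordered
bins, always summing to L.  Training labels come from the ground-truth tree:
a pair is positive at level t when the ancestors t edges above both leaves
exist and coincide (t = 1: siblings, t = 2: shares a grandparent, e.g.
cousins).  Positivity is monotone in t.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .matrix import Alphabet, BarcodeMatrix
from .simulate import Colony
from .tree import LineageTree


def feature_names(alphabet: Alphabet) -> list[str]:
    """Bin names F1..Fk in the fixed unordered-pair order (g,g), (g,e1), ...,
    (e1,e1), (e1,e2), ..., ordered by (i, j) with i <= j over category index."""
    m = alphabet.n_states
    return [f"F{b + 1}" for b in range(m * (m + 1) // 2)]


def feature_pair_map(alphabet: Alphabet) -> dict[str, tuple[str, str]]:
    """Audit map from bin name to the unordered category pair it counts."""
    syms = alphabet.symbols
    pairs = [(syms[i], syms[j]) for i in range(len(syms)) for j in range(i, len(syms))]
    return dict(zip(feature_names(alphabet), pairs))


def _bin_index_table(m: int) -> np.ndarray:
    """(m, m) lookup of unordered-pair bin index."""
    table = np.empty((m, m), dtype=np.int64)
    b = 0
    for i in range(m):
        for j in range(i, m):
            table[i, j] = table[j, i] = b
            b += 1
    return table


def pairwise_features(b1: np.ndarray, b2: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    """Feature vector for one cell pair: counts per unordered category-pair
    bin.  Symmetric in its arguments; entries sum to the barcode length."""
    b1 = np.asarray(b1)
    b2 = np.asarray(b2)
    if b1.shape != b2.shape:
        raise ValueError("barcode length mismatch")
    m = alphabet.n_states
    table = _bin_index_table(m)
    bins = table[b1, b2]
    return np.bincount(bins, minlength=m * (m + 1) // 2)


def all_pair_features(matrix: BarcodeMatrix) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Features for every unordered cell pair, vectorized.

    Returns the pair list (lexicographic by row order: (i, j), i < j) and a
    (n_pairs, n_bins) count matrix in the same order.
    """
    m = matrix.alphabet.n_states
    table = _bin_index_table(m)
    codes = matrix.codes
    n = matrix.n_cells
    ii, jj = np.triu_indices(n, k=1)
    n_bins = m * (m + 1) // 2
    n_pairs = len(ii)
    counts = np.empty((n_pairs, n_bins), dtype=np.int64)
    # block over pairs to bound memory on deep colonies (P x L intermediates)
    block = max(1, int(2e7) // max(matrix.n_units, 1))
    for start in range(0, n_pairs, block):
        stop = min(start + block, n_pairs)
        bins = table[codes[ii[start:stop]], codes[jj[start:stop]]]  # (B, L)
        offset = bins + n_bins * np.arange(stop - start)[:, None]
        counts[start:stop] = np.bincount(
            offset.ravel(), minlength=n_bins * (stop - start)
        ).reshape(stop - start, n_bins)
    pairs = [(matrix.cell_ids[i], matrix.cell_ids[j]) for i, j in zip(ii, jj)]
    return pairs, counts


def level_pair_labels(
    tree: LineageTree, t: int
) -> tuple[set[frozenset[str]], set[frozenset[str]]]:
    """Split all leaf pairs into those sharing their level-t ancestor and the
    rest.

    A pair is positive iff the ancestor t edges above each leaf exists and is
    the same node.  Leaves whose walk exits the root cannot share a level-t
    ancestor, so their pairs are negative at that level.
    """
    if t < 1:
        raise ValueError("level must be >= 1")
    groups: dict[int, list[str]] = {}
    for leaf in tree.leaves():
        anc = tree.ancestor_at_level(leaf, t)
        if anc is not None:
            groups.setdefault(id(anc), []).append(leaf.label)
    positives: set[frozenset[str]] = set()
    for members in groups.values():
        positives.update(frozenset(p) for p in itertools.combinations(members, 2))
    labels = tree.leaf_labels()
    all_pairs = {frozenset(p) for p in itertools.combinations(labels, 2)}
    return positives, all_pairs - positives


def build_training_table(colonies: list[Colony], levels: list[int]) -> pd.DataFrame:
    """Feature table for ML training: one row per (colony, level, cell pair),
    with the named feature counts, the level, and the boolean label."""
    if not colonies:
        raise ValueError("no colonies")
    frames = []
    for ci, colony in enumerate(colonies):
        if set(colony.tree.leaf_labels()) != set(colony.barcodes.cell_ids):
            raise ValueError(f"tree/matrix leaf mismatch in colony {ci}")
        names = feature_names(colony.barcodes.alphabet)
        pairs, counts = all_pair_features(colony.barcodes)
        pair_sets = [frozenset(p) for p in pairs]
        for t in levels:
            positives, _ = level_pair_labels(colony.tree, t)
            df = pd.DataFrame(counts, columns=names)
            df.insert(0, "colony", ci)
            df.insert(1, "cell_i", [p[0] for p in pairs])
            df.insert(2, "cell_j", [p[1] for p in pairs])
            df["level"] = t
            df["label"] = [ps in positives for ps in pair_sets]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
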