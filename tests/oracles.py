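"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: canonical-form tree
isomorphism, exhaustive enumeration of tree topologies and internal-state
assignments, ancestor walks, and naive split-based quartet topologies.
"""

import itertools

import numpy as np

from lintracer.tree import LineageTree, Node


def canonical_form(tree: LineageTree):
    def canon(node):
        if node.is_leaf:
            return node.label
        return tuple(sorted((canon(c) for c in node.children), key=str))

    return canon(tree.root)


def isomorphic(t1: LineageTree, t2: LineageTree) -> bool:
    return canonical_form(t1) == canonical_form(t2)


def all_rooted_binary_trees(labels):
    """Every rooted binary topology on the given leaves, by recursive
    bipartition: (2n-3)!! for n leaves rooted at the top split."""
    labels = list(labels)

    def build(subset):
        if len(subset) == 1:
            yield Node(label=subset[0])
            return
        first, rest = subset[0], subset[1:]
        for k in range(len(rest) + 1):
            for left_rest in itertools.combinations(rest, k):
                left = [first, *left_rest]
                right = [x for x in rest if x not in left_rest]
                if not right:
                    continue
                for lt_ in build(left):
                    for rt in build(right):
                        node = Node()
                        node.add_child(clone(lt_))
                        node.add_child(clone(rt))
                        yield node

    def clone(node):
        new = Node(label=node.label)
        for c in node.children:
            new.add_child(clone(c))
        return new

    for root in build(labels):
        yield LineageTree(root)


def brute_force_fitch(tree: LineageTree, states: dict[str, int], n_states: int) -> int:
    """Minimum changes over all internal-state assignments (single column)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = None
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        lookup = {id(n): s for n, s in zip(internals, assign)}

        def state(node):
            return states[node.label] if node.is_leaf else lookup[id(node)]

        changes = sum(
            state(c) != state(n) for n in internals for c in n.children
        )
        if best is None or changes < best:
            best = changes
    return best


def brute_force_level_labels(tree: LineageTree, t: int):
    """Positive pairs at level t by explicitly walking each leaf's ancestor
    chain."""
    chains = {}
    for leaf in tree.leaves():
        chain = []
        node = leaf
        while node.parent is not None:
            node = node.parent
            chain.append(node)
        chains[leaf.label] = chain
    positives = set()
    labels = sorted(chains)
    for a, b in itertools.combinations(labels, 2):
        ca, cb = chains[a], chains[b]
        if len(ca) >= t and len(cb) >= t and ca[t - 1] is cb[t - 1]:
            positives.add(frozenset((a, b)))
    return positives


def naive_quartet_topology(tree: LineageTree, quartet):
    """Quartet split via explicit bipartitions: returns a frozenset pairing
    like {{a,b},{c,d}} or None when unresolved."""
    q = set(quartet)
    clades = []
    for node in tree.preorder():
        leaves = frozenset(l.label for l in _leaves_under(node)) & q
        clades.append(leaves)
    for a, b in itertools.combinations(sorted(q), 2):
        pair = {a, b}
        other = q - pair
        for clade in clades:
            if clade == pair or clade == other:
                return frozenset((frozenset(pair), frozenset(other)))
    return None


def _leaves_under(node):
    out = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        stack.extend(cur.children)
    return out


def naive_splits(tree: LineageTree):
    """Nontrivial unrooted bipartitions, canonicalized as the side without
    the alphabetically first leaf."""
    all_leaves = frozenset(tree.leaf_labels())
    first = min(all_leaves)
    splits = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        below = frozenset(l.label for l in _leaves_under(node))
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = below if first not in below else all_leaves - below
            splits.add(side)
    return splits


def random_state_column(labels, n_states, rng) -> dict[str, int]:
    return {lab: int(rng.integers(n_states)) for lab in labels}


def geometric_sum_edit_probability(d, mu, alpha_s):
    """Term-by-term summation of the printed series for P(state s after d
    divisions)."""
    return sum((1 - mu) ** (k - 1) * mu * alpha_s for k in range(1, d + 1))
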