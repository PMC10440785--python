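"""Rooted lineage trees and Newick serialization.

A lineage tree is a rooted tree whose leaves are labeled with unique cell
identifiers.  Reconstruction always produces strictly binary trees, but parsed
trees may contain polytomies (e.g. the completely unresolved star tree used
when scoring degenerate reconstructions).  Branch lengths and internal labels
are accepted on input and preserved, but no computation in this package uses
them: every method here is topology-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


@dataclass
class Node:
    """One node of a rooted tree; leaves carry cell-identifier labels."""

    label: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class LineageTree:
    """Rooted tree with uniquely labeled leaves.

    Parameters
    ----------
    root
        Root node.  Leaf labels must be non-empty and unique.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.leaves():
            if not leaf.label:
                raise TreeValidationError("unlabeled leaf")
            if leaf.label in seen:
                raise TreeValidationError(f"duplicate leaf label {leaf.label!r}")
            seen.add(leaf.label)

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def leaf_depths(self) -> dict[str, int]:
        """Number of edges on each leaf's path to the root (= its ancestor
        count, i.e. how many divisions produced it)."""
        depths: dict[str, int] = {}
        stack: list[tuple[Node, int]] = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                depths[node.label] = d  # type: ignore[index]
            else:
                stack.extend((c, d + 1) for c in node.children)
        return depths

    def ancestor_at_level(self, leaf: Node, t: int) -> Node | None:
        """The ancestor ``t`` edges above ``leaf``, or None if the walk exits
        the root."""
        node: Node | None = leaf
        for _ in range(t):
            node = node.parent if node is not None else None
            if node is None:
                return None
        return node

    def copy(self) -> "LineageTree":
        def _copy(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return LineageTree(_copy(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"LineageTree({write_newick(self)!r})"


# -- Newick ---------------------------------------------------------------

_UNQUOTED_STOP = set("(),:;[]'\t\n ")


def parse_newick(text: str) -> LineageTree:
    """Parse a Newick string into a :class:`LineageTree`.

    Accepts quoted labels, branch lengths and polytomies; the terminating
    semicolon is optional.  Raises :class:`NewickError` naming the character
    offset of the first syntax problem, and :class:`TreeValidationError` on
    duplicate leaf labels.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos] in " \t\r\n":
            pos += 1

    def parse_label() -> str | None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            start = pos
            pos += 1
            out = []
            while True:
                if pos >= n:
                    raise NewickError("unterminated quoted label", start)
                ch = text[pos]
                if ch == "'":
                    if pos + 1 < n and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(ch)
                pos += 1
        start = pos
        while pos < n and text[pos] not in _UNQUOTED_STOP:
            pos += 1
        return text[start:pos] if pos > start else None

    def parse_length(node: Node) -> None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n and (text[pos] in "+-.eE" or text[pos].isdigit()):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < n and text[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= n:
                    raise NewickError("unmatched '('", open_at)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {text[pos]!r}", pos)
        node.label = parse_label()
        parse_length(node)
        return node

    skip_ws()
    if pos >= n:
        raise NewickError("empty Newick string", 0)
    root = parse_clade()
    skip_ws()
    if pos < n and text[pos] == ";":
        pos += 1
        skip_ws()
    if pos < n:
        raise NewickError(f"trailing characters after tree: {text[pos]!r}", pos)
    return LineageTree(root)


def _needs_quotes(label: str) -> bool:
    return any(c in _UNQUOTED_STOP for c in label)


def write_newick(tree: LineageTree, lengths: bool = False) -> str:
    """Serialize deterministically, children in stored order."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _fmt_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _fmt_label(node.label)
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    def _fmt_label(label: str | None) -> str:
        if label is None:
            return ""
        if _needs_quotes(label):
            return "'" + label.replace("'", "''") + "'"
        return label

    return fmt(tree.root) + ";"


def read_newick(path) -> LineageTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: LineageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- constructors used across the package ---------------------------------


def balanced_tree(depth: int, labels: list[str] | None = None) -> LineageTree:
    """Complete binary tree of the given depth with 2**depth leaves."""
    n = 2**depth
    if labels is None:
        labels = [f"c{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError(f"need {n} labels, got {len(labels)}")
    it = iter(labels)

    def build(d: int) -> Node:
        if d == 0:
            return Node(label=next(it))
        node = Node()
        node.add_child(build(d - 1))
        node.add_child(build(d - 1))
        return node

    return LineageTree(build(depth))


def star_tree(labels: list[str]) -> LineageTree:
    root = Node()
    for lab in labels:
        root.add_child(Node(label=lab))
    return LineageTree(root)


def random_binary_tree(labels: list[str], rng) -> LineageTree:
    """Uniform random sequential-addition binary tree on the given leaves."""
    labels = list(labels)
    if len(labels) == 1:
        return LineageTree(Node(label=labels[0]))
    rng.shuffle(labels)
    root = Node()
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    edges: list[Node] = list(root.children)
    for lab in labels[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        new_int = Node()
        new_leaf = Node(label=lab)
        idx = parent.children.index(target)
        parent.children[idx] = new_int
        new_int.parent = parent
        new_int.add_child(target)
        new_int.add_child(new_leaf)
        edges.extend([new_int, new_leaf])
    return LineageTree(root)
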