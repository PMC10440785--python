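"""Stochastic simulation of synchronously dividing colonies with irreversible
barcode editing.

A colony starts from a single cell carrying an all-ground array of L units.
Cells divide synchronously; after d divisions the colony has N = 2**d cells.
At every division each still-unedited unit of each daughter edits with
probability mu, landing in edit state s with probability alpha_s; an edited
unit is frozen forever after.  The per-unit marginals this process implies —
P(not edited after d divisions) = (1 - mu)**d and
P(state s) = alpha_s * (1 - (1 - mu)**d) — are what the inference module fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import Alphabet, BarcodeMatrix
from .tree import LineageTree, Node


@dataclass(frozen=True)
class EditModel:
    """Editing parameters: per-division, per-unit edit probability ``mu`` and
    the distribution ``alpha`` over edit states (aligned with
    ``alphabet.edits``)."""

    mu: float
    alpha: tuple[float, ...]
    alphabet: Alphabet

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if len(self.alpha) != len(self.alphabet.edits):
            raise ValueError("one alpha per edit state required")
        if any(a < 0 for a in self.alpha):
            raise ValueError("alpha must be nonnegative")
        if abs(sum(self.alpha) - 1.0) > 1e-12:
            raise ValueError("alpha must sum to 1")

    @classmethod
    def uniform(cls, mu: float, alphabet: Alphabet) -> "EditModel":
        k = len(alphabet.edits)
        return cls(mu=mu, alpha=(1.0 / k,) * k, alphabet=alphabet)


@dataclass
class Colony:
    """A simulated (or observed) colony: ground-truth tree, leaf barcodes and
    per-cell division counts.  ``internal_codes``, kept only by the simulator,
    maps internal node ids to their (unobservable) barcodes; reconstruction
    never sees it."""

    tree: LineageTree
    barcodes: BarcodeMatrix
    depths: dict[str, int]
    internal_codes: dict[int, np.ndarray] | None = None

    def __post_init__(self):
        if set(self.tree.leaf_labels()) != set(self.barcodes.cell_ids):
            raise ValueError("tree leaves and barcode cell ids differ")
        if any(d < 1 for d in self.depths.values()):
            raise ValueError("depths must be >= 1")


@dataclass
class SimConfig:
    """Sampling rules for a batch of simulated colonies.

    ``depths`` are drawn uniformly from ``depth_choices`` and ``mu`` from
    ``mu_choices`` (a point mass when a single value is given — e.g. the
    posterior-mean editing rate 0.15 of the three-state recorder — or an
    empirical posterior sample).
    """

    n_units: int
    depth_choices: tuple[int, ...] = (2, 3, 4, 5, 6)
    mu_choices: tuple[float, ...] = (0.15,)
    alphabet: Alphabet = field(default_factory=Alphabet.mouse_style)
    alpha: tuple[float, ...] | None = None  # None -> uniform over edit states
    n_colonies: int = 1

    def __post_init__(self):
        if not self.depth_choices:
            raise ValueError("empty depth distribution")
        if any(d < 1 for d in self.depth_choices):
            raise ValueError("depths must be >= 1")
        if self.n_units < 1:
            raise ValueError("need at least one unit")


def simulate_colony(
    n_units: int,
    depth: int,
    model: EditModel,
    rng: np.random.Generator,
    cell_prefix: str = "c",
) -> Colony:
    """Simulate one colony of 2**depth cells.

    Children inherit the parent barcode; each still-ground unit then edits
    independently with probability ``model.mu`` into state s w.p. alpha_s.
    Editing is irreversible, so along any root-to-leaf path a unit changes at
    most once.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    alpha = np.asarray(model.alpha)
    # state codes: 0 = ground, 1..|S| = edits
    edit_codes = np.arange(1, len(alpha) + 1, dtype=np.int8)

    root = Node()
    internal_codes: dict[int, np.ndarray] = {}
    root_code = np.zeros(n_units, dtype=np.int8)
    internal_codes[id(root)] = root_code

    leaf_counter = 0
    leaves: list[tuple[Node, np.ndarray]] = []
    frontier: list[tuple[Node, np.ndarray, int]] = [(root, root_code, 0)]
    while frontier:
        node, code, d = frontier.pop()
        if d == depth:
            leaf_counter += 1
            node.label = f"{cell_prefix}{leaf_counter}"
            leaves.append((node, code))
            continue
        for _ in range(2):
            child_code = code.copy()
            ground = child_code == 0
            n_ground = int(ground.sum())
            if n_ground:
                hits = rng.random(n_ground) < model.mu
                if hits.any():
                    states = rng.choice(edit_codes, size=int(hits.sum()), p=alpha)
                    idx = np.flatnonzero(ground)[hits]
                    child_code[idx] = states
            child = node.add_child(Node())
            if d + 1 < depth:
                internal_codes[id(child)] = child_code
            frontier.append((child, child_code, d + 1))

    tree = LineageTree(root)
    # frontier pops give an arbitrary leaf order; store rows in tree order
    order = {leaf.label: code for leaf, code in leaves}
    cell_ids = tree.leaf_labels()
    codes = np.stack([order[c] for c in cell_ids])
    barcodes = BarcodeMatrix(cell_ids, codes, model.alphabet)
    depths = {c: depth for c in cell_ids}
    return Colony(tree=tree, barcodes=barcodes, depths=depths, internal_codes=internal_codes)


def sample_experiment(config: SimConfig, rng: np.random.Generator) -> list[Colony]:
    """Simulate ``config.n_colonies`` colonies, each with its own depth and mu
    drawn from the configured choices.  Fully reproducible from the generator
    state."""
    colonies = []
    for i in range(config.n_colonies):
        depth = int(rng.choice(config.depth_choices))
        mu = float(rng.choice(config.mu_choices))
        if config.alpha is None:
            model = EditModel.uniform(mu, config.alphabet)
        else:
            model = EditModel(mu=mu, alpha=config.alpha, alphabet=config.alphabet)
        colonies.append(
            simulate_colony(config.n_units, depth, model, rng, cell_prefix=f"t{i + 1}_c")
        )
    return colonies


def leaf_depths(tree: LineageTree) -> dict[str, int]:
    """Per-leaf division counts: the number of ancestors on the root path."""
    return tree.leaf_depths()
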