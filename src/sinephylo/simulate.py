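"""Simulation of SINE insertion histories on a species tree.

Insertions are identity-by-descent markers: each event happens once on a
branch and is inherited by every descendant leaf, giving a perfectly
clade-consistent presence/absence column.  Real data deviate from this
ideal in known ways, each available here as an independent confounder:

* precise excision (rare) — a descendant subtree reverts to absence;
* near-parallel independent insertion — a second element at (nearly) the
  same locus on an unrelated branch;
* incomplete lineage sorting — an insertion polymorphic in an ancestral
  population sorts discordantly with the species tree, so the column
  follows an alternative resolution of a local trichotomy;
* missing data — PCR failure turns cells into "?".

Ground truth (per-branch insertion tallies keyed by clade) is returned
alongside the matrix so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .matrix import ABSENT, PRESENT, UNKNOWN, CharacterMatrix, Locus, TaxonPanel
from .trees import RootedTree

__all__ = ["SimConfig", "simulate_insertions", "random_binary_tree"]


def random_binary_tree(n_leaves: int, seed: int = 0,
                       labels=None, branch_length: float = 1.0) -> RootedTree:
    """A uniformly grown rooted binary tree (each new leaf attaches to a
    uniformly chosen edge, including the stem), unit branch lengths by
    default."""
    from .trees import Node

    if n_leaves < 2:
        raise InputError("need at least 2 leaves")
    labels = list(labels) if labels is not None else [f"t{i+1}"
                                                      for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise InputError("label count must equal n_leaves")
    rng = np.random.default_rng(seed)
    tree = RootedTree(Node())
    tree.root.add_child(Node(label=labels[0]))
    tree.root.add_child(Node(label=labels[1]))
    for label in labels[2:]:
        nodes = [n for n in tree.postorder()]
        tree.insert_leaf_on_edge(nodes[int(rng.integers(len(nodes)))], label)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = branch_length
    return tree


@dataclass
class SimConfig:
    """Parameters of an insertion-history simulation.

    ``insertion_rate`` is the expected number of insertions per unit
    branch length (events per branch are Poisson with mean
    rate × length).  Confounder probabilities apply independently per
    simulated column.  A fixed seed reproduces the output exactly.
    """

    tree: RootedTree
    insertion_rate: float = 2.0
    p_excision: float = 0.0
    p_parallel: float = 0.0
    p_ils: float = 0.0
    p_missing: float = 0.0
    seed: int = 0
    outgroups: tuple = ()

    def __post_init__(self):
        for name in ("p_excision", "p_parallel", "p_ils", "p_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be a probability, got {v}")
        if self.insertion_rate < 0:
            raise InputError("insertion rate must be non-negative")


def simulate_insertions(config: SimConfig) -> tuple[CharacterMatrix, dict]:
    """Simulate an insertion presence/absence matrix on the config tree.

    Returns ``(matrix, truth)`` where ``truth`` maps each branch's clade
    (descendant leaf set) to the number of insertions simulated on it,
    before any confounding.
    """
    tree = config.tree
    if not tree.is_binary():
        raise InputError("simulation requires a binary tree")
    rng = np.random.default_rng(config.seed)
    taxa = tree.leaf_labels()
    pos = {t: i for i, t in enumerate(taxa)}
    cm = tree.clade_map()

    branches = [n for n in tree.postorder() if n.parent is not None]
    truth: dict = {}
    columns: list[np.ndarray] = []
    ids: list[str] = []
    counter = 0

    for node in branches:
        length = node.length if node.length is not None else 1.0
        lam = config.insertion_rate * length
        k = int(rng.poisson(lam)) if lam > 0 else 0
        if k:
            truth[cm[node]] = truth.get(cm[node], 0) + k
        for _ in range(k):
            counter += 1
            lid = f"S{counter:04d}"
            col = np.zeros(len(taxa), dtype=np.int8)
            for t in cm[node]:
                col[pos[t]] = PRESENT
            col, extra = _confound(col, node, cm, pos, taxa, config, rng, lid)
            columns.append(col)
            ids.append(lid)
            for eid, ecol in extra:
                columns.append(ecol)
                ids.append(eid)

    if columns:
        states = np.stack(columns, axis=1)
        if config.p_missing > 0:
            mask = rng.random(states.shape) < config.p_missing
            states = np.where(mask, np.int8(UNKNOWN), states)
    else:
        states = np.zeros((len(taxa), 0), dtype=np.int8)
    panel = TaxonPanel(tuple(taxa), tuple(config.outgroups))
    loci = [Locus(lid, source="simulated") for lid in ids]
    return CharacterMatrix(panel, loci, states), truth


def _confound(col, node, cm, pos, taxa, config, rng, lid):
    """Apply per-column confounders; returns (column, extra_columns)."""
    extra = []
    if config.p_excision > 0 and rng.random() < config.p_excision:
        desc = _proper_descendants(node)
        if desc:
            revert = desc[int(rng.integers(len(desc)))]
            for t in cm[revert]:
                col[pos[t]] = ABSENT
    if config.p_parallel > 0 and rng.random() < config.p_parallel:
        others = [n for n in cm if n is not node and n.parent is not None
                  and not (cm[n] & cm[node])]
        if others:
            other = others[int(rng.integers(len(others)))]
            dup = np.zeros(len(taxa), dtype=np.int8)
            for t in cm[other]:
                dup[pos[t]] = PRESENT
            extra.append((f"{lid}A", dup))
    if config.p_ils > 0 and rng.random() < config.p_ils:
        discordant = _discordant_set(node, cm)
        if discordant is not None:
            col = np.zeros(len(taxa), dtype=np.int8)
            for t in discordant:
                col[pos[t]] = PRESENT
    return col, extra


def _proper_descendants(node):
    out, stack = [], list(node.children)
    while stack:
        cur = stack.pop()
        out.append(cur)
        stack.extend(cur.children)
    return out


def _discordant_set(node, cm):
    """Present set following an alternative resolution of the local
    trichotomy around the branch above ``node``: one child clade plus the
    sibling clade instead of the two children together."""
    if node.is_leaf or node.parent is None or len(node.children) != 2:
        return None
    parent = node.parent
    if len(parent.children) != 2:
        return None
    sib = next(c for c in parent.children if c is not node)
    return cm[node.children[0]] | cm[sib]
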