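"""Heuristic search for minimum-length Dollo trees, consensus and bootstrap.

The search is tiered: a perfect-phylogeny construction that is provably
optimal whenever the characters' present-taxon sets are pairwise
compatible, exhaustive enumeration for panels of up to 7 taxa, and
otherwise the classic parsimony recipe — a stepwise-addition starting
tree followed by hill-climbing rearrangement (NNI by default, SPR
optionally) until no neighbour improves the Dollo length.  All
tie-breaks are deterministic — first candidate in a fixed traversal
order — so a fixed seed reproduces the whole trajectory bit for bit.

Bootstrap support resamples loci with replacement, re-runs the search per
replicate and tallies the clades of the best tree; the consensus is
majority-rule (>50%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .dollo import TreeIndex, TreeScore, fast_length, reconstruct, synapomorphy_counts, tree_length
from .errors import InputError, SearchError
from .matrix import PRESENT, CharacterMatrix, TaxonPanel, classify_characters
from .trees import Node, RootedTree, tree_from_clades

__all__ = [
    "SearchConfig", "BootstrapResult",
    "search_mp_tree", "strict_consensus", "majority_rule_consensus",
    "bootstrap", "root_with_outgroups",
]


@dataclass
class SearchConfig:
    seed: int = 0
    addition_order: str = "as_given"      # "as_given" | "random"
    rearrangement: str = "nni"            # "nni" | "spr"
    max_equal_trees: int = 64
    collapse_unsupported: bool = False

    def __post_init__(self):
        if self.addition_order not in ("as_given", "random"):
            raise InputError(f"unknown addition order {self.addition_order!r}")
        if self.rearrangement not in ("nni", "spr"):
            raise InputError(f"unknown rearrangement {self.rearrangement!r}")


@dataclass
class BootstrapResult:
    replicates: int
    clade_freq: dict
    consensus: RootedTree
    failed_replicates: int = 0


# ------------------------------------------------------------------ search

def search_mp_tree(matrix: CharacterMatrix,
                   config: SearchConfig = None) -> tuple[list[RootedTree], TreeScore]:
    """Find minimum-length Dollo trees by stepwise addition + hill climbing.

    Returns all distinct equally-best topologies found (the optimum plus
    its equal-length rearrangement neighbours, up to
    ``config.max_equal_trees``), rooted on the panel outgroups when any
    are declared, together with the best tree's score.
    """
    config = config or SearchConfig()
    taxa = list(matrix.panel.taxa)
    if len(taxa) < 4:
        raise SearchError("tree search needs at least 4 taxa")
    cls = classify_characters(matrix)
    if cls.n_constant == matrix.n_loci:
        raise SearchError("no signal: every character is constant")

    states = matrix.states
    rng = np.random.default_rng(config.seed)
    order = list(range(len(taxa)))
    if config.addition_order == "random":
        order = list(rng.permutation(len(taxa)))

    def score(tree: RootedTree) -> int:
        return fast_length(TreeIndex(tree, taxa), states)

    # Every character needs at least one gain, so the Dollo length is
    # bounded below by the number of columns with a scored presence.  When
    # the present-taxon sets are pairwise compatible (nested or disjoint)
    # the perfect phylogeny displaying them attains that bound exactly and
    # is therefore provably minimum-length — no rearrangement can improve
    # it.  Otherwise it still makes a strong extra starting tree.
    lower_bound = int(((states == PRESENT).sum(axis=0) > 0).sum())
    comp = _compatibility_tree(matrix)
    if comp is not None and score(comp) == lower_bound:
        tree, best_len = comp, lower_bound
    elif len(taxa) <= 7:
        # the topology space is tiny (<= 10,395 rooted trees): search it
        # exhaustively instead of heuristically
        tree, best_len, extra = _exhaustive_search(taxa, score,
                                                   config.max_equal_trees)
    else:
        tree = _stepwise_addition(taxa, order, score)
        tree, best_len = _hill_climb(tree, score, config.rearrangement)
        if comp is not None:
            alt, alt_len = _hill_climb(comp, score, config.rearrangement)
            if alt_len < best_len:
                tree, best_len = alt, alt_len

    if len(taxa) <= 7 and comp is None:
        trees = [tree] + extra
    else:
        trees = [tree] + _equal_neighbours(tree, score, best_len,
                                           config.max_equal_trees)

    if matrix.panel.outgroups:
        trees = [root_with_outgroups(t, matrix.panel) for t in trees]
        trees = _dedupe(trees, config.max_equal_trees)
    if config.collapse_unsupported:
        trees = [collapse_unsupported_edges(t, matrix) for t in trees]
        trees = _dedupe(trees, config.max_equal_trees)
    return trees, tree_length(trees[0], matrix)


def _compatibility_tree(matrix: CharacterMatrix) -> Optional[RootedTree]:
    """The perfect phylogeny displaying every present-taxon set as a
    clade, or None when two characters' present sets overlap without
    nesting (no such tree exists)."""
    sets = set()
    for j in range(matrix.n_loci):
        col = matrix.states[:, j]
        ps = frozenset(t for t, s in zip(matrix.panel.taxa, col)
                       if s == PRESENT)
        if ps:
            sets.add(ps)
    sets = sorted(sets, key=lambda s: (-len(s), sorted(s)))
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            if a & b and not b <= a:   # sorted by size, so only b⊆a can nest
                return None
    return tree_from_clades(matrix.panel.taxa, sets)


def _exhaustive_search(taxa, score, cap):
    """Score every rooted binary topology; returns the first optimum, its
    length and the other equally-best trees (up to ``cap``)."""
    from .dollo import _rooted_shapes, _tree_from_shape

    best_len, best = None, []
    for shape in _rooted_shapes(len(taxa)):
        tree = _tree_from_shape(shape, taxa)
        length = score(tree)
        if best_len is None or length < best_len:
            best_len, best = length, [tree]
        elif length == best_len and len(best) < cap:
            best.append(tree)
    return best[0], best_len, best[1:]


def _stepwise_addition(taxa, order, score) -> RootedTree:
    first = [taxa[i] for i in order[:3]]
    cands = []
    for arrangement in ((0, 1, 2), (0, 2, 1), (1, 2, 0)):
        a, b, c = (first[k] for k in arrangement)
        root = Node()
        pair = root.add_child(Node())
        pair.add_child(Node(label=a))
        pair.add_child(Node(label=b))
        root.add_child(Node(label=c))
        cands.append(RootedTree(root))
    tree = min(cands, key=score)

    for i in order[3:]:
        label = taxa[i]
        best = None
        for child in list(tree.postorder()):
            attach = tree.insert_leaf_on_edge(child, label)
            length = score(tree)
            _undo_insert(tree, attach)
            if best is None or length < best[0]:
                best = (length, child)
        tree.insert_leaf_on_edge(best[1], label)
    return tree


def _undo_insert(tree: RootedTree, attach: Node) -> None:
    child = attach.children[0]
    parent = attach.parent
    if parent is None:
        child.parent = None
        tree.root = child
    else:
        idx = parent.children.index(attach)
        parent.children[idx] = child
        child.parent = parent


def _nni_edges(tree: RootedTree):
    """Internal non-root binary nodes, in postorder."""
    return [n for n in tree.postorder()
            if n.parent is not None and len(n.children) == 2
            and len(n.parent.children) == 2]


def _nni_swap(v: Node, which: int) -> tuple:
    """Swap v's ``which`` child with v's sibling; returns context to revert."""
    parent = v.parent
    sib_idx = 1 - parent.children.index(v)
    sib = parent.children[sib_idx]
    child = v.children[which]
    parent.children[sib_idx] = child
    child.parent = parent
    v.children[which] = sib
    sib.parent = v
    return (v, which, parent, sib_idx)


def _nni_revert(ctx) -> None:
    v, which, parent, sib_idx = ctx
    child = parent.children[sib_idx]
    sib = v.children[which]
    parent.children[sib_idx] = sib
    sib.parent = parent
    v.children[which] = child
    child.parent = v


def _hill_climb(tree, score, rearrangement) -> tuple[RootedTree, int]:
    best_len = score(tree)
    improved = True
    while improved:
        improved = False
        for v in _nni_edges(tree):
            for which in (0, 1):
                ctx = _nni_swap(v, which)
                length = score(tree)
                if length < best_len:
                    best_len = length
                    improved = True
                else:
                    _nni_revert(ctx)
            if improved:
                break
        if not improved and rearrangement == "spr":
            hit = _spr_pass(tree, score, best_len)
            if hit is not None:
                tree, best_len = hit
                improved = True
    return tree, best_len


def _spr_pass(tree, score, best_len):
    """One subtree-prune-regraft improvement pass; first improvement wins."""
    n_nodes = sum(1 for _ in tree.postorder())
    for pi in range(n_nodes):
        work = tree.copy()
        nodes = list(work.postorder())
        sub = nodes[pi]
        if sub.parent is None:
            continue
        sub.parent.remove_child(sub)
        work.suppress_unifurcations()
        if sum(1 for _ in work.postorder()) < 2:
            continue
        for child in list(work.postorder()):
            attach = work.insert_leaf_on_edge(child, "__stub__")
            attach.children[1] = sub
            sub.parent = attach
            length = score(work)
            if length < best_len:
                return work, length
            stub = Node(label="__stub__")
            stub.parent = attach
            attach.children[1] = stub
            _undo_insert(work, attach)
            sub.parent = None
    return None


def _equal_neighbours(tree, score, best_len, cap) -> list[RootedTree]:
    out = []
    seen = {_signature(tree)}
    for v in _nni_edges(tree):
        for which in (0, 1):
            ctx = _nni_swap(v, which)
            if score(tree) == best_len:
                sig = _signature(tree)
                if sig not in seen:
                    seen.add(sig)
                    out.append(tree.copy())
            _nni_revert(ctx)
            if len(out) + 1 >= cap:
                return out
    return out


def _signature(tree: RootedTree) -> frozenset:
    return frozenset(tree.clades(trivial=True))


def _dedupe(trees, cap):
    seen, out = set(), []
    for t in trees:
        sig = _signature(t)
        if sig not in seen:
            seen.add(sig)
            out.append(t)
        if len(out) >= cap:
            break
    return out


# --------------------------------------------------------------- consensus

def strict_consensus(trees: Sequence[RootedTree]) -> RootedTree:
    """Tree containing exactly the clades present in every input tree."""
    trees = list(trees)
    if not trees:
        raise InputError("strict consensus of an empty tree set")
    leafset = set(trees[0].leaf_labels())
    for t in trees[1:]:
        if set(t.leaf_labels()) != leafset:
            raise InputError("consensus requires identical leaf sets")
    common = set.intersection(*[set(t.clades()) for t in trees])
    return tree_from_clades(sorted(leafset), common)


def majority_rule_consensus(leaf_labels, clade_freq: dict,
                            min_freq: float = 0.5) -> RootedTree:
    """Majority-rule consensus from a clade frequency map (clades with
    frequency strictly above ``min_freq``; ties in compatibility resolved
    by frequency, then size)."""
    chosen: list[frozenset] = []
    for clade in sorted((c for c, f in clade_freq.items() if f > min_freq),
                        key=lambda c: (-clade_freq[c], -len(c), sorted(c))):
        if all(not (clade & c) or clade <= c or c <= clade for c in chosen):
            chosen.append(clade)
    return tree_from_clades(sorted(leaf_labels), chosen)


# --------------------------------------------------------------- bootstrap

def bootstrap(matrix: CharacterMatrix, reps: int,
              config: SearchConfig = None) -> BootstrapResult:
    """Nonparametric bootstrap over loci.

    Each replicate resamples ``n_loci`` columns with replacement, re-runs
    the heuristic search, and tallies the non-trivial clades of the first
    best tree.  Replicates whose resample carries no signal are recorded
    and skipped.  Deterministic for a fixed ``config.seed``.
    """
    if reps < 1:
        raise InputError("bootstrap needs at least one replicate")
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    tally: dict = {}
    done = failed = 0
    for _ in range(reps):
        idx = rng.integers(0, matrix.n_loci, matrix.n_loci)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sub = matrix.subset_loci(list(idx), relabel=True)
        try:
            trees, _ = search_mp_tree(sub, replace(config, seed=rep_seed))
        except SearchError:
            failed += 1
            continue
        done += 1
        for clade in trees[0].clades():
            tally[clade] = tally.get(clade, 0) + 1
    if done == 0:
        raise SearchError("every bootstrap replicate failed")
    freq = {clade: n / done for clade, n in tally.items()}
    consensus = majority_rule_consensus(matrix.panel.taxa, freq)
    return BootstrapResult(replicates=reps, clade_freq=freq,
                           consensus=consensus, failed_replicates=failed)


# ----------------------------------------------------------------- rooting

def root_with_outgroups(tree: RootedTree, panel: TaxonPanel) -> RootedTree:
    """Root the tree on the edge separating the outgroups from the ingroup.

    If the outgroups are not monophyletic in the unrooted sense, the root
    goes on the edge maximising the separation and the tree is flagged
    (``annotations['outgroup_monophyletic'] = False``).
    """
    og = set(panel.outgroups)
    if not og:
        raise InputError("panel declares no outgroups")
    leaves = set(tree.leaf_labels())
    if not og <= leaves:
        raise InputError("outgroup taxa missing from the tree")
    ingroup = leaves - og
    if not ingroup:
        raise InputError("outgroups cannot be the whole panel")

    tree = tree.copy()
    cm = tree.clade_map()
    for child in tree.root.children:
        if cm[child] == frozenset(ingroup) or cm[child] == frozenset(og):
            tree.annotations["outgroup_monophyletic"] = True
            return tree

    best, best_score = None, -1
    for node in tree.postorder():
        if node.parent is None:
            continue
        clade = cm[node]
        # orient the edge so the ingroup-like side is below it
        s = max(len(clade & ingroup) + len(og - clade),
                len(clade & og) + len(ingroup - clade))
        if s > best_score:
            best, best_score = node, s
    monophyletic = best_score == len(leaves)
    tree.reroot_above(best)
    # make sure the pure side is below the chosen child where possible
    tree.annotations["outgroup_monophyletic"] = monophyletic
    return tree


def collapse_unsupported_edges(tree: RootedTree,
                               matrix: CharacterMatrix) -> RootedTree:
    """Collapse internal edges carrying no unambiguous synapomorphy.

    Edges on the outgroup side of the root are kept (they are rooting
    structure, not insertion-supported claims)."""
    tree = tree.copy()
    rec = reconstruct(tree, matrix)
    counts, _ = synapomorphy_counts(rec, tree)
    og = set(matrix.panel.outgroups)
    cm = tree.clade_map()
    for node in list(tree.postorder()):
        if node.parent is None or node.is_leaf or node.parent.parent is None:
            continue
        clade = cm[node]
        if og and clade <= og:
            continue
        if counts.get(clade, 0) == 0:
            tree.collapse_edge(node)
            cm = tree.clade_map()
    return tree
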