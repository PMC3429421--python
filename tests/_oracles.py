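"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's scoring path: Dollo
steps are minimised by exhaustive enumeration of ancestral-state
assignments, and the trinomial test tail is summed with exact rational
arithmetic from the closed-form binomial expression.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def brute_force_dollo_steps(tree, column, taxa):
    """Minimal gains+losses over every ancestral-state assignment with at
    most one gain, counting a virtual all-absent ancestor above the root
    (so a root in state 1 costs one 'stem' gain).

    ``column`` maps taxa to states 1/0/-1 (-1 = unknown, minimised over).
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    unknown = [n for n in leaves if column[n.label] == -1]
    best = None
    for unk in product((0, 1), repeat=len(unknown)):
        leaf_state = {n.label: column[n.label] for n in leaves}
        for n, s in zip(unknown, unk):
            leaf_state[n.label] = s
        for assign in product((0, 1), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            for n in leaves:
                state[id(n)] = leaf_state[n.label]
            gains = losses = 0
            root = tree.root
            if state[id(root)] == 1:
                gains += 1          # stem gain from the all-absent ancestor
            for n in nodes:
                if n.parent is None:
                    continue
                sp, sc = state[id(n.parent)], state[id(n)]
                if sp == 0 and sc == 1:
                    gains += 1
                elif sp == 1 and sc == 0:
                    losses += 1
            if gains <= 1 and (best is None or gains + losses < best):
                best = gains + losses
    return best


def all_rooted_trees(labels):
    """Every rooted binary topology on the given leaf labels, as newick
    strings (grown by inserting each leaf on every edge incl. the stem)."""
    from sinephylo.trees import RootedTree

    shapes = [0]
    for leaf in range(1, len(labels)):
        shapes = [s2 for s in shapes for s2 in _insertions(s, leaf)]

    def nwk(s):
        if isinstance(s, int):
            return labels[s]
        return f"({nwk(s[0])},{nwk(s[1])})"

    return [RootedTree.from_newick(nwk(s) + ";") for s in shapes]


def _insertions(t, leaf):
    yield (t, leaf)
    if isinstance(t, tuple):
        a, b = t
        for sub in _insertions(a, leaf):
            yield (sub, b)
        for sub in _insertions(b, leaf):
            yield (a, sub)


def vectorised_dollo_oracle(tree, taxa):
    """Brute-force minimal Dollo steps for *all* binary columns on
    ``taxa`` at once (no unknowns).  Returns an array of length
    2**len(taxa) indexed by the column bitmask (bit i = taxon i present).

    Enumerates every internal-state assignment with numpy; a stem gain is
    charged when the root is in state 1; assignments with more than one
    gain are discarded.
    """
    nodes = list(tree.postorder())
    pos = {id(n): i for i, n in enumerate(nodes)}
    internal_idx = [i for i, n in enumerate(nodes) if not n.is_leaf]
    leaf_idx = [i for i, n in enumerate(nodes) if n.is_leaf]
    leaf_taxon = [taxa.index(nodes[i].label) for i in leaf_idx]
    n_taxa = len(taxa)
    n_int = len(internal_idx)
    n_cols = 2 ** n_taxa
    n_asn = 2 ** n_int

    cols = ((np.arange(n_cols)[:, None] >> np.arange(n_taxa)[None, :]) & 1
            ).astype(np.int8)                           # (cols, taxa)
    asn = ((np.arange(n_asn)[:, None] >> np.arange(n_int)[None, :]) & 1
           ).astype(np.int8)                            # (asn, internal)

    state = np.zeros((n_asn, n_cols, len(nodes)), dtype=np.int8)
    for k, i in enumerate(internal_idx):
        state[:, :, i] = asn[:, k][:, None]
    for i, t in zip(leaf_idx, leaf_taxon):
        state[:, :, i] = cols[:, t][None, :]

    gains = (state[:, :, pos[id(tree.root)]] == 1).astype(np.int32)
    losses = np.zeros((n_asn, n_cols), dtype=np.int32)
    for n in nodes:
        if n.parent is None:
            continue
        sp = state[:, :, pos[id(n.parent)]]
        sc = state[:, :, pos[id(n)]]
        gains += ((sp == 0) & (sc == 1))
        losses += ((sp == 1) & (sc == 0))
    steps = np.where(gains <= 1, gains + losses, np.iinfo(np.int32).max)
    return steps.min(axis=0)


def exact_trinomial_tail(k, m, n):
    """P(focal count >= k) for N = k+m+n markers under equal thirds,
    as an exact rational via the binomial closed form."""
    N = k + m + n
    if N == 0:
        return Fraction(1)
    p = Fraction(0)
    for a in range(k, N + 1):
        p += (Fraction(comb(N, a)) * Fraction(1, 3) ** a
              * Fraction(2, 3) ** (N - a))
    return p
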