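"""Per-branch insertion support and the likelihood-based significance test.

Each internal branch of a rooted species tree defines a local trichotomy:
with child clades X and Y below the branch and sibling clade Z next to it,
a clean insertion marker can land on X+Y (supporting the branch) or on
X+Z / Y+Z (supporting one of the two alternative resolutions).  Under the
null hypothesis that the trichotomy is a hard polytomy, each independent
marker supports one of the three resolutions with probability 1/3; the
significance of a branch with marker counts (k, m, n) is assessed by an
exact trinomial test.

The favourability ordering of outcomes is the one-sided likelihood ratio
for the prespecified (focal) resolution, which at a fixed total N is
monotone in the focal count, so the p-value reduces to the exact tail
P(K >= k) with K ~ Binomial(N, 1/3).  In particular a branch supported by
k markers with no conflict has p = (1/3)^k: one marker is never
significant (p = 1/3), six or more reach p < 0.01.  An "agnostic" variant
that does not prespecify the focal resolution (multiplying by the three
candidate resolutions, capped at 1) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

from .dollo import DolloReconstruction, reconstruct, synapomorphy_counts
from .errors import InputError
from .matrix import CharacterMatrix
from .search import BootstrapResult
from .trees import RootedTree

__all__ = ["BranchSupport", "branch_support_counts", "sine_likelihood_test",
           "stars_for", "annotate_tree"]


@dataclass
class BranchSupport:
    """Insertion support summary for one internal branch."""

    clade: frozenset            # descendant leaf set below the branch
    k_support: int              # unambiguous markers for this branch
    k_conflict_a: int           # markers for the X+Z resolution
    k_conflict_b: int           # markers for the Y+Z resolution
    p_value: float
    stars: str                  # "none" | "one" | "two"
    ambiguous: tuple = ()       # loss-requiring loci touching this branch


def sine_likelihood_test(k: int, m: int, n: int,
                         agnostic: bool = False) -> float:
    """Exact trinomial significance of an insertion-supported branch.

    Parameters are the marker counts for the focal resolution (``k``) and
    the two alternatives (``m``, ``n``).  Returns the probability, under
    the equal-thirds null, of an outcome at least as favourable to the
    focal resolution.  ``k = m = n = 0`` returns 1 by convention.
    """
    if min(k, m, n) < 0:
        raise InputError("marker counts must be non-negative")
    total = k + m + n
    if total == 0:
        return 1.0
    p = 0.0
    # enumerate the trinomial sample space; the LR ordering keeps exactly
    # the outcomes whose focal count reaches the observed one
    for a in range(total + 1):
        if a < k:
            continue
        for b in range(total - a + 1):
            c = total - a - b
            p += (comb(total, a) * comb(total - a, b)
                  * (1.0 / 3.0) ** total)
    if agnostic:
        p = min(1.0, 3.0 * p)
    return p


def stars_for(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    if not 0 < alpha2 < alpha1 < 1:
        raise InputError("significance thresholds must satisfy 0 < a2 < a1 < 1")
    if p < alpha2:
        return "two"
    if p < alpha1:
        return "one"
    return "none"


def branch_support_counts(matrix: CharacterMatrix, tree: RootedTree,
                          rec: Optional[DolloReconstruction] = None,
                          agnostic: bool = False) -> list[BranchSupport]:
    """Support and conflict counts, with significance, for every internal
    ingroup branch.

    Supporting markers come from the unambiguous synapomorphy map.  A
    conflicting marker is one whose present-taxon set is exactly one of
    the two alternative unions of the branch's local trichotomy; markers
    whose reconstruction requires losses are never counted as conflicts —
    they are listed as ambiguous.
    """
    rec = rec if rec is not None else reconstruct(tree, matrix)
    counts, ambiguous = synapomorphy_counts(rec, tree)
    present_sets: dict[frozenset, int] = {}
    for lid in matrix.locus_ids:
        ps = matrix.present_taxa(lid)
        if lid in ambiguous:
            continue
        present_sets[ps] = present_sets.get(ps, 0) + 1

    cm = tree.clade_map()
    og = set(matrix.panel.outgroups)
    out = []
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        clade = cm[node]
        if og and clade <= og:
            continue  # rooting structure, not an insertion-testable branch
        k = counts.get(clade, 0)
        m = n = 0
        amb = tuple(lid for lid in ambiguous
                    if rec[lid].gain_edge and (rec[lid].gain_edge & clade))
        if len(node.children) == 2 and len(node.parent.children) == 2:
            x, y = (cm[c] for c in node.children)
            sib = next(c for c in node.parent.children if c is not node)
            z = cm[sib]
            m = present_sets.get(frozenset(x | z), 0)
            n = present_sets.get(frozenset(y | z), 0)
        p = sine_likelihood_test(k, m, n, agnostic=agnostic)
        out.append(BranchSupport(clade=clade, k_support=k, k_conflict_a=m,
                                 k_conflict_b=n, p_value=p,
                                 stars=stars_for(p), ambiguous=amb))
    return out


def annotate_tree(tree: RootedTree, supports: Sequence[BranchSupport],
                  boot: Optional[BootstrapResult] = None,
                  matrix: Optional[CharacterMatrix] = None) -> RootedTree:
    """Attach support annotations to a copy of the tree.

    Internal ingroup edges receive ``bootstrap`` (percent), ``k``,
    ``p`` and ``stars``; pendant edges receive the count of taxon-specific
    (autapomorphic) insertions in an ``autapomorphies`` slot, following
    the convention of printing lineage-private counts in parentheses.
    """
    tree = tree.copy()
    cm = tree.clade_map()
    by_clade = {s.clade: s for s in supports}
    auta: dict[frozenset, int] = {}
    if matrix is not None:
        rec = reconstruct(tree, matrix)
        counts, _ = synapomorphy_counts(rec, tree)
        auta = {clade: c for clade, c in counts.items()
                if len(clade) == 1 and c > 0}
    for node in tree.postorder():
        if node.parent is None:
            continue
        clade = cm[node]
        if node.is_leaf:
            if clade in auta:
                node.annotations["autapomorphies"] = auta[clade]
            continue
        s = by_clade.get(clade)
        if s is not None:
            node.annotations["k"] = s.k_support
            node.annotations["p"] = f"{s.p_value:.3g}"
            node.annotations["stars"] = {"none": "", "one": "*",
                                         "two": "**"}[s.stars]
        if boot is not None and clade in boot.clade_freq:
            node.annotations["bootstrap"] = round(100 * boot.clade_freq[clade], 1)
    return tree
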