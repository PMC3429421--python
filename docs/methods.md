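# Methods

## Character model and polarity

A locus is a genomic position assayed for the presence of a SINE
insertion across a taxon panel. States are `1` (filled site, element
present), `0` (empty site) and `?` (no call — typically PCR
non-amplification). Polarity is fixed throughout: absence is ancestral
and presence derived, because each insertion is a unique historical event
and precise excision is rare. `?` cells never participate in majorities
or classification counts; they are excluded, not imputed, mirroring the
semantics of a failed amplification.

Characters are classified per locus from the scored (non-`?`) states:
*constant* (one state only, or entirely unknown — the latter flagged with
a warning rather than dropped, since silently removing a column would
desynchronise locus bookkeeping), *autapomorphic* (exactly one taxon
carries the minority state) and *parsimony-informative* (≥ 2 taxa in each
state). The three classes always partition the loci.

## Dollo scoring

Dollo parsimony allows one gain and any number of losses per character,
with the ancestral state absent. We model the ancestral constraint as a
virtual all-absent ancestor above the root: a root reconstructed as
present costs one "stem" gain. With that convention the minimal
reconstruction for a character with scored-present leaf set *P* is
closed-form:

* gain on the edge above MRCA(*P*) (the stem if *P* spans both root
  children — impossible for data with all-absent outgroups, but reachable
  in bootstrap resamples and simulated lineage-sorting columns);
* one loss per maximal subtree inside the gain clade containing a scored
  absence and no scored presence;
* `?` leaves take whichever state does not add steps — present inside the
  gain clade unless they fall inside a counted loss subtree, absent
  otherwise; ties resolve to absent, the conservative direction with
  respect to inferring insertions.

The test suite proves this equal to exhaustive minimisation over every
ancestral-state assignment with at most one gain, for every rooted binary
tree with up to 6 leaves and every binary column (and on random
unknown-bearing columns). Scoring is vectorised across characters: one
incidence-matrix product yields per-node present/absent leaf counts, after
which gain placement and loss counting are elementwise operations.
Multifurcating nodes need no special casing — losses are counted per
maximal all-absent child subtree.

## Ensemble indices

CI, HI and RI are computed over variable characters with per-character
minimum length 1 and the maximum taken over all rooted binary trees on
the scored taxa. The maximum is exact by enumeration of every rooted
topology for ≤ 8 scored taxa; above that the closed form (1 for a single
present leaf, otherwise 1 + n_absent) is used. The closed form comes from
the enumeration itself: a caterpillar interleaving the present leaves
isolates every absent leaf as its own loss, and disjoint loss subtrees
can never exceed the number of absent leaves. Note this is a *Dollo*
maximum — conventions that forbid stem gains or use Wagner maxima give
smaller values; the choice only matters for matrices with homoplasy,
since at CI = 1 the observed length already equals the minimum. RI is
reported as undefined when Σmax = Σmin (no informative characters).

## Tree search

`search_mp_tree` proceeds in three tiers:

1. **Perfect-phylogeny shortcut.** Total Dollo length is bounded below by
   the number of characters with at least one scored presence (each needs
   a gain). When the present-taxon sets are pairwise compatible (nested
   or disjoint) the tree displaying every such set as a clade attains that
   bound and is therefore provably minimum-length; it is returned without
   any rearrangement. Clean insertion data — and bootstrap resamples of
   it — take this path, which is what makes thousand-replicate bootstraps
   run in seconds.
2. **Exhaustive search** for panels of ≤ 7 taxa (≤ 10,395 rooted
   topologies), guaranteeing the optimum on small problems.
3. **Heuristic search** otherwise: stepwise addition (taxa inserted at the
   cheapest edge, first-tie-wins in a fixed traversal order) followed by
   hill climbing — NNI by default, with SPR passes (`rearrangement="spr"`)
   when NNI stalls. The compatibility tree, when it exists but is not
   provably optimal, seeds a second climb. All tie-breaks are
   deterministic, so a fixed seed reproduces the trajectory exactly.

Equally-best topologies encountered (the optimum's equal-length
rearrangement neighbours, or all optima in the exhaustive tier) are
deduplicated by clade set and returned up to `max_equal_trees`. Trees are
rooted on the declared outgroups; if the outgroups are not monophyletic
the root maximises the separation and the tree is flagged. Internal edges
carrying no unambiguous synapomorphy can be collapsed
(`collapse_unsupported`), which reports genuinely unresolved regions as
polytomies instead of arbitrary resolutions.

## Bootstrap

Each replicate resamples loci with replacement (same count), reruns the
search, and tallies the non-trivial clades of the first best tree.
Frequencies are relative to successful replicates; replicates whose
resample carries no signal are counted and skipped. The consensus is
majority-rule (> 50%), and per-replicate seeds derive from the master
seed, so results are byte-for-byte reproducible. The library default is
1,000 replicates — ample for clade frequencies read at whole-percent
resolution — with the count exposed for larger runs.

## Insertion significance test

An internal branch defines a local trichotomy (child clades X, Y;
sibling Z). Markers whose present sets are exactly X∪Y, X∪Z or Y∪Z are
counted as k, m, n; markers needing losses are listed as ambiguous and
never counted as conflicts, since apparent conflicts in real data
resolve, on sequencing, to independent events rather than homoplasy. The
p-value is the exact trinomial tail under the equal-thirds null, ordered
by the one-sided likelihood ratio for the prespecified branch — monotone
in k at fixed N, hence P(K ≥ k), K ~ Binomial(k+m+n, ⅓). Unopposed
support gives (⅓)ᵏ: k = 1 → 0.333, k = 3 → 0.037 (< 0.05), k ≥ 5 →
< 0.01. An agnostic variant that does not prespecify the resolution
(×3, capped at 1) is available behind a flag; the two variants agree on
every decision in the bundled reference data. Stars follow the
conventional thresholds: `*` p < 0.05, `**` p < 0.01.

## Locus screening

The screen consumes tool outputs rather than running the tools:
RepeatMasker `.out` rows (1-based inclusive coordinates, `C` orientation
mapped to `-`), precomputed outgroup alignment calls in a PSL-like table,
and PCR product sizes. Candidate filters are subfamily membership
(default: any `AluL*`) and strictly greater than 280 bp. Filled/empty
calls compare the product length to the empty-site and filled-site
windows (±`tol`, default 30 bp; overlapping windows are a configuration
error), with anything else — including no product — scored `?`.

Confounding events at a two-lineage locus are classified from three
evidence fields: subfamily identity, insertion-point offset, and
target-site-duplication (TSD) agreement. Same subfamily within
`offset_tol` (default 50 bp — the data give no canonical figure for
"nearly the same location", so it is an exposed configuration value) with
compatible TSDs is one orthologous element; different subfamilies or a
larger offset are near-parallel independent insertions, which directs
recoding of the locus into two lineage-specific characters; same
subfamily and position with contradictory TSDs is some other indel.
Unresolved TSDs do not veto orthology.

## Synthetic data

`simulate_insertions` draws insertions per branch from a Poisson law with
mean rate × branch length; each is present in exactly the descendant
leaves, giving clade-consistent columns with per-branch ground-truth
tallies. Confounders are independent per column: excision reverts a
random descendant subtree; near-parallel insertion adds a duplicate
column on a disjoint branch; lineage sorting swaps the present set to an
alternative resolution of the local trichotomy; missing data masks cells
to `?`. The generator reproduces byte-identically under a fixed seed.

What it does **not** emulate: insertion-rate heterogeneity across
branches and loci, ascertainment bias from discovering loci in a single
genome, alignment and primer failure correlated with divergence, and
polymorphic insertions segregating within species. Passing recovery tests
on these simulations therefore demonstrates correctness of the inference
machinery on identity-by-descent markers, not robustness to every
real-data pathology.

The 24-taxon reference matrix contains only loci whose clade placements
are stated explicitly in the source counts: 73 informative loci across
ten clades and 22 autapomorphic loci (95 total). Nodes whose counts are
not printed carry no loci, so the reference topology holds polytomies
there; the six loci excluding the aye-aye lineage are modelled as present
in all 21 remaining lemurs (placement is stated, per-taxon patterns are
an interpretation); one Indriidae locus with an ambiguous pattern is
omitted rather than guessed. Genome fixtures use i.i.d. uniform random
sequence — sufficient for parser and filter tests, with no repeat-like
sequence structure.

## Problem sizes and numerics

Default test and example scales — 24-taxon fixture, 8–12-leaf
simulations, 20 replicate recovery runs, 1,000-replicate bootstraps,
exhaustive oracles to 6–7 leaves — were chosen so every check is exact or
statistically overwhelming (e.g. the probability a fixture bootstrap
replicate misses all 19 markers of the Microcebus+Mirza clade is
(76/95)⁹⁵ ≈ 6×10⁻¹⁰) while the whole suite runs in well under a minute.
All randomness flows through seeded numpy generators; p-values are exact
tail sums in double precision; index computations are integer ratios
evaluated at the end.
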