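"""In-silico screening of repeat annotations for lineage-specific elements.

This mirrors the computational half of a SINE presence/absence marker
pipeline: parse RepeatMasker ``.out`` annotations, keep candidate elements
of the right subfamily and length, extract primer-design flanks, check
candidates against outgroup alignment hits, call filled/empty sites from
PCR product sizes, and classify confounding events (near-parallel
independent insertions vs. a shared orthologous element) from sequence
evidence.  Running RepeatMasker, BLAT or a primer designer is out of
scope — their outputs are inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError, NoCallError
from .matrix import ABSENT, PRESENT, UNKNOWN

__all__ = [
    "RepeatHit", "Flanks", "AmpliconObservation", "OrthologyCall",
    "InsertionAnnotation", "ConfoundCall",
    "parse_repeatmasker_out", "filter_candidates", "extract_flanks",
    "load_orthology_table", "select_lineage_specific",
    "call_presence", "classify_confounding", "recode_near_parallel",
]

DEFAULT_MIN_LEN = 280          # candidate elements must be strictly longer
DEFAULT_OFFSET_TOL = 50        # bp; "nearly the same location" window
ALUL_PREFIX = "AluL"


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker annotation record (1-based inclusive coordinates)."""

    contig: str
    begin: int
    end: int
    strand: str                 # "+" or "-"
    family: str                 # e.g. "AluL1", "AluJb"
    divergence: float = 0.0
    score: int = 0

    def __post_init__(self):
        if self.begin > self.end:
            raise InputError(f"hit on {self.contig}: begin {self.begin} > end {self.end}")
        if self.strand not in "+-":
            raise InputError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.begin + 1


def parse_repeatmasker_out(path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file.

    The standard layout is three header lines followed by whitespace-
    delimited records; header/blank lines are detected by a non-numeric
    first field.  Orientation ``C`` (complement) maps to strand ``-``.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].lstrip("-").isdigit():
                continue  # header or blank
            try:
                hits.append(RepeatHit(
                    score=int(fields[0]),
                    divergence=float(fields[1]),
                    contig=fields[4],
                    begin=int(fields[5]),
                    end=int(fields[6]),
                    strand="-" if fields[8] == "C" else fields[8],
                    family=fields[9],
                ))
            except (IndexError, ValueError, InputError) as exc:
                raise InputError(
                    f"{path}: malformed RepeatMasker record at line {lineno}: {exc}"
                ) from exc
    return hits


def filter_candidates(hits: Iterable[RepeatHit],
                      families: Optional[Iterable[str]] = None,
                      min_len: int = DEFAULT_MIN_LEN) -> list[RepeatHit]:
    """Keep hits of the target subfamilies strictly longer than ``min_len``.

    With ``families=None`` any subfamily whose name starts with ``AluL``
    qualifies; otherwise exact membership is required.  A hit of length
    exactly ``min_len`` is rejected (the length filter is strict).
    Idempotent by construction.
    """
    fam = set(families) if families is not None else None
    out = []
    for hit in hits:
        if fam is None:
            if not hit.family.startswith(ALUL_PREFIX):
                continue
        elif hit.family not in fam:
            continue
        if hit.length > min_len:
            out.append(hit)
    return out


@dataclass(frozen=True)
class Flanks:
    upstream: str
    downstream: str
    upstream_truncated: bool = False
    downstream_truncated: bool = False


def extract_flanks(contig_seq, hit: RepeatHit, flank: int) -> Flanks:
    """Flanking sequence on both sides of an element, for primer design.

    ``contig_seq`` is the contig sequence (a string or anything with
    ``str()`` semantics, e.g. a ``Bio.Seq``/``SeqRecord.seq``).  Flanks are
    truncated at contig ends, with truncation flagged.
    """
    seq = str(contig_seq.seq) if hasattr(contig_seq, "seq") else str(contig_seq)
    if flank < 1:
        raise ConfigurationError("flank length must be >= 1")
    if hit.begin < 1 or hit.end > len(seq):
        raise InputError(
            f"hit {hit.begin}-{hit.end} outside contig of length {len(seq)}")
    up_start = max(0, hit.begin - 1 - flank)
    upstream = seq[up_start:hit.begin - 1]
    downstream = seq[hit.end:hit.end + flank]
    return Flanks(upstream=upstream, downstream=downstream,
                  upstream_truncated=len(upstream) < flank,
                  downstream_truncated=len(downstream) < flank)


# ------------------------------------------------------- outgroup orthology

@dataclass(frozen=True)
class OrthologyCall:
    locus_id: str
    target: str
    status: str   # element_present | element_absent | no_orthologous_flank

    def __post_init__(self):
        if self.status not in ("element_present", "element_absent",
                               "no_orthologous_flank"):
            raise InputError(f"unknown orthology status {self.status!r}")


def load_orthology_table(path) -> list[OrthologyCall]:
    """Read a PSL-like tab-separated table of precomputed alignment calls
    with columns ``locus``, ``target``, ``status``."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "target", "status"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: need columns {sorted(required)}")
    return [OrthologyCall(str(r.locus), str(r.target), str(r.status))
            for r in df.itertuples()]


def select_lineage_specific(locus_ids: Iterable[str],
                            calls: Iterable[OrthologyCall],
                            targets: Iterable[str]) -> list[str]:
    """Loci absent from every outgroup target, with orthologous flank
    available in all of them (so primers can be designed)."""
    targets = set(targets)
    by_locus: dict[str, dict[str, str]] = {}
    for call in calls:
        by_locus.setdefault(call.locus_id, {})[call.target] = call.status
    out = []
    for lid in locus_ids:
        statuses = by_locus.get(lid, {})
        if targets <= set(statuses) and all(
                statuses[t] == "element_absent" for t in targets):
            out.append(lid)
    return out


# ----------------------------------------------------------- presence calls

@dataclass(frozen=True)
class AmpliconObservation:
    taxon: str
    product_length: Optional[int]     # None = no amplification
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.product_length is not None and self.product_length <= 0:
            raise InputError("product length must be positive")


def call_presence(observations: Sequence[AmpliconObservation],
                  empty_size: int, element_size: int,
                  tol: int = 30) -> dict[str, int]:
    """Filled/empty site calls from PCR product sizes.

    A product within ``tol`` of ``empty_size`` is an empty site (0); within
    ``tol`` of ``empty_size + element_size`` a filled site (1); no product,
    or a product outside both windows, is unresolved (?).  The two windows
    must not overlap.
    """
    if element_size <= 2 * tol:
        raise ConfigurationError(
            f"size windows overlap: element_size {element_size} <= 2*tol {2*tol}")
    filled_size = empty_size + element_size
    out: dict[str, int] = {}
    for obs in observations:
        if obs.product_length is None:
            out[obs.taxon] = UNKNOWN
        elif abs(obs.product_length - empty_size) <= tol:
            out[obs.taxon] = ABSENT
        elif abs(obs.product_length - filled_size) <= tol:
            out[obs.taxon] = PRESENT
        else:
            out[obs.taxon] = UNKNOWN
    return out


# --------------------------------------------------- confounding events

@dataclass(frozen=True)
class InsertionAnnotation:
    """Sequence-derived evidence for one taxon's element at a locus."""

    taxon: str
    subfamily: str
    insertion_point: int          # bp position in shared flank coordinates
    tsd: Optional[str] = None     # target site duplication, if resolved


@dataclass(frozen=True)
class ConfoundCall:
    locus_id: str
    verdict: str   # orthologous_same_element | near_parallel_independent | other_indel
    subfamily_match: bool
    offset_bp: int
    tsd_match: Optional[bool]


def classify_confounding(locus_id: str,
                         annotations: Sequence[InsertionAnnotation],
                         offset_tol: int = DEFAULT_OFFSET_TOL) -> ConfoundCall:
    """Decide whether elements observed in two or more lineages are the
    same insertion event.

    Rules (evidence-only, in order): same subfamily AND insertion points
    within ``offset_tol`` AND compatible TSDs → the same orthologous
    element; different subfamilies OR offset beyond ``offset_tol`` →
    near-parallel independent insertions (the locus should be recoded as
    two characters); same subfamily at the same spot with incompatible
    TSDs → some other indel event.
    """
    annotations = list(annotations)
    if len(annotations) < 2:
        raise NoCallError(f"{locus_id}: need elements from >=2 taxa to classify")
    if any(a.insertion_point is None for a in annotations):
        raise NoCallError(f"{locus_id}: unalignable flanks, no insertion point")
    subfams = {a.subfamily for a in annotations}
    points = [a.insertion_point for a in annotations]
    offset = max(points) - min(points)
    tsds = [a.tsd for a in annotations]
    tsd_match: Optional[bool]
    if any(t is None for t in tsds):
        tsd_match = None              # unresolved TSDs do not veto orthology
    else:
        tsd_match = len(set(tsds)) == 1
    subfamily_match = len(subfams) == 1
    if not subfamily_match or offset > offset_tol:
        verdict = "near_parallel_independent"
    elif tsd_match is False:
        verdict = "other_indel"
    else:
        verdict = "orthologous_same_element"
    return ConfoundCall(locus_id=locus_id, verdict=verdict,
                        subfamily_match=subfamily_match, offset_bp=offset,
                        tsd_match=tsd_match)


def recode_near_parallel(matrix, locus_id: str,
                         groups: tuple[Iterable[str], Iterable[str]],
                         new_suffix: str = "A"):
    """Split one confounded locus into two independent characters.

    ``groups`` are the two taxon sets carrying the two independent
    elements (e.g. the Cheirogaleidae set keeps the original id, the
    Indriidae set gets the ``A``-suffixed one).  Returns a new matrix with
    one extra column; taxa outside either group keep their original state
    in both columns unless they were scored present, which would
    contradict the two-element interpretation.
    """
    from .matrix import CharacterMatrix, Locus  # local import: avoid cycle

    ga, gb = (set(g) for g in groups)
    if ga & gb:
        raise InputError("recoding groups must be disjoint")
    j = matrix.locus_ids.index(locus_id)
    col = matrix.states[:, j]
    present = {t for t, s in zip(matrix.panel.taxa, col) if s == PRESENT}
    if not present <= (ga | gb):
        raise InputError(
            f"{locus_id}: present taxa {sorted(present - ga - gb)} outside "
            "both recoding groups")
    import numpy as np
    col_a = col.copy()
    col_b = col.copy()
    for i, t in enumerate(matrix.panel.taxa):
        if t in gb:
            col_a[i] = ABSENT if col[i] == PRESENT else col[i]
        if t in ga:
            col_b[i] = ABSENT if col[i] == PRESENT else col[i]
    states = np.insert(np.delete(matrix.states, j, axis=1), j, col_a, axis=1)
    states = np.insert(states, j + 1, col_b, axis=1)
    old = matrix.loci[j]
    loci = list(matrix.loci)
    loci[j] = Locus(old.id, old.source, old.note)
    loci.insert(j + 1, Locus(old.id + new_suffix, old.source,
                             f"recoded from {old.id} (near-parallel insertion)"))
    return CharacterMatrix(matrix.panel, loci, states)
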