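"""Presence/absence character matrices and their I/O.

The central object is :class:`CharacterMatrix`: a taxa × loci table of
binary insertion states with missing data.  State semantics follow the
standard retroelement coding — ``1`` a filled site (element present, the
derived state), ``0`` an empty site (ancestral absence), ``?`` no call
(e.g. no PCR amplification).  Polarity is fixed: absence is ancestral.

Supported formats: a simple CSV table (taxa in rows, loci in columns) and
NEXUS with TAXA/CHARACTERS blocks plus an ASSUMPTIONS block declaring all
characters Dollo.up, ready for external parsimony programs.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .errors import InputError, MatrixFormatError

__all__ = [
    "PRESENT", "ABSENT", "UNKNOWN",
    "TaxonPanel", "Locus", "CharacterMatrix", "CharacterClass",
    "read_matrix_csv", "write_matrix_csv", "write_nexus", "read_nexus",
    "classify_characters",
]

PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

_SYMBOL = {PRESENT: "1", ABSENT: "0", UNKNOWN: "?"}
_STATE = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}

LOCUS_SOURCES = ("this_study", "herke2007", "roos2004", "fixture", "simulated")


@dataclass(frozen=True)
class TaxonPanel:
    """An ordered panel of taxa with a designated outgroup subset."""

    taxa: tuple[str, ...]
    outgroups: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "outgroups", tuple(self.outgroups))
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("taxon labels must be unique")
        missing = set(self.outgroups) - set(self.taxa)
        if missing:
            raise InputError(f"outgroups not in panel: {sorted(missing)}")

    @property
    def ingroup(self) -> tuple[str, ...]:
        og = set(self.outgroups)
        return tuple(t for t in self.taxa if t not in og)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def __len__(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class Locus:
    id: str
    source: str = "this_study"
    note: str = ""

    def __post_init__(self):
        if self.source not in LOCUS_SOURCES:
            raise InputError(f"unknown locus source {self.source!r}")


class CharacterMatrix:
    """Taxa × loci binary-with-missing character matrix.

    States are stored as an ``int8`` array with values ``1`` (present),
    ``0`` (absent) and ``-1`` (unknown).  Row order follows the panel,
    column order the locus list; both are stable under round-trip I/O.
    """

    def __init__(self, panel: TaxonPanel, loci: Sequence[Locus],
                 states: np.ndarray):
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(panel), len(loci)):
            raise InputError(
                f"states shape {states.shape} does not match "
                f"{len(panel)} taxa x {len(loci)} loci")
        bad = ~np.isin(states, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            raise InputError("states must be 1, 0 or -1 (unknown)")
        ids = [loc.id for loc in loci]
        if len(set(ids)) != len(ids):
            raise InputError("locus ids must be unique within a matrix")
        self.panel = panel
        self.loci = tuple(loci)
        self.states = states

    # ------------------------------------------------------------- access
    @property
    def n_taxa(self) -> int:
        return len(self.panel)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(loc.id for loc in self.loci)

    def state(self, taxon: str, locus_id: str) -> int:
        return int(self.states[self.panel.index(taxon),
                               self.locus_ids.index(locus_id)])

    def column(self, locus_id: str) -> np.ndarray:
        return self.states[:, self.locus_ids.index(locus_id)].copy()

    def present_taxa(self, locus_id: str) -> frozenset:
        col = self.states[:, self.locus_ids.index(locus_id)]
        return frozenset(t for t, s in zip(self.panel.taxa, col) if s == PRESENT)

    def subset_loci(self, indices: Sequence[int],
                    relabel: bool = False) -> "CharacterMatrix":
        """Column subset (with repetition allowed — used for bootstrap
        resampling).  With ``relabel`` duplicated loci get unique ids."""
        loci = []
        seen: dict[str, int] = {}
        for i in indices:
            loc = self.loci[i]
            if relabel:
                n = seen.get(loc.id, 0)
                seen[loc.id] = n + 1
                if n:
                    loc = Locus(f"{loc.id}.r{n}", loc.source, loc.note)
            loci.append(loc)
        return CharacterMatrix(self.panel, loci, self.states[:, list(indices)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        # identity = panel, locus ids and states; locus provenance
        # (source/note) is annotation and not carried by the file formats
        return (self.panel == other.panel
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.states, other.states))

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_loci} loci>"


@dataclass
class CharacterClass:
    """Per-locus classification into constant / autapomorphic /
    parsimony-informative, with warnings for all-unknown columns."""

    labels: dict[str, str]
    warnings: tuple[str, ...] = ()

    @property
    def n_constant(self) -> int:
        return sum(1 for v in self.labels.values() if v == "constant")

    @property
    def n_autapomorphic(self) -> int:
        return sum(1 for v in self.labels.values() if v == "autapomorphic")

    @property
    def n_informative(self) -> int:
        return sum(1 for v in self.labels.values()
                   if v == "parsimony_informative")


# ------------------------------------------------------------------ CSV I/O

def read_matrix_csv(path, outgroups: Iterable[str] = ()) -> CharacterMatrix:
    """Read a CSV matrix: header row of locus ids (first cell ignored),
    one row per taxon, cells in {0,1,?}."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise MatrixFormatError(f"{path}: need a header row and >=1 taxon row")
    header = rows[0]
    ncol = len(header)
    locus_ids = header[1:]
    taxa, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise MatrixFormatError(
                f"{path}: row {r} has {len(row)} fields, expected {ncol}")
        taxa.append(row[0])
        states = []
        for c, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell not in _STATE:
                raise MatrixFormatError(
                    f"{path}: illegal state {cell!r} at row {r}, column {c} "
                    f"(taxon {row[0]!r}, locus {header[c-1]!r})")
            states.append(_STATE[cell])
        data.append(states)
    panel = TaxonPanel(tuple(taxa), tuple(outgroups))
    loci = [Locus(lid) for lid in locus_ids]
    return CharacterMatrix(panel, loci, np.array(data, dtype=np.int8))


def write_matrix_csv(matrix: CharacterMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", *matrix.locus_ids])
        for i, taxon in enumerate(matrix.panel.taxa):
            w.writerow([taxon, *(_SYMBOL[int(s)] for s in matrix.states[i])])


# ---------------------------------------------------------------- NEXUS I/O

def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Emit NEXUS with TAXA and CHARACTERS blocks and an ASSUMPTIONS block
    setting every character to Dollo.up (single gain, ancestral absence)."""
    ntax, nchar = matrix.n_taxa, matrix.n_loci
    pad = max(len(t) for t in matrix.panel.taxa) + 2
    lines = ["#NEXUS", ""]
    if matrix.panel.outgroups:
        lines.append("[!outgroups: " + " ".join(matrix.panel.outgroups) + "]")
    lines += [
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={ntax};",
        "    TAXLABELS",
        *(f"        {t}" for t in matrix.panel.taxa),
        "    ;",
        "END;",
        "",
        "BEGIN CHARACTERS;",
        f"    DIMENSIONS NCHAR={nchar};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    CHARLABELS",
        *(f"        {lid}" for lid in matrix.locus_ids),
        "    ;",
        "    MATRIX",
    ]
    for i, taxon in enumerate(matrix.panel.taxa):
        row = "".join(_SYMBOL[int(s)] for s in matrix.states[i])
        lines.append(f"        {taxon:<{pad}}{row}")
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN ASSUMPTIONS;",
        f"    CTYPE Dollo.up: 1-{nchar};",
        "END;",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS standard matrix written by :func:`write_nexus` (or any
    01/? standard matrix).  Character labels and the outgroup comment are
    recovered when present."""
    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus",
                                              preserve_underscores=True)
    taxa = [t.label for t in cm.taxon_namespace]
    data = []
    for taxon in cm.taxon_namespace:
        row = []
        for cell in cm[taxon]:
            sym = str(cell.symbol) if hasattr(cell, "symbol") else str(cell)
            if sym not in _STATE:
                raise MatrixFormatError(f"{path}: unexpected symbol {sym!r}")
            row.append(_STATE[sym])
        data.append(row)
    text = open(path).read()
    locus_ids = _parse_charlabels(text)
    nchar = len(data[0]) if data else 0
    if locus_ids is None:
        locus_ids = [f"char{i+1}" for i in range(nchar)]
    if len(locus_ids) != nchar:
        raise MatrixFormatError(
            f"{path}: {len(locus_ids)} CHARLABELS for {nchar} characters")
    m = re.search(r"\[!outgroups:\s*([^\]]+)\]", text)
    outgroups = tuple(m.group(1).split()) if m else ()
    panel = TaxonPanel(tuple(taxa), outgroups)
    return CharacterMatrix(panel, [Locus(lid) for lid in locus_ids],
                           np.array(data, dtype=np.int8))


def _parse_charlabels(text: str) -> Optional[list[str]]:
    m = re.search(r"CHARLABELS\s+(.*?);", text, re.S | re.I)
    if not m:
        return None
    return m.group(1).split()


# ----------------------------------------------------------- classification

def classify_characters(matrix: CharacterMatrix) -> CharacterClass:
    """Classify each locus from its non-unknown states.

    constant
        all scored taxa share one state (or the column is entirely
        unknown, which is flagged);
    autapomorphic
        exactly one taxon carries the minority state;
    parsimony_informative
        at least two taxa present and two absent.
    """
    if matrix.n_loci == 0:
        raise InputError("cannot classify an empty matrix")
    labels: dict[str, str] = {}
    warns: list[str] = []
    for j, lid in enumerate(matrix.locus_ids):
        col = matrix.states[:, j]
        n1 = int((col == PRESENT).sum())
        n0 = int((col == ABSENT).sum())
        if n1 == 0 and n0 == 0:
            labels[lid] = "constant"
            warns.append(f"locus {lid!r} is entirely unknown; "
                         "classified constant")
        elif n1 == 0 or n0 == 0:
            labels[lid] = "constant"
        elif n1 >= 2 and n0 >= 2:
            labels[lid] = "parsimony_informative"
        else:
            labels[lid] = "autapomorphic"
    return CharacterClass(labels, tuple(warns))
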