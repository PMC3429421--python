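"""Reference fixtures: the 24-taxon lemur panel and matrix, synthetic
genomes with implanted elements, and a near-parallel-insertion fixture.

The lemur matrix is reconstructed from per-clade locus counts reported
for the 24-species panel (22 Lemuriformes plus *Galago senegalensis* and
*Homo sapiens* as outgroups): 95 loci whose placements are stated
explicitly in the running text.  Nodes whose counts are not printed in
text carry no fixture loci, so the fixture tree has polytomies there;
counts are never invented.  Named loci that are placeable from the text
(MmM97, LI1, PcC1, PcC2, MmA2c, MmA20A, Str67A, Str71B, Str59, Em6,
MmA27) keep their published ids; the remainder get systematic ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import PRESENT, CharacterMatrix, Locus, TaxonPanel
from .screen import InsertionAnnotation
from .trees import RootedTree, tree_from_clades

__all__ = [
    "LEMUR_TAXA", "OUTGROUPS", "LEMUR_CLADES",
    "build_lemur_fixture", "lemur_reference_tree",
    "build_genome_fixture", "GenomeFixture",
    "inject_confounder_fixture", "ConfounderFixture",
]

OUTGROUPS = ("Galago_senegalensis", "Homo_sapiens")

EULEMUR = (
    "Eulemur_coronatus", "Eulemur_albifrons", "Eulemur_collaris",
    "Eulemur_fulvus", "Eulemur_sanfordi", "Eulemur_macaco",
    "Eulemur_flavifrons", "Eulemur_mongoz", "Eulemur_rubriventer",
)
# the macaco group (E. macaco, E. flavifrons) plus the four panel species
# of the fulvus group
MACACO_FULVUS = (
    "Eulemur_albifrons", "Eulemur_collaris", "Eulemur_fulvus",
    "Eulemur_sanfordi", "Eulemur_macaco", "Eulemur_flavifrons",
)
LEMURIDAE = (
    "Lemur_catta", *EULEMUR, "Hapalemur_griseus_griseus",
    "Varecia_variegata_rubra", "Varecia_variegata_variegata",
)
CHEIROGALEIDAE = ("Microcebus_murinus", "Mirza_coquereli", "Cheirogaleus_medius")
INDRIIDAE = ("Avahi_laniger", "Propithecus_coquereli",
             "Propithecus_coronatus", "Propithecus_verreauxi")

LEMUR_TAXA = (
    "Lemur_catta",
    *EULEMUR,
    "Hapalemur_griseus_griseus",
    "Varecia_variegata_rubra",
    "Varecia_variegata_variegata",
    *CHEIROGALEIDAE,
    "Lepilemur_ruficaudatus",
    *INDRIIDAE,
    "Daubentonia_madagascariensis",
    *OUTGROUPS,
)

LEMURS = tuple(t for t in LEMUR_TAXA if t not in OUTGROUPS)
NON_DAUBENTONIA = tuple(t for t in LEMURS
                        if t != "Daubentonia_madagascariensis")
LEPILEMUR_CHEIROGALEIDAE = ("Lepilemur_ruficaudatus", *CHEIROGALEIDAE)
INDRIIDAE_LEMURIDAE = (*INDRIIDAE, *LEMURIDAE)
LEMUR_HAPALEMUR = ("Lemur_catta", "Hapalemur_griseus_griseus")
LEMUR_HAPALEMUR_EULEMUR = ("Lemur_catta", "Hapalemur_griseus_griseus", *EULEMUR)
MICROCEBUS_MIRZA = ("Microcebus_murinus", "Mirza_coquereli")

# (clade, number of loci, explicit locus ids to use first)
_INFORMATIVE_GROUPS = (
    ("lemuriformes", LEMURS, 10, ("Str71B",)),
    ("non_daubentonia", NON_DAUBENTONIA, 6, ()),
    ("lepilemur_cheirogaleidae", LEPILEMUR_CHEIROGALEIDAE, 1, ("MmM97",)),
    ("indriidae_lemuridae", INDRIIDAE_LEMURIDAE, 1, ("LI1",)),
    ("lemuridae", LEMURIDAE, 10, ("Em6",)),
    ("lemur_hapalemur", LEMUR_HAPALEMUR, 6, ()),
    ("lemur_hapalemur_eulemur", LEMUR_HAPALEMUR_EULEMUR, 8, ()),
    ("macaco_fulvus", MACACO_FULVUS, 6, ()),
    ("microcebus_mirza", MICROCEBUS_MIRZA, 19, ("MmA27",)),
    ("indriidae", INDRIIDAE, 6, ("PcC1", "PcC2", "MmA20A", "Str67A")),
)

_AUTAPOMORPHIES = (
    ("Lemur_catta", 3, ()),
    ("Eulemur_macaco", 2, ()),
    ("Microcebus_murinus", 16, ("Str59",)),
    ("Avahi_laniger", 1, ("MmA2c",)),
)

_GROUP_PREFIX = {
    "lemuriformes": "LF", "non_daubentonia": "ND",
    "lepilemur_cheirogaleidae": "LCh", "indriidae_lemuridae": "IL",
    "lemuridae": "LM", "lemur_hapalemur": "LH",
    "lemur_hapalemur_eulemur": "LHE", "macaco_fulvus": "MF",
    "microcebus_mirza": "MM", "indriidae": "IN",
}

LEMUR_CLADES = {name: frozenset(taxa)
                for name, taxa, _, _ in _INFORMATIVE_GROUPS}


def build_lemur_fixture() -> CharacterMatrix:
    """The 24-taxon × 95-locus reference matrix.

    Every locus is absent in both outgroups; 73 columns mark the ten
    text-supported clades and 22 are autapomorphic.  Every column is
    consistent with the reference topology, so each needs exactly one
    Dollo gain and no losses on it.
    """
    panel = TaxonPanel(LEMUR_TAXA, OUTGROUPS)
    pos = {t: i for i, t in enumerate(LEMUR_TAXA)}
    loci: list[Locus] = []
    cols: list[np.ndarray] = []

    def add(lid: str, present, note: str):
        col = np.zeros(len(LEMUR_TAXA), dtype=np.int8)
        for t in present:
            col[pos[t]] = PRESENT
        cols.append(col)
        loci.append(Locus(lid, source="fixture", note=note))

    for name, taxa, count, named in _INFORMATIVE_GROUPS:
        prefix = _GROUP_PREFIX[name]
        ids = list(named) + [f"{prefix}{i:02d}" for i in range(len(named) + 1,
                                                               count + 1)]
        for lid in ids:
            add(lid, taxa, f"shared by {name}")
    for taxon, count, named in _AUTAPOMORPHIES:
        short = "".join(w[0] for w in taxon.split("_")).upper()
        ids = list(named) + [f"{short}sp{i:02d}" for i in range(len(named) + 1,
                                                                count + 1)]
        for lid in ids:
            add(lid, (taxon,), f"specific to {taxon}")
    return CharacterMatrix(panel, loci, np.stack(cols, axis=1))


def lemur_reference_tree() -> RootedTree:
    """Rooted tree displaying exactly the ten text-supported clades (and
    the pendant edges); unsupported regions are polytomies."""
    return tree_from_clades(LEMUR_TAXA, LEMUR_CLADES.values())


# ------------------------------------------------------- genome fixture

@dataclass
class GenomeFixture:
    fasta_path: Path
    out_path: Path
    truth_path: Path
    truth: pd.DataFrame


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching "
    "repeat      position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat    "
    "class/family   begin end (left)  ID\n"
    "\n"
)


def build_genome_fixture(n_contigs: int, contig_len: int, implants,
                         seed: int, out_dir) -> GenomeFixture:
    """Random contigs with implanted repeat elements, plus the matching
    RepeatMasker-style annotation and a truth table.

    ``implants`` is a sequence of ``(family, length, lineage)`` tuples;
    the lineage label records which simulated lineage carries the element
    (the screen should recover exactly the implants whose family and
    length pass its filters).  Placement avoids overlaps, retrying a
    bounded number of times.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = {f"contig_{i+1}": rng.integers(0, 4, contig_len)
               for i in range(n_contigs)}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    rows = []
    for idx, (family, length, lineage) in enumerate(implants, start=1):
        if length >= contig_len:
            raise InputError(f"implant {idx}: length {length} >= contig "
                             f"length {contig_len}")
        placed = False
        for _ in range(200):
            contig = f"contig_{1 + int(rng.integers(n_contigs))}"
            begin = 1 + int(rng.integers(contig_len - length))
            end = begin + length - 1
            if all(end < b or begin > e for b, e in occupied[contig]):
                occupied[contig].append((begin, end))
                placed = True
                break
        if not placed:
            raise InputError(f"implant {idx}: could not place without overlap")
        strand = "+" if rng.random() < 0.5 else "C"
        rows.append(dict(locus_id=f"IMP{idx:03d}", family=family,
                         length=length, lineage=lineage, contig=contig,
                         begin=begin, end=end,
                         strand="-" if strand == "C" else "+",
                         orient=strand))

    truth = pd.DataFrame(rows, columns=["locus_id", "family", "length",
                                        "lineage", "contig", "begin", "end",
                                        "strand", "orient"])

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, arr in contigs.items():
            seq = _BASES[arr].tobytes().decode()
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    out_path = out_dir / "genome.out"
    with open(out_path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(rows, start=1):
            div = 5.0 + (i % 7)
            left = contig_len - r["end"]
            fh.write(f"{1000+i:5d} {div:5.1f}  0.0  0.0  {r['contig']:<10s} "
                     f"{r['begin']:>7d} {r['end']:>7d} ({left}) "
                     f"{r['orient']} {r['family']:<10s} SINE/Alu "
                     f"1 {r['length']} (0) {i}\n")

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return GenomeFixture(fasta_path=fasta_path, out_path=out_path,
                         truth_path=truth_path, truth=truth)


# ---------------------------------------------------- confounder fixture

@dataclass
class ConfounderFixture:
    locus_id: str
    annotations: list
    alignment: dict            # taxon -> amplicon sequence
    groups: tuple              # the two carrier taxon sets


def inject_confounder_fixture(variant: str = "near_parallel",
                              seed: int = 7) -> ConfounderFixture:
    """A two-lineage locus whose carriers harbour elements at nearly the
    same position.

    ``variant="near_parallel"`` (the default) gives elements of different
    subfamilies offset by 4 bp with distinct target-site duplications —
    two independent insertion events that must be recoded into two
    characters.  ``variant="orthologous"`` gives one shared element:
    same subfamily, zero offset, identical TSD.
    """
    if variant not in ("near_parallel", "orthologous"):
        raise InputError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    flank_left = _BASES[rng.integers(0, 4, 120)].tobytes().decode()
    flank_right = _BASES[rng.integers(0, 4, 120)].tobytes().decode()
    elem_a = _BASES[rng.integers(0, 4, 300)].tobytes().decode()
    cheiro = "Cheirogaleus_medius"
    indri = "Propithecus_coquereli"
    if variant == "orthologous":
        ann = [
            InsertionAnnotation(cheiro, "AluL1", insertion_point=120,
                                tsd="AATTCCGGAATT"),
            InsertionAnnotation(indri, "AluL1", insertion_point=120,
                                tsd="AATTCCGGAATT"),
        ]
        aln = {
            cheiro: flank_left + elem_a + flank_right,
            indri: flank_left + elem_a + flank_right,
        }
    else:
        elem_b = _BASES[rng.integers(0, 4, 310)].tobytes().decode()
        ann = [
            InsertionAnnotation(cheiro, "AluL1", insertion_point=120,
                                tsd="AATTCCGGAATT"),
            InsertionAnnotation(indri, "AluL4", insertion_point=124,
                                tsd="GGCCTTAAGGCC"),
        ]
        aln = {
            cheiro: flank_left + elem_a + flank_right,
            indri: flank_left[:124] + elem_b + flank_left[124:] + flank_right,
        }
    return ConfounderFixture(
        locus_id="MmA20", annotations=ann, alignment=aln,
        groups=(frozenset(CHEIROGALEIDAE), frozenset(INDRIIDAE)))
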