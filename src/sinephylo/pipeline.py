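"""End-to-end orchestration: matrix in, annotated tree + reports out.

``run_phylogeny`` chains matrix loading, Dollo tree search, bootstrap,
branch support with significance, and ensemble indices into one
reproducible run; ``run_screen`` chains RepeatMasker parsing and the
candidate filters.  Outputs are plain text (newick, TSV) and contain no
timestamps, so identical configs produce byte-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .dollo import ensemble_indices, reconstruct, synapomorphy_counts, tree_length
from .errors import ConfigurationError
from .matrix import CharacterMatrix, classify_characters, read_matrix_csv, read_nexus
from .search import SearchConfig, bootstrap, search_mp_tree, strict_consensus
from .support import annotate_tree, branch_support_counts
from .screen import filter_candidates, parse_repeatmasker_out

__all__ = ["RunConfig", "ReportBundle", "run_phylogeny", "ScreenConfig",
           "run_screen"]


@dataclass
class RunConfig:
    matrix_path: str
    out_dir: str
    outgroups: tuple = ()
    seed: int = 1
    bootstrap_reps: int = 1000
    alpha1: float = 0.05          # one star
    alpha2: float = 0.01          # two stars
    rearrangement: str = "nni"
    collapse_unsupported: bool = True
    log_level: str = "info"

    def __post_init__(self):
        if not 0 < self.alpha2 < self.alpha1 < 1:
            raise ConfigurationError(
                f"need 0 < alpha2 < alpha1 < 1, got {self.alpha2}, {self.alpha1}")
        if self.bootstrap_reps < 0:
            raise ConfigurationError("bootstrap_reps must be >= 0")


@dataclass
class ReportBundle:
    tree_path: Path
    consensus_path: Path
    support_path: Path
    summary_path: Path
    bootstrap_path: Path
    log_path: Path
    matrix: CharacterMatrix
    tree: object
    supports: list
    indices: object


def run_phylogeny(config: RunConfig) -> ReportBundle:
    """Full presence/absence phylogeny run; deterministic given the seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"sinephylo {__version__}", f"seed: {config.seed}",
                      f"matrix: {config.matrix_path}"]

    path = str(config.matrix_path)
    if path.endswith((".nex", ".nexus")):
        matrix = read_nexus(path)
        if config.outgroups:
            from .matrix import TaxonPanel
            matrix = CharacterMatrix(
                TaxonPanel(matrix.panel.taxa, tuple(config.outgroups)),
                matrix.loci, matrix.states)
    else:
        matrix = read_matrix_csv(path, outgroups=config.outgroups)
    cls = classify_characters(matrix)
    log.append(f"loci: {matrix.n_loci} (informative {cls.n_informative}, "
               f"autapomorphic {cls.n_autapomorphic}, constant {cls.n_constant})")
    for w in cls.warnings:
        log.append(f"warning: {w}")

    scfg = SearchConfig(seed=config.seed, rearrangement=config.rearrangement,
                        collapse_unsupported=config.collapse_unsupported)
    trees, score = search_mp_tree(matrix, scfg)
    best = trees[0]
    log.append(f"best Dollo length: {score.total_length} "
               f"({len(trees)} equally parsimonious tree(s) retained)")

    boot = None
    if config.bootstrap_reps > 0:
        boot = bootstrap(matrix, config.bootstrap_reps, scfg)
        log.append(f"bootstrap: {boot.replicates} replicates, "
                   f"{boot.failed_replicates} failed")

    rec = reconstruct(best, matrix)
    counts, ambiguous = synapomorphy_counts(rec, best)
    supports = branch_support_counts(matrix, best, rec=rec)
    indices = ensemble_indices(matrix, best)
    annotated = annotate_tree(best, supports, boot=boot, matrix=matrix)

    tree_path = out / "tree_annotated.nwk"
    annotated.write(tree_path, annotations=True)
    consensus_path = out / "strict_consensus.nwk"
    strict_consensus(trees).write(consensus_path)

    support_path = out / "support.tsv"
    rows = []
    for s in sorted(supports, key=lambda s: (-len(s.clade), sorted(s.clade))):
        freq = boot.clade_freq.get(s.clade) if boot else None
        rows.append(dict(
            clade=";".join(sorted(s.clade)),
            n_taxa=len(s.clade),
            bootstrap_pct=(round(100 * freq, 1) if freq is not None else ""),
            k_support=s.k_support, m_conflict=s.k_conflict_a,
            n_conflict=s.k_conflict_b, p_value=f"{s.p_value:.4g}",
            stars={"none": "", "one": "*", "two": "**"}[s.stars]))
    pd.DataFrame(rows).to_csv(support_path, sep="\t", index=False)

    bootstrap_path = out / "bootstrap.tsv"
    if boot is not None:
        brows = [dict(clade=";".join(sorted(c)), frequency_pct=round(100 * f, 2))
                 for c, f in sorted(boot.clade_freq.items(),
                                    key=lambda kv: (-kv[1], sorted(kv[0])))]
        pd.DataFrame(brows).to_csv(bootstrap_path, sep="\t", index=False)
    else:
        bootstrap_path.write_text("clade\tfrequency_pct\n")

    summary_path = out / "summary.tsv"
    ri = f"{indices.ri:.3f}" if indices.ri is not None else "undefined"
    summary = [
        ("n_taxa", matrix.n_taxa), ("n_loci", matrix.n_loci),
        ("informative", cls.n_informative),
        ("autapomorphic", cls.n_autapomorphic),
        ("constant", cls.n_constant),
        ("tree_length", score.total_length),
        ("CI", f"{indices.ci:.3f}"), ("HI", f"{indices.hi:.3f}"),
        ("RI", ri),
        ("ambiguous_loci", len(ambiguous)),
    ]
    with open(summary_path, "w") as fh:
        fh.write("quantity\tvalue\n")
        for k, v in summary:
            fh.write(f"{k}\t{v}\n")

    log.append(f"defaults in effect: alpha1={config.alpha1} "
               f"alpha2={config.alpha2} rearrangement={config.rearrangement} "
               f"collapse_unsupported={config.collapse_unsupported}")
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")

    return ReportBundle(tree_path=tree_path, consensus_path=consensus_path,
                        support_path=support_path, summary_path=summary_path,
                        bootstrap_path=bootstrap_path, log_path=log_path,
                        matrix=matrix, tree=annotated, supports=supports,
                        indices=indices)


@dataclass
class ScreenConfig:
    rm_path: str
    out_dir: str
    fasta_path: Optional[str] = None
    families: Optional[tuple] = None       # None = any AluL* subfamily
    min_len: int = 280
    flank: int = 500


def run_screen(config: ScreenConfig) -> Path:
    """Screen RepeatMasker annotations; writes a candidate table with the
    filter verdict for every hit and returns its path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits = parse_repeatmasker_out(config.rm_path)
    kept = set(id(h) for h in filter_candidates(
        hits, families=config.families, min_len=config.min_len))
    rows = []
    for h in hits:
        if id(h) in kept:
            verdict, rule = "kept", ""
        elif config.families is not None and h.family not in config.families:
            verdict, rule = "rejected", "family_not_in_target_set"
        elif config.families is None and not h.family.startswith("AluL"):
            verdict, rule = "rejected", "family_not_AluL"
        else:
            verdict, rule = "rejected", f"length_le_{config.min_len}"
        rows.append(dict(contig=h.contig, begin=h.begin, end=h.end,
                         strand=h.strand, family=h.family, length=h.length,
                         divergence=h.divergence, verdict=verdict, rule=rule))
    table = out / "candidates.tsv"
    pd.DataFrame(rows, columns=["contig", "begin", "end", "strand", "family",
                                "length", "divergence", "verdict",
                                "rule"]).to_csv(table, sep="\t", index=False)

    if config.fasta_path:
        # flank FASTA for the surviving candidates, ready for primer design
        from Bio import SeqIO

        from .screen import extract_flanks

        contigs = {rec.id: str(rec.seq)
                   for rec in SeqIO.parse(str(config.fasta_path), "fasta")}
        with open(out / "flanks.fa", "w") as fh:
            for h in hits:
                if id(h) not in kept or h.contig not in contigs:
                    continue
                fl = extract_flanks(contigs[h.contig], h, config.flank)
                stem = f"{h.contig}_{h.begin}_{h.end}"
                fh.write(f">{stem}_up\n{fl.upstream}\n"
                         f">{stem}_down\n{fl.downstream}\n")
    return table
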