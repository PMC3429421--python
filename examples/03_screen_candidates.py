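"""Screen a synthetic genome's repeat annotations for marker candidates.

Implants a mixture of elements into random contigs, parses the
RepeatMasker-style annotation, and applies the subfamily + strict length
filter; survivors are exactly the implanted AluL elements > 280 bp.
"""

import tempfile

from sinephylo import filter_candidates, parse_repeatmasker_out
from sinephylo.fixtures import build_genome_fixture

implants = ([("AluL1", 300, "microcebus")] * 4
            + [("AluL4", 295, "microcebus")] * 2
            + [("AluL1", 280, "microcebus")]       # exactly 280 bp: rejected
            + [("AluJb", 310, "ancestral")] * 3)   # wrong subfamily
with tempfile.TemporaryDirectory() as d:
    fx = build_genome_fixture(n_contigs=5, contig_len=3000,
                              implants=implants, seed=1, out_dir=d)
    hits = parse_repeatmasker_out(fx.out_path)
    kept = filter_candidates(hits, min_len=280)

print(f"annotation records: {len(hits)}")
print(f"candidates surviving AluL + >280 bp filter: {len(kept)}")
for h in kept:
    print(f"  {h.contig}:{h.begin}-{h.end} {h.family} ({h.length} bp)")
print("the 280 bp element and the AluJb elements were rejected, "
      "matching the implant truth table")
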