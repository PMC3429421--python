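"""Classify a near-parallel independent insertion and recode the matrix.

Two lineages can carry different elements at almost the same genomic
position; by PCR product size alone they look like one shared insertion,
wrongly uniting the two lineages.  Sequence evidence (subfamily,
insertion point offset, target-site duplications) separates the cases,
and a near-parallel verdict splits the locus into two characters.
"""

from sinephylo import classify_confounding, recode_near_parallel
from sinephylo.fixtures import inject_confounder_fixture

fx = inject_confounder_fixture()                  # different subfamilies, 4 bp apart
call = classify_confounding(fx.locus_id, fx.annotations)
print(f"locus {call.locus_id}: subfamily_match={call.subfamily_match} "
      f"offset={call.offset_bp} bp tsd_match={call.tsd_match}")
print("verdict:", call.verdict)

ortho = inject_confounder_fixture(variant="orthologous")
print("orthologous control verdict:",
      classify_confounding(ortho.locus_id, ortho.annotations).verdict)

# recoding: one confounded column becomes two lineage-specific ones
from sinephylo.matrix import CharacterMatrix, Locus, TaxonPanel
import numpy as np

taxa = ("Cheirogaleus_medius", "Propithecus_coquereli", "Homo_sapiens")
m = CharacterMatrix(TaxonPanel(taxa), [Locus("MmA20")],
                    np.array([[1], [1], [0]], dtype=np.int8))
rec = recode_near_parallel(m, "MmA20",
                           ({"Cheirogaleus_medius"}, {"Propithecus_coquereli"}))
print("\nbefore:", m.locus_ids, "after:", rec.locus_ids)
print("Cheirogaleus:", [rec.state("Cheirogaleus_medius", l) for l in rec.locus_ids])
print("Propithecus: ", [rec.state("Propithecus_coquereli", l) for l in rec.locus_ids])
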