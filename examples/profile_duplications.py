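"""Profile gene duplications: paralog families, median Ks, duplicate types.

Generates a miniature genome with planted tandem/proximal/dispersed pairs
and two collinear (segmental) blocks, then reconstructs families, the
median-Ks distribution and the duplicate-type breakdown.
"""

import itertools
from collections import Counter

from yewmine import synthetic_data as sd
from yewmine.dup_profile import (classify_duplicates,
                                 cluster_paralog_families,
                                 find_syntenic_blocks, ks_distribution)

spec = sd.SyntheticGenomeSpec(
    seed=4, n_chromosomes=2, genes_per_chromosome=150,
    ltr_cohorts=(), cluster=None,
    duplications=sd.DuplicationPlan(tandem=6, proximal=4, dispersed=4,
                                    segmental_blocks=1))
genome = sd.generate(spec)

families = cluster_paralog_families(genome.proteins, cds=genome.cds)
pairs = [(f.members[i], f.members[j]) for f in families
         for i, j in itertools.combinations(range(len(f.members)), 2)]
blocks = find_syntenic_blocks(genome.annotation, pairs)
classes = classify_duplicates(genome.annotation, families, blocks)

print(f"{len(families)} paralog families from "
      f"{len(genome.annotation)} genes; "
      f"{len(blocks)} syntenic block(s) of sizes "
      f"{[b.anchor_count for b in blocks]}")
hist, undefined = ks_distribution(families, bin_width=0.05)
print("median-Ks histogram (bin -> families):")
for b, n in hist.items():
    print(f"  [{b * 0.05:.2f}, {(b + 1) * 0.05:.2f}): {n}")
print("duplicate classes:", dict(Counter(classes.values())))
agree = sum(classes[g] == c
            for g, c in genome.truth.duplicate_classes.items())
print(f"agreement with planted truth: {agree}/{len(classes)}")
print("Tandem pairs sit at adjacent gene ranks, proximal within a 10-gene")
print("window, segmental anchors inside collinear blocks of >= 5 paralogs;")
print("a Ks peak plus widespread blocks would signal a WGD.")
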