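"""Show the off-target screen rejecting a primer with planted near-copies.

Plants four 85%-identity copies of a gene's top-ranked left primer into
the genome; the screen then counts 5 loci (self + 4 copies) for that
primer, rejects the pair, and the designer iterates to an alternative.
"""

import numpy as np

from promoterforge import primers, specificity, templates
from promoterforge.synth import design_batch_spec, generate_genome, plant_offtarget_copies

build = generate_genome(design_batch_spec(seed=11, n_genes=1))
model = build.gene_models[0]
tpl = templates.build_template(build.sequences, model)
params = primers.DesignParams()

rank1 = primers.enumerate_pairs(tpl, params).pairs[0]
print(f"rank-1 left primer: {rank1.left.sequence}")

ts = model.translation_start
genome, placements = plant_offtarget_copies(
    build.sequences, rank1.left.sequence, 4, identity=0.85,
    rng=np.random.default_rng(11), avoid={model.contig_id: [(ts - 3100, ts + 400)]},
)
print(f"planted 4 copies at 85% identity: {placements}")

outcome = primers.design_for_gene(
    tpl, params, lambda pair: specificity.evaluate_pair(pair, genome)
)
pair = outcome.pair
print(f"\npairs rejected before acceptance: {len(outcome.rejections)}")
print(f"accepted left primer: {pair.left.sequence}")
print(f"left loci={len(pair.specificity.left_hits)}, right loci={len(pair.specificity.right_hits)}")
# each primer of the accepted pair hits at most 3 genomic loci at >=80%
# identity (one of which is always its own template locus).
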