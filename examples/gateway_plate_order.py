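"""Append attB tails, inspect the two-stage PCR programs and write a
96-well plate order file for a designed batch."""

import tempfile

from promoterforge import gateway, primers, specificity, templates
from promoterforge.synth import design_batch_spec, generate_genome

build = generate_genome(design_batch_spec(seed=11, n_genes=3))
genome = build.sequences
params = primers.DesignParams()

tailed = []
for model in build.gene_models:
    tpl = templates.build_template(genome, model)
    outcome = primers.design_for_gene(
        tpl, params, lambda pair: specificity.evaluate_pair(pair, genome)
    )
    if outcome.accepted:
        tailed.append(gateway.add_tails(outcome.pair, gene_id=model.gene_id))

for tp in tailed:
    print(f"{tp.gene_id}: left {len(tp.left_oligo)} nt  {tp.left_oligo}")
    print(f"{' ' * len(tp.gene_id)}  right {len(tp.right_oligo)} nt  {tp.right_oligo}")
    print(f"{' ' * len(tp.gene_id)}  stage-1 product {tp.expected_stage1_product} bp, "
          f"stage-2 {tp.expected_stage2_product} bp")

stage1 = gateway.emit_pcr_protocol(1)
anneal = [s[0] for b in stage1 for s in b.steps if 50 <= s[0] <= 65]
print(f"\nstage-1 touchdown annealing temperatures: {anneal} C")
print(f"stage-2: {gateway.emit_pcr_protocol(2)[1].repeats} cycles at 56 C")

plates = gateway.layout_plates(tailed)
with tempfile.NamedTemporaryFile("r", suffix=".tsv", delete=False) as fh:
    gateway.write_order_file(plates, fh.name)
    print(f"\norder file ({fh.name}):")
    print(open(fh.name).read().rstrip())
# every left oligo starts with the attB1 partial tail AAAAAGCAGGCT and
# every right oligo with AGAAAGCTGGT; stage 2 extends both to 29 nt
# adapters completing the recombination sites.
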