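import pytest

from promoterforge import primers, specificity, templates
from promoterforge.synth import design_batch_spec, generate_genome


@pytest.fixture(scope="session")
def batch_build():
    """Seeded 20-gene batch on 20 kb contigs, full 3150 bp templates."""
    return generate_genome(design_batch_spec(seed=1, n_genes=20))


@pytest.fixture(scope="session")
def batch_designs(batch_build):
    """Accepted designs for the whole batch, screened against the genome."""
    genome = batch_build.sequences
    params = primers.DesignParams()
    outcomes = []
    for model in batch_build.gene_models:
        tpl = templates.build_template(genome, model)
        outcome = primers.design_for_gene(
            tpl, params, lambda pair: specificity.evaluate_pair(pair, genome)
        )
        outcomes.append((tpl, outcome))
    return outcomes
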