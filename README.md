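# promoterforge

Batch design of Gateway-compatible promoter-cloning primers for
promoter-reporter (GFP) studies, with genome-wide off-target screening and
analytics for the resulting construct pipeline.

## The problem

Many plant genes — in *Arabidopsis*, thousands — show no detectable
expression on microarrays, so their function cannot be inferred from
expression profiling. A classical alternative is to fuse each gene's
upstream regulatory region to a fluorescent reporter, transform the
construct into plants, and read expression patterns directly from
reporter fluorescence. Doing this for hundreds of genes requires
automating the front end: picking candidate genes, designing cloning
primers that amplify each promoter exactly once from genomic DNA, and
tracking every construct through cloning, transformation and screening.

`promoterforge` implements that front end as a Python library:

- **Candidate selection** — classify genes from a genes × arrays grid of
  present/marginal/absent (P/M/A) detection calls. A gene is a candidate
  when its present fraction `p = #P / #arrays` satisfies `p = 0`
  (no expression) or `0 < p < 0.05` (low expression; strict inequality),
  and it is not independently seen expressed by MPSS sequencing.
- **Template extraction** — for each candidate, the design template is
  the window from 3000 bp upstream to 150 bp downstream of the
  translation start (the A of ATG), read in promoter orientation on
  either strand; unannotated genes are anchored by exact matching of the
  CDS 5′ prefix.
- **Primer pair design** — enumerate and rank primer pairs subject to
  product size 2150–2650 bp, product containing the 50 bp target window
  starting at the ATG, left primer ≥ 2000 bp upstream, right primer
  50–150 bp downstream (hence ≥ ⌊50/3⌋ = 16 native codons in the
  reporter fusion). Candidates are filtered by length (18–27 nt), GC
  (0.20–0.80), melting temperature (57–63 °C, SantaLucia 1998
  nearest-neighbor model with Owczarzy 2004 salt correction) and
  self-complementarity, then ranked by
  `|Tm−60| + |len−20|` per primer plus the mate Tm difference.
- **Specificity screen** — each primer is matched ungapped against both
  strands of the whole genome; windows with identity ≥ 0.80 are
  off-target loci (overlapping windows merged). A pair is accepted iff
  each primer has ≤ 3 loci — one of which is always its own template
  site. The designer walks the ranked pair list until a pair passes.
- **Gateway output** — accepted primers get partial attB tails
  (`aaaaagcaggct` / `agaaagctggt`) for two-stage PCR with universal 29 nt
  attB1/attB2 adapters, and are written as 96-well plate order files;
  the two thermal programs (touchdown 63→58 °C, then 19 × 56 °C) are
  emitted as structured metadata.
- **Tracking & PO analytics** — constructs move through a monotone
  funnel (designed → entry clone → … → GFP-positive); stage success
  rates, per-gene expression-consistency categories, and
  promoters-per-Plant-Ontology-code summaries are computed from line
  tables, with an embedded SQLite store for queries by PO code, gene id
  or tissue name.
- **Synthetic data** — seeded generators plant genes, off-target primer
  copies with exact substitution counts, call matrices with exact P
  counts, and construct funnels, so every stage is testable against
  known ground truth.

## Worked example

```bash
python examples/design_primers.py
```

```
gene       strand  product  upstream  downstream  codons  Tm(L/R)
synth_001       +     2582      2489          93      31  59.5/59.5
synth_002       -     2593      2461         132      44  59.9/59.8
synth_003       +     2637      2554          83      27  60.0/59.9
```

Each row is one accepted, genome-screened pair: the amplicon length in
bp, the left primer's distance upstream of the ATG (≥ 2000), the right
primer's offset downstream of it (50–150, here giving 31/44/27 native
codons in the fusion), and both melting temperatures inside the 57–63 °C
window. `examples/` contains similar short scripts for candidate
selection, the off-target screen, plate-order output, and the funnel/PO
analytics (which print the study funnel's 74.8 % entry-cloning and
75.4 % transformation success rates and the 81-region PO summary from
the packaged fixtures).

A thin CLI wraps the same calls: `promoterforge prepare` (templates from
FASTA + GFF3), `promoterforge design` (screened, tailed primers and an
order file) and `promoterforge funnel-report`.

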