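"""Promoter design templates: 3000 bp upstream + 150 bp downstream of ATG.

The design template for a gene is the genomic window spanning 3000 bp
upstream of the translation start through 150 bp downstream of it, read
in promoter orientation (promoter -> ATG -> coding) regardless of the
gene's genomic strand. When a gene model is available its annotated
translation start is used; unannotated candidates are anchored by exact
matching of the CDS 5' prefix against both strands of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .genome import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    as_contig_dict,
    extract_region,
    reverse_complement,
)

DEFAULT_UPSTREAM = 3000
DEFAULT_DOWNSTREAM = 150
#: minimum upstream span for which any product in the default 2150-2650 bp
#: range can be placed (product floor minus the downstream allowance)
MIN_DESIGNABLE_UPSTREAM = 2150


class AnchorNotFoundError(LookupError):
    """CDS prefix has no exact occurrence in the genome."""


class AmbiguousAnchorError(LookupError):
    """CDS prefix occurs at two or more genomic loci."""


class TranslationStart(NamedTuple):
    contig_id: str
    position: int  # + strand axis offset of the A of ATG
    strand: str


@dataclass
class PromoterTemplate:
    """A promoter design template in 5'->3' promoter orientation.

    ``atg_offset`` is the offset of the A of ATG within ``sequence``
    (3000 whenever the full upstream span exists); ``upstream_achieved`` /
    ``downstream_achieved`` record boundary clipping.
    """

    gene_id: str
    sequence: str
    atg_offset: int
    source_interval: GenomicInterval
    upstream_achieved: int
    downstream_achieved: int
    flags: list[str] = field(default_factory=list)

    @property
    def designable(self) -> bool:
        return self.upstream_achieved >= MIN_DESIGNABLE_UPSTREAM

    def __len__(self) -> int:
        return len(self.sequence)


def locate_translation_start(
    cds_sequence: str,
    genome: list[GenomeSequence] | dict[str, GenomeSequence],
    min_anchor: int = 30,
    retry_doubling: bool = True,
) -> TranslationStart:
    """Anchor a CDS to the genome by exact match of its 5' prefix.

    Searches the first ``min_anchor`` bases of the CDS (which must begin
    with ATG) on both strands of every contig. A unique hit yields the
    genomic position of the A of the ATG and the strand. With
    ``retry_doubling`` (default), an ambiguous anchor is retried with a
    doubled prefix length until unique or the CDS is exhausted.
    """
    cds = cds_sequence.upper()
    if len(cds) < min_anchor:
        raise ValueError(f"CDS length {len(cds)} < min_anchor {min_anchor}")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not begin with ATG")
    contigs = as_contig_dict(genome)

    anchor_len = min_anchor
    while True:
        anchor = cds[:anchor_len]
        rc_anchor = reverse_complement(anchor)
        hits: list[TranslationStart] = []
        for contig in contigs.values():
            pos = contig.residues.find(anchor)
            while pos != -1:
                hits.append(TranslationStart(contig.contig_id, pos, "+"))
                pos = contig.residues.find(anchor, pos + 1)
            pos = contig.residues.find(rc_anchor)
            while pos != -1:
                # ATG 'A' sits at the 3'-most base of the match on the + axis
                hits.append(TranslationStart(contig.contig_id, pos + anchor_len - 1, "-"))
                pos = contig.residues.find(rc_anchor, pos + 1)
        if len(hits) == 1:
            return hits[0]
        if len(hits) == 0:
            raise AnchorNotFoundError(
                f"no exact genomic occurrence of the {anchor_len} nt CDS prefix"
            )
        if retry_doubling and anchor_len < len(cds):
            anchor_len = min(2 * anchor_len, len(cds))
            continue
        raise AmbiguousAnchorError(
            f"{len(hits)} genomic occurrences of the {anchor_len} nt CDS prefix"
        )


def build_template(
    genome: list[GenomeSequence] | dict[str, GenomeSequence],
    gene: GeneModel | TranslationStart,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterTemplate:
    """Extract the promoter design template around a translation start.

    For a + strand gene the + axis interval ``[start-upstream,
    start+downstream)`` is taken; for a - strand gene the mirror interval
    is extracted and reverse complemented so the template always reads
    promoter -> ATG -> coding. Clipping at contig boundaries is recorded
    (a short upstream span flags the template; a translation start within
    3 bp of the contig end, where not even ATG fits, is an error).
    """
    contigs = as_contig_dict(genome)
    if isinstance(gene, GeneModel):
        gene_id, contig_id = gene.gene_id, gene.contig_id
        strand, start = gene.strand, gene.translation_start
    else:
        gene_id, contig_id = "anchored", gene.contig_id
        strand, start = gene.strand, gene.position
    if contig_id not in contigs:
        raise KeyError(f"unknown contig {contig_id!r}")
    contig = contigs[contig_id]
    if strand == "+":
        if start + 3 > contig.length:
            raise ValueError("translation start within 3 bp of contig end")
        want = GenomicInterval(contig_id, start - upstream, start + downstream, "+")
    else:
        if start - 2 < 0:
            raise ValueError("translation start within 3 bp of contig end")
        want = GenomicInterval(contig_id, start - downstream + 1, start + upstream + 1, "-")
    seq, achieved = extract_region(contigs, want)
    if strand == "+":
        upstream_achieved = start - achieved.start
        downstream_achieved = achieved.end - start
    else:
        upstream_achieved = achieved.end - start - 1
        downstream_achieved = start - achieved.start + 1
    flags: list[str] = []
    if upstream_achieved < upstream:
        flags.append("short_upstream")
    if downstream_achieved < downstream:
        flags.append("short_downstream")
    if upstream_achieved < MIN_DESIGNABLE_UPSTREAM:
        flags.append("undesignable")
    return PromoterTemplate(
        gene_id=gene_id,
        sequence=seq,
        atg_offset=upstream_achieved,
        source_interval=achieved,
        upstream_achieved=upstream_achieved,
        downstream_achieved=downstream_achieved,
        flags=flags,
    )
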