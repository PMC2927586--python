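"""Genome sequences, gene models and strand-aware coordinate arithmetic.

All internal coordinates are 0-based half-open on the + strand axis;
GFF3 (1-based inclusive) is converted at the parsing boundary. Intervals
that run past a contig end are clipped, not rejected, and the achieved
bounds are reported alongside the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Malformed FASTA/GFF3 input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A reference contig with normalized residues (uppercase, U mapped to T)."""

    contig_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig; strand is '+' or '-'."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments and the translation start.

    ``translation_start`` is the + strand axis offset of the A of the ATG
    codon (for - strand genes this is the highest genomic coordinate of the
    first CDS segment in transcript orientation). ``atg_ok`` records whether
    the annotated start actually reads ATG on the coding strand; models that
    fail the check are flagged, never silently dropped.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_segments: list[GenomicInterval] = field(default_factory=list)
    translation_start: int = 0
    atg_ok: bool = True

    @property
    def cds_length(self) -> int:
        return sum(seg.width for seg in self.cds_segments)


def normalize_residues(raw: str) -> str:
    """Uppercase, map U->T; raise on residues outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise GenomeFormatError(f"disallowed residues after normalization: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq.upper()) - VALID_RESIDUES
    if bad:
        raise ValueError(f"cannot complement residues: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _bad_residue_line(path: str, contig_id: str) -> int | None:
    """Locate the first offending line of a contig for error reporting."""
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                current = line[1:].split()[0] if len(line) > 1 else ""
                continue
            if current == contig_id:
                try:
                    normalize_residues(line.strip())
                except GenomeFormatError:
                    return lineno
    return None


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized :class:`GenomeSequence` records.

    Duplicate contig ids and residues outside {A,C,G,T,N,U} (after case
    folding) are format errors; the error message names the offending line
    where it can be located.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise GenomeFormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise GenomeFormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        try:
            residues = normalize_residues(str(rec.seq))
        except GenomeFormatError as err:
            lineno = _bad_residue_line(path, rec.id)
            where = f"line {lineno}" if lineno else f"record {rec.id!r}"
            raise GenomeFormatError(f"{path}: {where}: {err}") from err
        records.append(GenomeSequence(contig_id=rec.id, residues=residues))
    return records


def write_fasta(records: list[GenomeSequence], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


def as_contig_dict(genome: list[GenomeSequence] | dict[str, GenomeSequence]) -> dict[str, GenomeSequence]:
    if isinstance(genome, dict):
        return genome
    return {g.contig_id: g for g in genome}


def extract_region(
    genome: list[GenomeSequence] | dict[str, GenomeSequence],
    interval: GenomicInterval,
) -> tuple[str, GenomicInterval]:
    """Extract a strand-aware subsequence, clipping at contig boundaries.

    Returns ``(sequence, achieved)`` where ``achieved`` is the interval that
    was actually extracted after clipping. For strand '-', the returned
    sequence is the reverse complement of the + strand substring.
    """
    contigs = as_contig_dict(genome)
    if interval.contig_id not in contigs:
        raise KeyError(f"unknown contig {interval.contig_id!r}")
    contig = contigs[interval.contig_id]
    start = max(0, interval.start)
    end = min(contig.length, interval.end)
    if start > end:
        start = end = min(max(interval.start, 0), contig.length)
    achieved = GenomicInterval(interval.contig_id, start, end, interval.strand)
    seq = contig.residues[start:end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq, achieved


def _codon_at_start(contig: GenomeSequence, pos: int, strand: str) -> str | None:
    if strand == "+":
        if pos + 3 > contig.length:
            return None
        return contig.residues[pos : pos + 3]
    if pos - 2 < 0:
        return None
    return reverse_complement(contig.residues[pos - 2 : pos + 1])


def read_gff3(
    path: str,
    genome: list[GenomeSequence] | dict[str, GenomeSequence],
) -> list[GeneModel]:
    """Read CDS features from a GFF3 file into gene models.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``gene`` then ``ID``). GFF3 1-based inclusive coordinates are converted
    to the internal 0-based half-open convention; the translation start is
    the first CDS base in transcript orientation (the highest coordinate for
    - strand genes). Models whose start codon does not read ATG on the
    coding strand are returned with ``atg_ok=False``.
    """
    contigs = as_contig_dict(genome)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    groups: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        key = None
        for attr in ("Parent", "gene", "ID"):
            if attr in feat.attributes:
                key = feat.attributes[attr][0]
                break
        if key is None:
            raise GenomeFormatError(f"{path}: CDS feature without Parent/gene/ID attribute")
        if feat.seqid not in contigs:
            raise GenomeFormatError(f"{path}: CDS references unknown contig {feat.seqid!r}")
        contig = contigs[feat.seqid]
        start0, end0 = feat.start - 1, feat.end  # GFF3 1-based inclusive -> 0-based half-open
        if start0 < 0 or end0 > contig.length:
            raise GenomeFormatError(
                f"{path}: CDS {feat.start}-{feat.end} out of bounds on contig "
                f"{feat.seqid!r} (length {contig.length})"
            )
        if feat.strand not in ("+", "-"):
            raise GenomeFormatError(f"{path}: CDS of {key!r} lacks a strand")
        groups.setdefault(key, []).append((feat.seqid, start0, end0, feat.strand))

    models: list[GeneModel] = []
    for gene_id, feats in groups.items():
        contig_ids = {f[0] for f in feats}
        strands = {f[3] for f in feats}
        if len(contig_ids) > 1 or len(strands) > 1:
            raise GenomeFormatError(f"{path}: CDS of {gene_id!r} spans contigs/strands")
        contig_id, strand = feats[0][0], feats[0][3]
        ascending = sorted(feats, key=lambda f: f[1])
        for (_, _, e1, _), (_, s2, _, _) in zip(ascending, ascending[1:]):
            if s2 < e1:
                raise GenomeFormatError(f"{path}: overlapping CDS segments in {gene_id!r}")
        ordered = ascending if strand == "+" else ascending[::-1]
        segments = [GenomicInterval(contig_id, s, e, strand) for _, s, e, _ in ordered]
        if strand == "+":
            translation_start = segments[0].start
        else:
            translation_start = segments[0].end - 1
        codon = _codon_at_start(contigs[contig_id], translation_start, strand)
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=contig_id,
                strand=strand,
                cds_segments=segments,
                translation_start=translation_start,
                atg_ok=codon == "ATG",
            )
        )
    return models


def translate_cds(seq: str) -> str:
    """Translate a CDS string (convenience wrapper around Biopython)."""
    return str(Seq(seq).translate())
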