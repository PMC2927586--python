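"""Seeded synthetic data: genomes with planted genes and off-target
primer copies, expression-call matrices with planted labels, and
construct funnels with transgenic lines and PO annotations.

Backgrounds are i.i.d. nucleotides at a specified GC fraction — no
repeat structure beyond what is explicitly planted — so ground truth
(template coordinates, off-target hit counts, expression labels) is
exactly recoverable by construction. All generators are deterministic
for a fixed spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionCallMatrix
from .fixtures import load_funnel_fixture, load_table1_fixture
from .genome import GeneModel, GenomeSequence, GenomicInterval, reverse_complement
from .tracking import (
    FUNNEL_STAGES,
    SCREENING_STAGES,
    PipelineRecord,
    POAnnotation,
    TransgenicLine,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


class PlantedGene(NamedTuple):
    gene_id: str
    contig_id: str
    offset: int  # + axis position of the A of ATG
    strand: str
    cds_length: int


class PlantedOfftarget(NamedTuple):
    sequence: str  # the primer window to copy
    n_copies: int
    identity: float  # per-copy ungapped identity (substitutions only)


@dataclass
class SyntheticGenomeSpec:
    seed: int
    n_contigs: int = 1
    contig_length: int = 20_000
    gc: float = 0.5
    genes: list[PlantedGene] = field(default_factory=list)
    planted_offtargets: list[PlantedOfftarget] = field(default_factory=list)
    #: permit genes without the full 3000 bp upstream / 150 bp downstream room
    allow_truncation: bool = False
    #: never substitute the first/last base of a planted copy, keeping the
    #: copy's terminal seeds intact
    protect_copy_ends: bool = True


@dataclass
class GenomeBuild:
    sequences: list[GenomeSequence]
    gene_models: list[GeneModel]
    truth: pd.DataFrame  # planted feature coordinates


def _gene_footprint(gene: PlantedGene, upstream: int = 3000, downstream: int = 150) -> tuple[int, int]:
    if gene.strand == "+":
        lo = gene.offset - upstream
        hi = max(gene.offset + gene.cds_length, gene.offset + downstream)
    else:
        hi = gene.offset + upstream + 1
        lo = min(gene.offset - gene.cds_length + 1, gene.offset - downstream + 1)
    return lo, hi


def plant_offtarget_copies(
    sequences: list[GenomeSequence],
    window: str,
    n_copies: int,
    identity: float,
    rng: np.random.Generator,
    avoid: Optional[dict[str, list[tuple[int, int]]]] = None,
    protect_ends: bool = True,
) -> tuple[list[GenomeSequence], list[tuple[str, int]]]:
    """Plant degraded copies of a primer window into the genome.

    Each copy carries exactly ``round((1 - identity) * len)`` substitutions
    at distinct positions (excluding the first/last base when
    ``protect_ends``). Placements avoid the given intervals and each
    other. Returns the modified contigs and the copy coordinates.
    """
    window = window.upper()
    k = len(window)
    n_subs = int(round((1.0 - identity) * k))
    avoid = {c: list(v) for c, v in (avoid or {}).items()}
    buffers = {s.contig_id: bytearray(s.residues.encode()) for s in sequences}
    placements: list[tuple[str, int]] = []
    contig_ids = [s.contig_id for s in sequences]
    for _ in range(n_copies):
        for _attempt in range(10_000):
            cid = contig_ids[int(rng.integers(len(contig_ids)))]
            length = len(buffers[cid])
            if length < k:
                continue
            pos = int(rng.integers(0, length - k + 1))
            if any(pos < hi and pos + k > lo for lo, hi in avoid.get(cid, ())):
                continue
            break
        else:
            raise RuntimeError("could not place off-target copy without overlap")
        copy = list(window)
        lo_pos = 1 if protect_ends else 0
        hi_pos = k - 1 if protect_ends else k
        sub_at = rng.choice(np.arange(lo_pos, hi_pos), size=n_subs, replace=False)
        for i in sub_at:
            alternatives = [b for b in "ACGT" if b != copy[i]]
            copy[int(i)] = alternatives[int(rng.integers(3))]
        buffers[cid][pos : pos + k] = "".join(copy).encode()
        avoid.setdefault(cid, []).append((pos, pos + k))
        placements.append((cid, pos))
    out = [GenomeSequence(cid, buffers[cid].decode()) for cid in contig_ids]
    return out, placements


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeBuild:
    """Build a random genome with planted genes and off-target copies.

    Every planted gene begins ATG at its offset (on its strand) and is
    modelled as a single-segment CDS. The truth table records all planted
    coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    buffers: dict[str, bytearray] = {}
    for i in range(spec.n_contigs):
        cid = f"ctg{i + 1}"
        buffers[cid] = bytearray(_random_seq(rng, spec.contig_length, spec.gc).encode())

    footprints: dict[str, list[tuple[int, int]]] = {}
    truth_rows = []
    models: list[GeneModel] = []
    for gene in spec.genes:
        if gene.contig_id not in buffers:
            raise ValueError(f"unknown contig {gene.contig_id!r} for {gene.gene_id}")
        length = len(buffers[gene.contig_id])
        cds = "ATG" + _random_seq(rng, gene.cds_length - 3, spec.gc)
        if gene.strand == "+":
            lo, hi = gene.offset, gene.offset + gene.cds_length
            planted = cds
            seg = GenomicInterval(gene.contig_id, lo, hi, "+")
        else:
            lo, hi = gene.offset - gene.cds_length + 1, gene.offset + 1
            planted = reverse_complement(cds)
            seg = GenomicInterval(gene.contig_id, lo, hi, "-")
        if lo < 0 or hi > length:
            raise ValueError(f"{gene.gene_id}: CDS outside contig bounds")
        if not spec.allow_truncation:
            f_lo, f_hi = _gene_footprint(gene)
            if f_lo < 0 or f_hi > length:
                raise ValueError(
                    f"{gene.gene_id}: less than 3000 bp upstream / 150 bp downstream room "
                    f"(set allow_truncation to plant a clipped case)"
                )
        for o_lo, o_hi in footprints.get(gene.contig_id, ()):
            if lo < o_hi and hi > o_lo:
                raise ValueError(f"{gene.gene_id}: planted features overlap")
        buffers[gene.contig_id][lo:hi] = planted.encode()
        footprints.setdefault(gene.contig_id, []).append(_gene_footprint(gene))
        models.append(
            GeneModel(
                gene_id=gene.gene_id,
                contig_id=gene.contig_id,
                strand=gene.strand,
                cds_segments=[seg],
                translation_start=gene.offset,
            )
        )
        truth_rows.append(
            {
                "kind": "gene",
                "feature_id": gene.gene_id,
                "contig_id": gene.contig_id,
                "position": gene.offset,
                "strand": gene.strand,
                "length": gene.cds_length,
                "identity": 1.0,
            }
        )

    sequences = [GenomeSequence(cid, buf.decode()) for cid, buf in buffers.items()]
    for ot in spec.planted_offtargets:
        sequences, placements = plant_offtarget_copies(
            sequences,
            ot.sequence,
            ot.n_copies,
            ot.identity,
            rng,
            avoid=footprints,
            protect_ends=spec.protect_copy_ends,
        )
        for cid, pos in placements:
            footprints.setdefault(cid, []).append((pos, pos + len(ot.sequence)))
            truth_rows.append(
                {
                    "kind": "offtarget",
                    "feature_id": ot.sequence,
                    "contig_id": cid,
                    "position": pos,
                    "strand": "+",
                    "length": len(ot.sequence),
                    "identity": ot.identity,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "feature_id", "contig_id", "position", "strand", "length", "identity"],
    )
    return GenomeBuild(sequences=sequences, gene_models=models, truth=truth)


def design_batch_spec(
    seed: int,
    n_genes: int = 20,
    contig_length: int = 20_000,
    cds_length: int = 300,
    gc: float = 0.5,
) -> SyntheticGenomeSpec:
    """A batch of genes on separate contigs, each with the full 3000 bp
    upstream and 150 bp downstream room (alternating strands)."""
    genes = []
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        offset = 5000 if strand == "+" else contig_length - 5001
        genes.append(PlantedGene(f"synth_{i + 1:03d}", f"ctg{i + 1}", offset, strand, cds_length))
    return SyntheticGenomeSpec(
        seed=seed, n_contigs=n_genes, contig_length=contig_length, gc=gc, genes=genes
    )


def generate_call_matrix(
    n_genes: int,
    n_arrays: int = 1381,
    seed: int = 0,
    present_counts: Optional[Sequence[int]] = None,
    label_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    threshold: float = 0.05,
    marginal_rate: float = 0.1,
) -> tuple[ExpressionCallMatrix, pd.DataFrame]:
    """Generate a P/M/A call matrix with exactly planted present counts.

    When ``present_counts`` is omitted, per-gene counts are drawn so that
    ``label_fractions`` of genes fall in the no / low / expressed classes
    (low means 1 <= count < threshold * n_arrays). M calls are sprinkled
    among the non-present cells. Truth labels are derived from the exact
    planted counts, so classification recovers them exactly.
    """
    rng = np.random.default_rng(seed)
    cut = math.ceil(threshold * n_arrays)  # smallest expressed count
    if present_counts is None:
        counts = []
        labels = rng.choice(3, size=n_genes, p=np.asarray(label_fractions))
        for lab in labels:
            if lab == 0:
                counts.append(0)
            elif lab == 1:
                counts.append(int(rng.integers(1, cut)))
            else:
                counts.append(int(rng.integers(cut, n_arrays + 1)))
    else:
        counts = [int(c) for c in present_counts]
        if len(counts) != n_genes:
            raise ValueError("present_counts length != n_genes")

    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    array_ids = [f"array_{j + 1:04d}" for j in range(n_arrays)]
    grid = np.full((n_genes, n_arrays), "A", dtype="<U1")
    truth_rows = []
    for i, c in enumerate(counts):
        cols = rng.choice(n_arrays, size=c, replace=False)
        grid[i, cols] = "P"
        non_p = np.setdiff1d(np.arange(n_arrays), cols)
        m_cols = non_p[rng.random(len(non_p)) < marginal_rate]
        grid[i, m_cols] = "M"
        frac = c / n_arrays
        label = "no_expression" if c == 0 else ("low_expression" if frac < threshold else "expressed")
        truth_rows.append({"gene_id": gene_ids[i], "present_count": c, "label": label})
    matrix = ExpressionCallMatrix(pd.DataFrame(grid, index=gene_ids, columns=array_ids))
    return matrix, pd.DataFrame(truth_rows)


def _study_transition_probs() -> tuple[float, ...]:
    counts = load_funnel_fixture()
    vals = [counts[s] for s in FUNNEL_STAGES]
    return tuple(vals[i + 1] / vals[i] for i in range(len(vals) - 1))


@dataclass
class SyntheticFunnelSpec:
    seed: int
    n_genes: int = 627
    #: success probability of each transition along the funnel stage order;
    #: defaults follow the packaged study funnel
    transition_probs: tuple[float, ...] = field(default_factory=_study_transition_probs)
    n_dips: int = 3
    seedlings_per_dip: int = 3
    line_recovery_prob: float = 0.7
    line_survival_prob: float = 0.77  # plants surviving transfer to soil
    line_expression_prob: float = 0.8  # expressing lines of an expressing gene
    inconsistent_fraction: float = 0.05
    max_codes_per_pattern: int = 3

    def __post_init__(self) -> None:
        if len(self.transition_probs) != len(FUNNEL_STAGES) - 1:
            raise ValueError(
                f"transition_probs must have {len(FUNNEL_STAGES) - 1} entries"
            )
        for p in self.transition_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")


@dataclass
class FunnelBuild:
    records: list[PipelineRecord]
    lines: list[TransgenicLine]
    annotations: list[POAnnotation]


def generate_funnel(spec: SyntheticFunnelSpec) -> FunnelBuild:
    """Sample a construct funnel with transgenic lines and PO annotations.

    Every gene starts at primer_designed and survives each transition
    independently with the configured probability. Genes reaching
    transgenic_positive receive up to n_dips x seedlings_per_dip lines
    (at least one); expressing genes get a fixed per-gene PO pattern,
    with a configurable fraction of deviating (inconsistent) lines.
    """
    rng = np.random.default_rng(spec.seed)
    vocab_rows = load_table1_fixture().rows
    codes = [r.po_code for r in vocab_rows]
    weights = np.array([r.n_promoters for r in vocab_rows], dtype=float)
    weights /= weights.sum()

    def draw_pattern() -> frozenset[str]:
        n = int(rng.integers(1, spec.max_codes_per_pattern + 1))
        return frozenset(rng.choice(codes, size=n, replace=False, p=weights))

    records: list[PipelineRecord] = []
    lines: list[TransgenicLine] = []
    annotations: list[POAnnotation] = []
    image_counter = 0
    for i in range(spec.n_genes):
        gene_id = f"gene_{i + 1:04d}"
        furthest = FUNNEL_STAGES[0]
        for stage, p in zip(FUNNEL_STAGES[1:], spec.transition_probs):
            if rng.random() >= p:
                break
            furthest = stage
        records.append(PipelineRecord(gene_id=gene_id, furthest_stage=furthest))
        reached = set(FUNNEL_STAGES[: FUNNEL_STAGES.index(furthest) + 1])
        if "transgenic_positive" not in reached:
            continue
        gene_expresses = "gfp_positive" in reached
        pattern = draw_pattern() if gene_expresses else frozenset()

        gene_lines: list[TransgenicLine] = []
        for dip in range(1, spec.n_dips + 1):
            n_seedlings = int(rng.binomial(spec.seedlings_per_dip, spec.line_recovery_prob))
            for s in range(n_seedlings):
                gene_lines.append(
                    TransgenicLine(
                        line_id=f"{gene_id}_d{dip}s{s + 1}",
                        gene_id=gene_id,
                        dip_event=f"{gene_id}_dip{dip}",
                        survived_to_soil=bool(rng.random() < spec.line_survival_prob),
                    )
                )
        if not gene_lines:
            gene_lines.append(
                TransgenicLine(
                    line_id=f"{gene_id}_d1s1",
                    gene_id=gene_id,
                    dip_event=f"{gene_id}_dip1",
                    survived_to_soil=True,
                )
            )
        if "in_soil" in reached and not any(l.survived_to_soil for l in gene_lines):
            gene_lines[0].survived_to_soil = True

        if gene_expresses:
            expressing = [l for l in gene_lines if rng.random() < spec.line_expression_prob]
            if not expressing:
                expressing = [gene_lines[0]]
            for line in expressing:
                line_pattern = pattern
                if rng.random() < spec.inconsistent_fraction:
                    line_pattern = draw_pattern()
                n_stages = int(rng.integers(1, 3))
                stages = rng.choice(SCREENING_STAGES, size=n_stages, replace=False)
                for stage in stages:
                    line.observations.setdefault(str(stage), set()).update(line_pattern)
                    image_counter += 1
                    annotations.append(
                        POAnnotation(
                            image_id=f"img_{image_counter:05d}",
                            line_id=line.line_id,
                            gene_id=gene_id,
                            po_codes=line_pattern,
                            stage=str(stage),
                        )
                    )
        lines.extend(gene_lines)
    return FunnelBuild(records=records, lines=lines, annotations=annotations)
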