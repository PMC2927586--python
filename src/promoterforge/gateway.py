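"""Gateway attB tail assembly, PCR program metadata and plate-format orders.

Stage-1 PCR uses gene-specific primers carrying partial attB tails;
stage-2 uses universal 29 nt adapter primers that complete the attB1/attB2
recombination sites. The recombination site contributes an 8 amino acid
linker to the final promoter-reporter fusion, which also carries at least
16 native codons of the tagged gene (right primer 50-150 bp downstream of
the ATG).
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from typing import Optional

from .primers import PrimerPair
from .templates import PromoterTemplate

ADAPTER_LENGTH = 29


@dataclass(frozen=True)
class GatewayConstants:
    """Tail and adapter sequences for two-stage attB amplification.

    The downstream tail is stored as published (11 nt). The universal
    attB2 adapter ends ...AGAAAGCTGGGT, a 12 nt suffix differing from the
    11 nt tail by one G; ``standard_attb2()`` supplies the conventional
    12 nt tail for users who prefer the two to agree.
    """

    left_tail: str = "aaaaagcaggct"
    right_tail: str = "agaaagctggt"
    attb1_adapter: str = "GGGGACAAGTTTGTACAAAAAAGCAGGCT"
    attb2_adapter: str = "GGGGACCACTTTGTACAAGAAAGCTGGGT"
    linker_aa: int = 8

    def __post_init__(self) -> None:
        if len(self.attb1_adapter) != ADAPTER_LENGTH or len(self.attb2_adapter) != ADAPTER_LENGTH:
            raise ValueError("attB adapters must be 29 nt")
        if not self.attb1_adapter.upper().endswith(self.left_tail.upper()):
            raise ValueError("attB1 adapter does not end with the upstream tail")

    @classmethod
    def standard_attb2(cls) -> "GatewayConstants":
        return cls(right_tail="agaaagctgggt")


DEFAULT_CONSTANTS = GatewayConstants()


@dataclass
class TailedPrimerPair:
    gene_id: str
    left_oligo: str  # 5'->3': tail + gene-specific left primer
    right_oligo: str
    left_gene_specific: str
    right_gene_specific: str
    expected_stage1_product: int
    expected_stage2_product: int
    constants: GatewayConstants = field(default_factory=GatewayConstants)


def add_tails(
    pair: PrimerPair, constants: GatewayConstants = DEFAULT_CONSTANTS, gene_id: str = ""
) -> TailedPrimerPair:
    """Prepend the partial attB tails to an accepted pair's primers.

    Pure 5' concatenation; the gene-specific portions are unchanged. The
    stage-1 product is the genomic product plus both tails; stage 2
    extends each end to the full 29 nt adapter.
    """
    stage1 = pair.product_length + len(constants.left_tail) + len(constants.right_tail)
    stage2 = stage1 + (ADAPTER_LENGTH - len(constants.left_tail)) + (
        ADAPTER_LENGTH - len(constants.right_tail)
    )
    return TailedPrimerPair(
        gene_id=gene_id,
        left_oligo=constants.left_tail + pair.left.sequence,
        right_oligo=constants.right_tail + pair.right.sequence,
        left_gene_specific=pair.left.sequence,
        right_gene_specific=pair.right.sequence,
        expected_stage1_product=stage1,
        expected_stage2_product=stage2,
        constants=constants,
    )


def check_coding_inclusion(
    template: Optional[PromoterTemplate], pair: PrimerPair
) -> tuple[int, bool]:
    """Complete native codons captured downstream of the ATG, and whether
    the right primer end preserves the reading frame.

    With the 50-150 bp downstream placement every accepted design carries
    at least floor(50/3) = 16 codons.
    """
    if template is not None:
        atg = template.atg_offset
        if template.sequence[atg : atg + 3].upper() != "ATG":
            raise ValueError("template has no ATG at its annotated offset")
    codons = pair.downstream_offset // 3
    in_frame = pair.downstream_offset % 3 == 0
    return codons, in_frame


@dataclass(frozen=True)
class CycleBlock:
    repeats: int
    steps: tuple[tuple[float, Optional[int]], ...]  # (temperature C, seconds; None = hold)


#: Stage-1 touchdown program: annealing descends 63 -> 58 C, final block 9x.
STAGE1_PROGRAM: tuple[CycleBlock, ...] = (
    CycleBlock(1, ((98, 30),)),
    CycleBlock(1, ((98, 10), (63, 30), (72, 120))),
    CycleBlock(1, ((98, 10), (62, 30), (72, 120))),
    CycleBlock(1, ((98, 10), (61, 30), (72, 120))),
    CycleBlock(1, ((98, 10), (60, 30), (72, 120))),
    CycleBlock(1, ((98, 10), (59, 30), (72, 120))),
    CycleBlock(9, ((98, 10), (58, 30), (72, 120))),
    CycleBlock(1, ((72, 600),)),
    CycleBlock(1, ((4, None),)),
)

#: Stage-2 adapter program: single 56 C annealing temperature over 19 cycles.
STAGE2_PROGRAM: tuple[CycleBlock, ...] = (
    CycleBlock(1, ((98, 30),)),
    CycleBlock(19, ((98, 10), (56, 30), (72, 120))),
    CycleBlock(1, ((72, 600),)),
    CycleBlock(1, ((4, None),)),
)


def emit_pcr_protocol(stage: int) -> tuple[CycleBlock, ...]:
    """Return the thermal cycling program for amplification stage 1 or 2."""
    if stage == 1:
        return STAGE1_PROGRAM
    if stage == 2:
        return STAGE2_PROGRAM
    raise ValueError(f"stage must be 1 or 2, got {stage}")


WELLS_96 = tuple(f"{row}{col}" for row in string.ascii_uppercase[:8] for col in range(1, 13))


@dataclass
class PlateOrder:
    plate_id: str
    wells: dict[str, tuple[str, str, str]]  # well -> (gene_id, role, sequence)

    def __post_init__(self) -> None:
        if len(self.wells) > 96:
            raise ValueError("more than 96 wells on a plate")


def layout_plates(batch: list[TailedPrimerPair], prefix: str = "plate") -> list[PlateOrder]:
    """Arrange a batch into paired left/right 96-well plates, row-major.

    The left and right oligo of gene k occupy the same well index on the
    corresponding left/right plates; overflow opens a new plate pair.
    """
    plates: list[PlateOrder] = []
    for chunk_start in range(0, len(batch), 96):
        chunk = batch[chunk_start : chunk_start + 96]
        idx = chunk_start // 96 + 1
        left_wells, right_wells = {}, {}
        for well, tp in zip(WELLS_96, chunk):
            left_wells[well] = (tp.gene_id, "left", tp.left_oligo.upper())
            right_wells[well] = (tp.gene_id, "right", tp.right_oligo.upper())
        plates.append(PlateOrder(f"{prefix}_{idx}_left", left_wells))
        plates.append(PlateOrder(f"{prefix}_{idx}_right", right_wells))
    return plates


ORDER_COLUMNS = ("plate", "well", "name", "sequence")


def write_order_file(plates: list[PlateOrder], path: str) -> None:
    """Vendor-style delimited oligo order file (uppercase sequences)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(ORDER_COLUMNS)
        for plate in plates:
            for well in WELLS_96:
                if well not in plate.wells:
                    continue
                gene_id, role, seq = plate.wells[well]
                writer.writerow([plate.plate_id, well, f"{gene_id}_{role}", seq])


def read_order_file(path: str) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if tuple(reader.fieldnames or ()) != ORDER_COLUMNS:
            raise ValueError(f"unexpected order-file header in {path}")
        return list(reader)
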