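"""Construct-funnel tracking, expression consistency and PO analytics.

Constructs progress through an ordered funnel from primer design to a
GFP-positive transgenic line; per-stage attrition is summarized as
percentage success rates. Transgenic lines carry Plant Ontology (PO)
coded expression observations from four screening stages; per-gene
consistency categories and promoters-per-code summaries reproduce the
study's reporting shape. Storage is an embedded relational (SQLite)
file with delimited-text import/export — a desk-scale stand-in for a
server LIMS.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

FUNNEL_STAGES: tuple[str, ...] = (
    "primer_designed",
    "entry_clone",
    "sequence_confirmed",
    "expression_clone",
    "agro_clone",
    "dipped",
    "transgenic_positive",
    "in_soil",
    "gfp_positive",
)

SCREENING_STAGES: tuple[str, ...] = ("plate_day10", "rosette", "pre_flowering", "flowering")

PO_CODE_RE = re.compile(r"^PO:\d{7}$")

CONSISTENT_MULTI = "consistent_multi"
SINGLE_LINE_EXPRESSING = "single_line_expressing"
SINGLE_EXPRESSING_OF_MANY = "single_expressing_of_many"
INCONSISTENT = "inconsistent"
NO_EXPRESSION = "no_expression"


@dataclass
class PipelineRecord:
    """Per-gene progress through the construct funnel.

    Stages are monotone: a stage can only be reached if every prior
    stage was reached, so progress is stored as the furthest stage index.
    """

    gene_id: str
    furthest_stage: Optional[str] = None
    notes: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.furthest_stage is not None and self.furthest_stage not in FUNNEL_STAGES:
            raise ValueError(f"unknown funnel stage {self.furthest_stage!r}")

    def reached(self, stage: str) -> bool:
        if stage not in FUNNEL_STAGES:
            raise ValueError(f"unknown funnel stage {stage!r}")
        if self.furthest_stage is None:
            return False
        return FUNNEL_STAGES.index(stage) <= FUNNEL_STAGES.index(self.furthest_stage)


@dataclass
class TransgenicLine:
    """One kanamycin-selected plant from a floral-dip transformation."""

    line_id: str
    gene_id: str
    dip_event: str  # identifier of the independent transformation (3 per construct)
    survived_to_soil: bool = True
    observations: dict[str, set[str]] = field(default_factory=dict)  # stage -> PO codes

    def __post_init__(self) -> None:
        for stage in self.observations:
            if stage not in SCREENING_STAGES:
                raise ValueError(f"unknown screening stage {stage!r}")

    @property
    def pattern(self) -> frozenset[str]:
        """Union of the line's PO codes over all screening stages."""
        out: set[str] = set()
        for codes in self.observations.values():
            out |= codes
        return frozenset(out)

    @property
    def gfp_observed(self) -> bool:
        return bool(self.pattern)


@dataclass(frozen=True)
class POAnnotation:
    image_id: str
    line_id: str
    gene_id: str
    po_codes: frozenset[str]
    stage: str

    def __post_init__(self) -> None:
        for code in self.po_codes:
            if not PO_CODE_RE.match(code):
                raise ValueError(f"invalid PO code {code!r}")
        if self.stage not in SCREENING_STAGES:
            raise ValueError(f"unknown screening stage {self.stage!r}")


class POSummaryRow(NamedTuple):
    po_code: str
    po_name: str
    n_promoters: int


@dataclass
class POSummary:
    """Promoters-per-code table: one row per PO code, counting distinct
    annotated genes (a gene annotated on many images counts once)."""

    rows: list[POSummaryRow]

    @property
    def n_distinct_codes(self) -> int:
        return len(self.rows)

    @property
    def most_frequent(self) -> Optional[tuple[str, int]]:
        if not self.rows:
            return None
        best = min(self.rows, key=lambda r: (-r.n_promoters, r.po_code))
        return best.po_code, best.n_promoters


def stage_counts(records: Iterable[PipelineRecord]) -> dict[str, int]:
    records = list(records)
    return {stage: sum(r.reached(stage) for r in records) for stage in FUNNEL_STAGES}


def records_from_counts(counts: dict[str, int], prefix: str = "gene") -> list[PipelineRecord]:
    """Expand nested per-stage counts into individual records (gene i
    reaches stage s iff i < counts[s]); counts must be non-increasing
    along the funnel."""
    prev = None
    for stage in FUNNEL_STAGES:
        n = counts.get(stage, 0)
        if prev is not None and n > prev:
            raise ValueError(f"count for {stage!r} exceeds the preceding stage")
        prev = n
    total = counts.get(FUNNEL_STAGES[0], 0)
    records = []
    for i in range(total):
        furthest = None
        for stage in FUNNEL_STAGES:
            if i < counts.get(stage, 0):
                furthest = stage
        records.append(PipelineRecord(gene_id=f"{prefix}_{i + 1:04d}", furthest_stage=furthest))
    return records


def success_rate(
    records: Iterable[PipelineRecord], stage_from: str, stage_to: str
) -> float:
    """Percentage of records at ``stage_from`` that also reached
    ``stage_to``, rounded half-up to one decimal (so 469/627 -> 74.8)."""
    records = list(records)
    n_from = sum(r.reached(stage_from) for r in records)
    n_to = sum(r.reached(stage_from) and r.reached(stage_to) for r in records)
    if n_from == 0:
        raise ZeroDivisionError(f"no record reached {stage_from!r}")
    pct = Decimal(100 * n_to) / Decimal(n_from)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class ConsistencyResult(NamedTuple):
    category: str
    independent_dip_consistent: bool


def classify_consistency(
    lines: Sequence[TransgenicLine], relaxed: bool = False
) -> ConsistencyResult:
    """Classify the GFP consistency of one gene's transgenic lines.

    A line's pattern is the union of its PO codes over all screening
    stages; two lines agree iff their patterns are equal non-empty sets
    (``relaxed=True`` weakens agreement to a non-empty intersection).
    ``independent_dip_consistent`` additionally requires agreeing lines
    from at least two distinct dip events.
    """
    if not lines:
        raise ValueError("at least one line is required")
    genes = {l.gene_id for l in lines}
    if len(genes) > 1:
        raise ValueError(f"lines from multiple genes: {sorted(genes)}")
    expressing = [l for l in lines if l.gfp_observed]
    if not expressing:
        return ConsistencyResult(NO_EXPRESSION, False)
    if len(lines) == 1:
        return ConsistencyResult(SINGLE_LINE_EXPRESSING, False)
    if len(expressing) == 1:
        return ConsistencyResult(SINGLE_EXPRESSING_OF_MANY, False)

    if relaxed:
        agree = all(
            a.pattern & b.pattern
            for i, a in enumerate(expressing)
            for b in expressing[i + 1 :]
        )
    else:
        agree = len({l.pattern for l in expressing}) == 1
    if not agree:
        return ConsistencyResult(INCONSISTENT, False)
    dips = {l.dip_event for l in expressing}
    return ConsistencyResult(CONSISTENT_MULTI, len(dips) >= 2)


def summarize_po(
    annotations: Iterable[POAnnotation],
    vocabulary: Optional[dict[str, str]] = None,
) -> POSummary:
    """Count distinct promoters (genes) per PO code.

    Rows are ordered by descending promoter count, ties by code.
    ``vocabulary`` maps codes to names; codes outside it raise, matching
    load-time validation of the controlled vocabulary.
    """
    genes_per_code: dict[str, set[str]] = {}
    for ann in annotations:
        for code in ann.po_codes:
            if vocabulary is not None and code not in vocabulary:
                raise ValueError(f"PO code {code!r} not in vocabulary")
            genes_per_code.setdefault(code, set()).add(ann.gene_id)
    rows = [
        POSummaryRow(code, (vocabulary or {}).get(code, ""), len(genes))
        for code, genes in genes_per_code.items()
    ]
    rows.sort(key=lambda r: (-r.n_promoters, r.po_code))
    return POSummary(rows=rows)


class QueryResult(NamedTuple):
    annotations: list[POAnnotation]
    summary_rows: list[POSummaryRow]


class AnnotationStore:
    """Embedded relational store for lines, annotations and PO vocabulary."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.executescript(
            """
            CREATE TABLE IF NOT EXISTS po_vocab (
                po_code TEXT PRIMARY KEY, po_name TEXT, n_promoters INTEGER
            );
            CREATE TABLE IF NOT EXISTS lines (
                line_id TEXT PRIMARY KEY, gene_id TEXT, dip_event TEXT,
                survived_to_soil INTEGER
            );
            CREATE TABLE IF NOT EXISTS annotations (
                image_id TEXT, line_id TEXT, gene_id TEXT, po_code TEXT, stage TEXT
            );
            """
        )

    def load_vocabulary(self, rows: Iterable[POSummaryRow]) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO po_vocab VALUES (?, ?, ?)",
                [(r.po_code, r.po_name, r.n_promoters) for r in rows],
            )

    def add_lines(self, lines: Iterable[TransgenicLine]) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO lines VALUES (?, ?, ?, ?)",
                [(l.line_id, l.gene_id, l.dip_event, int(l.survived_to_soil)) for l in lines],
            )

    def add_annotations(self, annotations: Iterable[POAnnotation]) -> None:
        vocab = {row[0] for row in self.conn.execute("SELECT po_code FROM po_vocab")}
        rows = []
        for ann in annotations:
            for code in sorted(ann.po_codes):
                if vocab and code not in vocab:
                    raise ValueError(f"PO code {code!r} not in the loaded vocabulary")
                rows.append((ann.image_id, ann.line_id, ann.gene_id, code, ann.stage))
        with self.conn:
            self.conn.executemany("INSERT INTO annotations VALUES (?, ?, ?, ?, ?)", rows)

    def _annotations_where(self, where: str, params: tuple) -> list[POAnnotation]:
        cur = self.conn.execute(
            f"SELECT image_id, line_id, gene_id, stage, GROUP_CONCAT(po_code) "
            f"FROM annotations WHERE {where} "
            f"GROUP BY image_id, line_id, gene_id, stage ORDER BY gene_id, image_id",
            params,
        )
        return [
            POAnnotation(img, line, gene, frozenset(codes.split(",")), stage)
            for img, line, gene, stage, codes in cur
        ]

    def query(self, by: str, value: str) -> QueryResult:
        """Search by exact ``po_code`` or ``gene_id``, or case-insensitive
        ``tissue`` substring against PO names; annotation results are
        ordered by (gene_id, image_id)."""
        if by == "po_code":
            anns = self._annotations_where("po_code = ?", (value,))
            rows = self.conn.execute(
                "SELECT po_code, po_name, n_promoters FROM po_vocab WHERE po_code = ?", (value,)
            ).fetchall()
        elif by == "gene_id":
            anns = self._annotations_where("gene_id = ?", (value,))
            rows = []
        elif by == "tissue":
            rows = self.conn.execute(
                "SELECT po_code, po_name, n_promoters FROM po_vocab "
                "WHERE LOWER(po_name) LIKE ? ORDER BY po_code",
                (f"%{value.lower()}%",),
            ).fetchall()
            codes = [r[0] for r in rows]
            if codes:
                marks = ",".join("?" * len(codes))
                anns = self._annotations_where(f"po_code IN ({marks})", tuple(codes))
            else:
                anns = []
        else:
            raise ValueError(f"unknown query key {by!r} (use po_code, gene_id or tissue)")
        return QueryResult(annotations=anns, summary_rows=[POSummaryRow(*r) for r in rows])

    def export_annotations(self, path: str) -> None:
        df = pd.read_sql_query(
            "SELECT * FROM annotations ORDER BY gene_id, image_id, po_code", self.conn
        )
        df.to_csv(path, sep="\t", index=False)

    def import_annotations(self, path: str) -> None:
        df = pd.read_csv(path, sep="\t", dtype=str)
        grouped: dict[tuple, set[str]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault((row.image_id, row.line_id, row.gene_id, row.stage), set()).add(
                row.po_code
            )
        self.add_annotations(
            POAnnotation(img, line, gene, frozenset(codes), stage)
            for (img, line, gene, stage), codes in grouped.items()
        )


def query(store: AnnotationStore, by: str, value: str) -> QueryResult:
    """Module-level convenience wrapper around :meth:`AnnotationStore.query`."""
    return store.query(by, value)
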