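"""Packaged study fixtures: the construct funnel and the PO summary table.

These are the study's printed aggregate outcomes, shipped as plain-text
data so the analytics layer can be exercised and checked without any
download. Line-level wet-lab data was never published; the aggregate
totals that depend on it are carried here as metadata and consistency-
checked, not recomputed.
"""

from __future__ import annotations

import csv
import hashlib
from importlib import resources

from .tracking import POSummary, POSummaryRow, PipelineRecord, records_from_counts

_TABLE1_SHA256 = "81d321eb183bb4b260a2a93288043abfc89ae0125200b4673e5082aed7f7afe3"


def _data_text(name: str) -> str:
    return resources.files("promoterforge.data").joinpath(name).read_text()


def load_table1_fixture() -> POSummary:
    """The packaged promoters-per-PO-code summary (81 codes; leaf
    vascular system is the most frequent at 38 promoters)."""
    text = _data_text("table1_po_summary.tsv")
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError("table1_po_summary.tsv checksum mismatch; fixture corrupted")
    rows = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for rec in reader:
        rows.append(POSummaryRow(rec["po_code"], rec["po_name"], int(rec["n_promoters"])))
    return POSummary(rows=rows)


def po_vocabulary() -> dict[str, str]:
    """PO code -> name mapping from the packaged summary."""
    return {r.po_code: r.po_name for r in load_table1_fixture().rows}


def load_funnel_fixture() -> dict[str, int]:
    """Per-stage construct counts of the study funnel (627 designed
    through 150 GFP-positive)."""
    counts = {}
    for rec in csv.DictReader(_data_text("funnel_figure2.csv").splitlines()):
        counts[rec["stage"]] = int(rec["count"])
    return counts


def funnel_records() -> list[PipelineRecord]:
    """The funnel fixture expanded into per-gene pipeline records."""
    return records_from_counts(load_funnel_fixture())


#: Aggregate wet-lab outcomes that depend on unpublished line-level data.
#: Carried as metadata for consistency checks only; the per-line events
#: behind them cannot be regenerated.
STUDY_METADATA: dict[str, object] = {
    "transgenic_lines_total": 1885,
    "genes_with_transgenic_lines": 266,
    "plants_survived_to_soil": 1457,
    "genes_survived_to_soil": 239,
    "expressing_plants": 761,
    "expressing_genes": 150,
    "gfp_images": 2287,
    "po_assignments": 3371,
    "consistency_categories": {
        "consistent_multi": 112,
        "single_line_expressing": 19,
        "single_expressing_of_many": 14,
        "inconsistent": 5,
    },
    "independent_dip_consistent_genes": 79,
    # GFP-negative PCR spot checks reported at two scopes in the source;
    # both retained as notes.
    "gfp_negative_pcr_checks": (
        {"plants": 256, "promoters": 89},
        {"lines": 423, "promoters": 83},
    ),
}
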