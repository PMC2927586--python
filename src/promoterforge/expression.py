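"""Candidate-gene selection from microarray detection calls.

Genes are classified from a gene x array grid of Affymetrix-style
present/marginal/absent (P/M/A) calls: a gene is *expressed* in an array
iff the call is P; marginal counts as non-expressed. A gene with no P
calls at all is a *no_expression* candidate, one with a present fraction
strictly below the threshold (default 5%) is *low_expression*, and
anything at or above the threshold is *expressed* and never a candidate.
Candidates independently shown to be expressed by MPSS (massively
parallel signature sequencing) are excluded afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

CALLS = frozenset("PMA")

NO_EXPRESSION = "no_expression"
LOW_EXPRESSION = "low_expression"
EXPRESSED = "expressed"


@dataclass
class ExpressionCallMatrix:
    """P/M/A call grid; rows are genes, columns are arrays.

    ``n_imputed`` counts input cells that were missing and explicitly
    imputed as A (absent).
    """

    calls: pd.DataFrame
    n_imputed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.calls.values.ravel()) - CALLS
        if bad:
            raise ValueError(f"calls must be P/M/A, found {sorted(bad)}")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValueError("duplicate gene or array ids in call matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    present_fraction: float
    label: str


def read_call_matrix(path: str, sep: str = "\t") -> ExpressionCallMatrix:
    """Read a delimited call matrix: first column gene id, header row of
    array ids, values P/M/A (case-insensitive). Missing cells are imputed
    as A and counted."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    n_missing = int(df.isna().sum().sum())
    df = df.fillna("A").apply(lambda col: col.str.strip().str.upper())
    return ExpressionCallMatrix(calls=df, n_imputed=n_missing)


def classify_expression(
    matrix: ExpressionCallMatrix, threshold: float = 0.05
) -> list[ExpressionClass]:
    """Label every gene by its fraction of present calls.

    ``less than`` the threshold is read strictly: a gene at exactly the
    threshold is *expressed*. With the study's 1381 arrays, 69 P calls
    (0.04997) is low_expression and 70 (0.05068) is expressed.
    """
    n_arrays = len(matrix.array_ids)
    if n_arrays == 0:
        raise ValueError("call matrix has zero array columns")
    present = (matrix.calls == "P").sum(axis=1)
    out = []
    for gene_id, n_present in present.items():
        frac = n_present / n_arrays
        if frac == 0:
            label = NO_EXPRESSION
        elif frac < threshold:
            label = LOW_EXPRESSION
        else:
            label = EXPRESSED
        out.append(ExpressionClass(gene_id=str(gene_id), present_fraction=frac, label=label))
    return out


class SelectionResult(NamedTuple):
    candidates: list[ExpressionClass]
    excluded: list[tuple[str, str]]  # (gene_id, reason)


def apply_mpss_exclusion(
    classes: list[ExpressionClass], mpss_expressed: set[str]
) -> SelectionResult:
    """Drop no/low-expression candidates with independent MPSS expression
    evidence. Expressed genes were never candidates; MPSS ids that match
    no gene are ignored with a warning."""
    known = {c.gene_id for c in classes}
    unknown = mpss_expressed - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} MPSS ids not present in the call matrix were ignored",
            stacklevel=2,
        )
    candidates: list[ExpressionClass] = []
    excluded: list[tuple[str, str]] = []
    for cls in classes:
        if cls.label == EXPRESSED:
            continue
        if cls.gene_id in mpss_expressed:
            excluded.append((cls.gene_id, "mpss_expressed"))
        else:
            candidates.append(cls)
    return SelectionResult(candidates=candidates, excluded=excluded)
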