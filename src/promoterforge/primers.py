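"""Primer pair enumeration and scoring for promoter cloning.

Pairs are picked on a promoter template under hard placement constraints:
the product (2150-2650 bp) must contain the 50 bp target window starting
at the ATG, the left primer 5' end must sit at least 2000 bp upstream of
the ATG, and the right primer 3' end between 50 and 150 bp downstream of
it — guaranteeing at least 16 native codons in the eventual reporter
fusion. Within those constraints candidates are filtered by length, GC,
melting temperature and self-complementarity, ranked by a penalty score,
and handed to the genome-wide specificity screen in rank order until one
pair passes.

Melting temperatures use the SantaLucia (1998) unified nearest-neighbor
parameter set with the Owczarzy (2004) monovalent salt correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .genome import reverse_complement
from .templates import PromoterTemplate

R_GAS = 1.987  # cal / (mol K)

# SantaLucia 1998 unified NN parameters: dH (kcal/mol), dS (cal/mol/K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
NN_INIT_AT = (2.3, 4.1)
NN_INIT_GC = (0.1, -2.8)
NN_SYMMETRY_DS = -1.4

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for duplex melting.

    Divalent cations are folded into an equivalent monovalent
    concentration (von Ahsen et al. 2001: Na_eq = mono + 120*sqrt(Mg-dNTP),
    concentrations in mM).
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    oligo_nM: float = 50.0

    @property
    def sodium_equivalent_M(self) -> float:
        free_mg = max(self.divalent_mM - self.dntp_mM, 0.0)
        return (self.monovalent_mM + 120.0 * math.sqrt(free_mg)) * 1e-3


DEFAULT_CONDITIONS = TmConditions()


@dataclass
class DesignParams:
    """Tunable primer design constraints; defaults are the pipeline's."""

    product_min: int = 2150
    product_max: int = 2650
    target_length: int = 50  # target window = [atg, atg + target_length)
    min_upstream: int = 2000  # left 5' end to ATG, bp
    downstream_min: int = 50  # ATG to right 3' end, bp
    downstream_max: int = 150
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    #: self-dimer caps under the match=+1/mismatch=0 scoring; chosen near
    #: the upper decile of random-sequence scores so only strongly
    #: palindromic oligos (a perfect 20-mer palindrome scores 20) fail
    max_self_any: int = 16
    max_self_end: int = 12
    max_homopolymer: int = 5
    weight_tm: float = 1.0
    weight_len: float = 1.0
    weight_tm_diff: float = 1.0
    candidates_per_gene: int = 20
    #: per-side shortlist depth used during pairing; primers beyond this
    #: rank by individual penalty are never considered
    candidates_per_side: int = 150
    enforce_frame: bool = False
    conditions: TmConditions = field(default_factory=TmConditions)


@dataclass
class PrimerCandidate:
    sequence: str  # 5'->3'
    template_start: int  # leftmost template offset of the annealing window
    length: int
    orientation: str  # 'left' or 'right'
    tm: float
    gc: float
    self_any: int = 0
    self_end: int = 0
    hairpin: int = 0
    penalty: float = 0.0

    @property
    def five_prime(self) -> int:
        """Template offset of the 5' end (the tailed end)."""
        return self.template_start if self.orientation == "left" else self.template_start + self.length - 1

    @property
    def three_prime(self) -> int:
        """Template offset of the 3' (extending) end."""
        return self.template_start + self.length - 1 if self.orientation == "left" else self.template_start

    @property
    def outer_boundary(self) -> int:
        """Template offset of the amplicon boundary this primer defines:
        the leftmost base for a left primer, the rightmost for a right
        primer (both primers are fully contained in the product)."""
        return self.template_start if self.orientation == "left" else self.template_start + self.length - 1


@dataclass
class PrimerPair:
    left: PrimerCandidate
    right: PrimerCandidate
    product_length: int  # right outer boundary - left outer boundary + 1
    upstream_distance: int  # left 5' end to ATG, bp
    downstream_offset: int  # ATG through the right primer's outer base, bp (inclusive)
    pair_penalty: float
    specificity: Optional[object] = None  # SpecificityReport, attached by the screen
    status: str = "candidate"  # candidate | accepted | rejected_specificity | failed


@dataclass
class EnumerationResult:
    pairs: list[PrimerPair]
    reason: Optional[str] = None  # set when no pairs could be produced


@dataclass
class DesignOutcome:
    """Result of iterative design for one gene: an accepted pair, or a
    failure record listing the per-pair rejection reasons."""

    gene_id: str
    pair: Optional[PrimerPair]
    rejections: list[tuple[int, str]] = field(default_factory=list)
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.pair is not None


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length; rejects empty or N-containing sequences."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT residues: {seq}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def compute_tm(seq: str, conditions: TmConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor melting temperature in deg C.

    SantaLucia 1998 unified dH/dS sums with terminal initiation terms;
    self-complementary sequences get the symmetry entropy correction and
    a total-strand (rather than CT/4) concentration term. The 1 M Tm is
    then adjusted to the monovalent concentration with the Owczarzy 2004
    quadratic-in-ln[Na+] reciprocal-temperature correction.
    """
    seq = seq.upper()
    if not 8 <= len(seq) <= 36:
        raise ValueError(f"sequence length {len(seq)} outside 8..36")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT residues")

    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        if step not in NN_PARAMS:
            step = _COMP[step[1]] + _COMP[step[0]]  # reverse complement step
        h, s = NN_PARAMS[step]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = NN_INIT_AT if terminal in "AT" else NN_INIT_GC
        dh += h
        ds += s

    selfcomp = seq == reverse_complement(seq)
    ct = conditions.oligo_nM * 1e-9
    if selfcomp:
        ds += NN_SYMMETRY_DS
        k = ct
    else:
        k = ct / 4.0
    tm_1m = dh * 1000.0 / (ds + R_GAS * math.log(k))  # Kelvin

    na = conditions.sodium_equivalent_M
    fgc = gc_fraction(seq)
    inv_tm = 1.0 / tm_1m + (4.29 * fgc - 3.95) * 1e-5 * math.log(na) + 9.40e-6 * math.log(na) ** 2
    return 1.0 / inv_tm - 273.15


def self_complementarity(seq: str) -> tuple[int, int]:
    """Ungapped self-dimer scores (match=+1, mismatch=0).

    ``self_any`` is the maximum number of complementary base pairs over
    all antiparallel self-alignments; ``self_end`` restricts the maximum
    to alignments in which the 3'-terminal base is paired, so
    self_end <= self_any always.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    self_any = 0
    self_end = 0
    # offset d: position i pairs with j = n - 1 - i + d
    for d in range(-(n - 1), n):
        score = 0
        for i in range(n):
            j = n - 1 - i + d
            if 0 <= j < n and _COMP.get(seq[i]) == seq[j]:
                score += 1
        self_any = max(self_any, score)
        if 0 <= d < n:  # 3' base (i = n-1) pairs with j = d
            self_end = max(self_end, score)
    return self_any, self_end


def hairpin_score(seq: str) -> int:
    """Longest contiguous complementary stem closable with a >=3 nt loop."""
    seq = seq.upper()
    n = len(seq)
    best = 0
    run: dict[tuple[int, int], int] = {}
    for gap in range(4, n):  # j - i >= 4 means loop >= 3
        for i in range(0, n - gap):
            j = i + gap
            if _COMP.get(seq[i]) == seq[j]:
                inner = run.get((i + 1, j - 1), 0)
                run[(i, j)] = inner + 1 if (inner > 0 or gap >= 4) else 0
                best = max(best, run[(i, j)])
    return best


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _candidate_windows(
    template: str,
    orientation: str,
    anchor_range: tuple[int, int],
    params: DesignParams,
) -> list[PrimerCandidate]:
    """Enumerate, filter and shortlist one side's primer candidates.

    ``anchor_range`` is the inclusive range of 5' positions (left) or 3'
    positions (right). Cheap filters (alphabet, homopolymer, GC, Tm) run
    on every window; self-complementarity caps are applied while walking
    candidates in ascending individual penalty until the per-side
    shortlist is full, which leaves the ranked output identical to
    filtering everything first.
    """
    lo, hi = anchor_range
    n = len(template)
    raw: list[PrimerCandidate] = []
    for anchor in range(lo, hi + 1):
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            if orientation == "left":
                start, end = anchor, anchor + length
            else:
                start, end = anchor - length + 1, anchor + 1
            if start < 0 or end > n:
                continue
            window = template[start:end]
            seq = window if orientation == "left" else reverse_complement(window)
            if "N" in seq:
                continue
            if _max_homopolymer(seq) > params.max_homopolymer:
                continue
            gc = gc_fraction(seq)
            if not params.gc_min <= gc <= params.gc_max:
                continue
            tm = compute_tm(seq, params.conditions)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            penalty = params.weight_tm * abs(tm - params.tm_opt) + params.weight_len * abs(
                length - params.primer_len_opt
            )
            raw.append(
                PrimerCandidate(
                    sequence=seq,
                    template_start=start,
                    length=length,
                    orientation=orientation,
                    tm=tm,
                    gc=gc,
                    penalty=penalty,
                )
            )
    raw.sort(key=lambda c: (c.penalty, c.template_start, c.length))
    shortlist: list[PrimerCandidate] = []
    for cand in raw:
        if len(shortlist) >= params.candidates_per_side:
            break
        self_any, self_end = self_complementarity(cand.sequence)
        if self_any > params.max_self_any or self_end > params.max_self_end:
            continue
        cand.self_any, cand.self_end = self_any, self_end
        cand.hairpin = hairpin_score(cand.sequence)
        shortlist.append(cand)
    return shortlist


def enumerate_pairs(template: PromoterTemplate, params: DesignParams) -> EnumerationResult:
    """Enumerate and rank primer pairs satisfying all placement constraints.

    Returns the top ``candidates_per_gene`` pairs by ascending pair
    penalty (ties broken by (left start, right end, left length, right
    length)); an empty list carries a reason code.
    """
    seq = template.sequence.upper()
    atg = template.atg_offset
    n = len(seq)

    right_end_lo = atg + params.downstream_min - 1
    right_end_hi = min(atg + params.downstream_max - 1, n - 1)
    left_start_lo = max(0, right_end_lo + 1 - params.product_max)
    left_start_hi = min(atg - params.min_upstream, right_end_hi + 1 - params.product_min)
    if right_end_lo > right_end_hi or left_start_lo > left_start_hi:
        return EnumerationResult(pairs=[], reason="template_too_short")

    lefts = _candidate_windows(seq, "left", (left_start_lo, left_start_hi), params)
    rights = _candidate_windows(seq, "right", (right_end_lo, right_end_hi), params)
    if not lefts or not rights:
        return EnumerationResult(pairs=[], reason="no_feasible_primer")

    pairs: list[PrimerPair] = []
    for left in lefts:
        for right in rights:
            product = right.outer_boundary - left.outer_boundary + 1
            if not params.product_min <= product <= params.product_max:
                continue
            downstream = right.outer_boundary - atg + 1
            if params.enforce_frame and downstream % 3 != 0:
                continue
            pair_penalty = left.penalty + right.penalty + params.weight_tm_diff * abs(
                left.tm - right.tm
            )
            pairs.append(
                PrimerPair(
                    left=left,
                    right=right,
                    product_length=product,
                    upstream_distance=atg - left.five_prime,
                    downstream_offset=downstream,
                    pair_penalty=pair_penalty,
                )
            )
    if not pairs:
        return EnumerationResult(pairs=[], reason="no_feasible_pair")
    pairs.sort(
        key=lambda p: (
            p.pair_penalty,
            p.left.outer_boundary,
            p.right.outer_boundary,
            p.left.length,
            p.right.length,
        )
    )
    return EnumerationResult(pairs=pairs[: params.candidates_per_gene])


def design_for_gene(
    template: PromoterTemplate,
    params: DesignParams,
    screen: Callable[[PrimerPair], object],
) -> DesignOutcome:
    """Iterate through ranked pairs until one passes the specificity screen.

    ``screen`` is called with each pair in rank order and must return a
    report object with a boolean ``passed`` attribute (attached to the
    pair). The first passing pair is returned with status ``accepted``;
    exhaustion yields a failure record listing every rejection.
    """
    enum = enumerate_pairs(template, params)
    if not enum.pairs:
        return DesignOutcome(gene_id=template.gene_id, pair=None, reason=enum.reason)
    rejections: list[tuple[int, str]] = []
    for rank, pair in enumerate(enum.pairs):
        report = screen(pair)
        pair.specificity = report
        if getattr(report, "passed"):
            pair.status = "accepted"
            return DesignOutcome(gene_id=template.gene_id, pair=pair, rejections=rejections)
        pair.status = "rejected_specificity"
        rejections.append((rank, "specificity"))
    return DesignOutcome(
        gene_id=template.gene_id, pair=None, rejections=rejections, reason="all_candidates_rejected"
    )
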