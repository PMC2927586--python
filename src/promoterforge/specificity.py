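"""Genome-wide primer specificity screening.

Each primer is slid (ungapped, both strands) across the genome; a window
whose identity — matching bases over primer length — reaches the
threshold (default 80%) is an off-target locus. Overlapping windows on
one strand are merged into a single locus anchored at the best-identity
offset. A primer pair passes when each primer has at most ``max_hits``
(default 3) loci; the intended locus is always among them, since a
primer hits itself in the genome.

Two matchers are provided: an exhaustive sliding scan (the oracle) and a
k-mer seed-and-verify fast path that is guaranteed complete whenever the
pigeonhole condition holds — (mismatch budget + 1) disjoint seeds of the
chosen length fit inside the primer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import GenomeSequence, reverse_complement
from .primers import PrimerPair

DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MAX_HITS = 3
DEFAULT_SEED_LENGTH = 11


@dataclass(frozen=True)
class MatchLocus:
    contig_id: str
    start: int  # + strand axis offset of the window start
    strand: str
    identity: float
    primer_role: str | None = None  # 'left' or 'right' once attached to a pair


@dataclass
class SpecificityReport:
    left_hits: list[MatchLocus]
    right_hits: list[MatchLocus]
    passed: bool
    max_hits: int = DEFAULT_MAX_HITS
    min_identity: float = DEFAULT_MIN_IDENTITY
    mode: str = "per_primer"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _min_matches(k: int, min_identity: float) -> int:
    # smallest integer m with m / k >= min_identity
    return int(np.ceil(min_identity * k - 1e-9))


def _window_match_counts(contig_arr: np.ndarray, primer_arr: np.ndarray) -> np.ndarray:
    """Matching-base count for every window of primer length (vectorized)."""
    k = len(primer_arr)
    n_windows = len(contig_arr) - k + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n_windows, dtype=np.int32)
    for j in range(k):
        counts += contig_arr[j : j + n_windows] == primer_arr[j]
    return counts


def _merge_windows(
    contig_id: str, strand: str, starts: np.ndarray, counts: np.ndarray, k: int
) -> list[MatchLocus]:
    """Merge overlapping same-strand windows; keep the best-identity
    anchor, ties resolved leftmost."""
    loci: list[MatchLocus] = []
    order = np.argsort(starts, kind="stable")
    starts, counts = starts[order], counts[order]
    i = 0
    n = len(starts)
    while i < n:
        best_start, best_count = int(starts[i]), int(counts[i])
        cluster_end = best_start + k
        j = i + 1
        while j < n and int(starts[j]) < cluster_end:
            if int(counts[j]) > best_count:
                best_count, best_start = int(counts[j]), int(starts[j])
            cluster_end = max(cluster_end, int(starts[j]) + k)
            j += 1
        loci.append(MatchLocus(contig_id, best_start, strand, best_count / k))
        i = j
    return loci


def brute_force_matches(
    primer: str,
    genome: list[GenomeSequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[MatchLocus]:
    """Exhaustive ungapped scan of both strands of every contig."""
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 nt")
    k = len(primer)
    need = _min_matches(k, min_identity)
    loci: list[MatchLocus] = []
    probes = {"+": _encode(primer), "-": _encode(reverse_complement(primer))}
    for contig in genome:
        arr = _encode(contig.residues)
        for strand, probe in probes.items():
            counts = _window_match_counts(arr, probe)
            hits = np.nonzero(counts >= need)[0]
            if hits.size:
                loci.extend(_merge_windows(contig.contig_id, strand, hits, counts[hits], k))
    return sorted(loci, key=lambda m: (m.contig_id, m.start, m.strand))


class GenomeKmerIndex:
    """Exact k-mer position index over the + strand of every contig."""

    def __init__(self, genome: list[GenomeSequence], seed_length: int):
        self.seed_length = seed_length
        self.positions: dict[str, dict[str, list[int]]] = {}
        for contig in genome:
            table: dict[str, list[int]] = {}
            s = contig.residues
            for i in range(len(s) - seed_length + 1):
                table.setdefault(s[i : i + seed_length], []).append(i)
            self.positions[contig.contig_id] = table


def seeded_matches(
    primer: str,
    genome: list[GenomeSequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_length: int = DEFAULT_SEED_LENGTH,
    index: GenomeKmerIndex | None = None,
) -> list[MatchLocus]:
    """k-mer seed-and-verify matcher, equivalent to the exhaustive scan
    whenever the pigeonhole condition holds.

    The primer is partitioned into ``budget + 1`` disjoint seed blocks
    (budget = floor((1 - min_identity) * length)); any window within the
    mismatch budget must contain at least one exact block. If the blocks
    do not fit, the matcher falls back to the exhaustive scan with a
    warning.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 nt")
    k = len(primer)
    budget = int((1.0 - min_identity) * k + 1e-9)
    if (budget + 1) * seed_length > k:
        warnings.warn(
            f"pigeonhole condition violated ({budget + 1} seeds of {seed_length} nt "
            f"do not fit in a {k} nt primer); falling back to the exhaustive scan",
            stacklevel=2,
        )
        return brute_force_matches(primer, genome, min_identity)
    if index is None or index.seed_length != seed_length:
        index = GenomeKmerIndex(genome, seed_length)
    need = _min_matches(k, min_identity)
    seed_offsets = [b * seed_length for b in range(budget + 1)]
    probes = {"+": primer, "-": reverse_complement(primer)}
    loci: list[MatchLocus] = []
    for contig in genome:
        arr = _encode(contig.residues)
        table = index.positions[contig.contig_id]
        for strand, probe in probes.items():
            probe_arr = _encode(probe)
            starts: set[int] = set()
            for off in seed_offsets:
                for pos in table.get(probe[off : off + seed_length], ()):
                    w = pos - off
                    if 0 <= w <= len(arr) - k:
                        starts.add(w)
            if not starts:
                continue
            verified = []
            for w in sorted(starts):
                m = int((arr[w : w + k] == probe_arr).sum())
                if m >= need:
                    verified.append((w, m))
            if verified:
                ws = np.array([v[0] for v in verified])
                ms = np.array([v[1] for v in verified])
                loci.extend(_merge_windows(contig.contig_id, strand, ws, ms, k))
    return sorted(loci, key=lambda m: (m.contig_id, m.start, m.strand))


def _with_role(loci: list[MatchLocus], role: str) -> list[MatchLocus]:
    return [
        MatchLocus(m.contig_id, m.start, m.strand, m.identity, primer_role=role) for m in loci
    ]


def count_amplicons(
    left_hits: list[MatchLocus],
    right_hits: list[MatchLocus],
    max_amplicon: int = 10_000,
) -> int:
    """Convergent co-placements of the two primers that could amplify."""
    n = 0
    for l in left_hits:
        for r in right_hits:
            if l.contig_id != r.contig_id or l.strand == r.strand:
                continue
            fwd, rev = (l, r) if l.strand == "+" else (r, l)
            if fwd.start <= rev.start and rev.start - fwd.start <= max_amplicon:
                n += 1
    return n


def evaluate_pair(
    pair: PrimerPair,
    genome: list[GenomeSequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits: int = DEFAULT_MAX_HITS,
    mode: str = "per_primer",
    matcher: str = "brute",
    seed_length: int = DEFAULT_SEED_LENGTH,
    index: GenomeKmerIndex | None = None,
) -> SpecificityReport:
    """Screen a primer pair against the genome.

    In the default ``per_primer`` mode the pair passes iff each primer
    has at most ``max_hits`` genomic loci (boundary inclusive: exactly 3
    loci still passes). The stricter ``amplicon`` mode instead caps the
    number of convergent left/right co-placements.
    """
    if matcher == "brute":
        find = lambda seq: brute_force_matches(seq, genome, min_identity)
    elif matcher == "seeded":
        find = lambda seq: seeded_matches(seq, genome, min_identity, seed_length, index)
    else:
        raise ValueError(f"unknown matcher {matcher!r}")
    left_hits = _with_role(find(pair.left.sequence), "left")
    right_hits = _with_role(find(pair.right.sequence), "right")
    if mode == "per_primer":
        passed = len(left_hits) <= max_hits and len(right_hits) <= max_hits
    elif mode == "amplicon":
        passed = count_amplicons(left_hits, right_hits) <= max_hits
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SpecificityReport(
        left_hits=left_hits,
        right_hits=right_hits,
        passed=passed,
        max_hits=max_hits,
        min_identity=min_identity,
        mode=mode,
    )


def write_bed(loci: list[MatchLocus], primer_length: int, path: str) -> None:
    """Write match loci as BED (0-based half-open, strand column)."""
    with open(path, "w") as fh:
        for m in loci:
            name = f"{m.primer_role or 'primer'}_id{m.identity:.2f}"
            fh.write(
                f"{m.contig_id}\t{m.start}\t{m.start + primer_length}\t{name}\t"
                f"{int(round(1000 * m.identity))}\t{m.strand}\n"
            )
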