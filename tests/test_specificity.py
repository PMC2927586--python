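"""Off-target matching: brute-force oracle, seeded fast path, pair screening."""

import numpy as np
import pytest

from promoterforge.genome import GenomeSequence, reverse_complement
from promoterforge.primers import PrimerCandidate, PrimerPair
from promoterforge.specificity import (
    GenomeKmerIndex,
    brute_force_matches,
    count_amplicons,
    evaluate_pair,
    seeded_matches,
    write_bed,
)
from promoterforge.synth import plant_offtarget_copies


def _random_genome(seed: int, length: int = 10_000, contig_id: str = "c") -> GenomeSequence:
    rng = np.random.default_rng(seed)
    return GenomeSequence(contig_id, "".join(rng.choice(list("ACGT"), size=length)))


def _mutate(seq: str, n_subs: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in rng.choice(np.arange(1, len(seq) - 1), size=n_subs, replace=False):
        out[i] = [b for b in "ACGT" if b != out[i]][int(rng.integers(3))]
    return "".join(out)


def test_planted_primer_found_exactly_once():
    genome = _random_genome(21)
    primer = genome.residues[4000:4020]
    loci = brute_force_matches(primer, [genome])
    assert len(loci) == 1
    assert (loci[0].contig_id, loci[0].start, loci[0].strand) == ("c", 4000, "+")
    assert loci[0].identity == 1.0


def test_identity_threshold_is_inclusive():
    """A 20-mer copy with 4 substitutions (16/20 = 0.80) is reported;
    5 substitutions (0.75) is not."""
    genome = _random_genome(22)
    primer = genome.residues[2000:2020]
    for n_subs, expected in [(4, 2), (5, 1)]:
        copy = _mutate(primer, n_subs)
        residues = genome.residues[:7000] + copy + genome.residues[7020:]
        loci = brute_force_matches(primer, [GenomeSequence("c", residues)])
        assert len(loci) == expected
        if expected == 2:
            assert {l.start for l in loci} == {2000, 7000}
            assert min(l.identity for l in loci) == pytest.approx(0.80)


def test_reverse_complement_planting_reported_on_minus_strand():
    genome = _random_genome(23)
    primer = genome.residues[1000:1020]
    rc = reverse_complement(primer)
    residues = genome.residues[:6000] + rc + genome.residues[6020:]
    loci = brute_force_matches(primer, [GenomeSequence("c", residues)])
    by_strand = {l.strand: l for l in loci}
    assert by_strand["+"].start == 1000
    assert by_strand["-"].start == 6000


def test_lowering_identity_never_shrinks_hit_set():
    genome = _random_genome(24, length=30_000)
    primer = genome.residues[5000:5020]
    strict = brute_force_matches(primer, [genome], min_identity=0.9)
    loose = brute_force_matches(primer, [genome], min_identity=0.7)
    strict_keys = {(l.contig_id, l.strand, l.start) for l in strict}
    loose_spans = {
        (l.contig_id, l.strand): [m.start for m in loose if (m.contig_id, m.strand) == (l.contig_id, l.strand)]
        for l in loose
    }
    # every strict locus is covered by a loose locus (merging may shift anchors)
    for cid, strand, start in strict_keys:
        assert any(abs(start - s) < 20 for s in loose_spans[(cid, strand)])
    assert len(loose) >= len(strict)


def test_seeded_equals_brute_force_on_random_draws():
    """Locus-set equality of the seeded matcher and the exhaustive oracle
    under the pigeonhole condition (20-mer, budget 4, seed 4)."""
    rng = np.random.default_rng(30)
    for trial in range(30):
        genome = _random_genome(1000 + trial, length=int(rng.integers(5_000, 40_000)))
        if trial % 2 == 0:
            start = int(rng.integers(0, genome.length - 20))
            primer = genome.residues[start : start + 20]
        else:
            primer = "".join(rng.choice(list("ACGT"), size=20))
        brute = brute_force_matches(primer, [genome])
        seeded = seeded_matches(primer, [genome], seed_length=4)
        assert [(l.contig_id, l.start, l.strand, l.identity) for l in brute] == [
            (l.contig_id, l.start, l.strand, l.identity) for l in seeded
        ]


def test_seeded_fallback_when_pigeonhole_fails():
    genome = _random_genome(31)
    primer = genome.residues[100:120]
    with pytest.warns(UserWarning, match="pigeonhole"):
        loci = seeded_matches(primer, [genome], seed_length=11)
    assert loci == brute_force_matches(primer, [genome])


def test_seeded_empty_genome():
    assert seeded_matches("ACGTACGTACGTACGTACGT", [], seed_length=4) == []


def test_seeded_accepts_prebuilt_index():
    genome = _random_genome(32)
    primer = genome.residues[500:520]
    index = GenomeKmerIndex([genome], seed_length=4)
    loci = seeded_matches(primer, [genome], seed_length=4, index=index)
    assert loci == brute_force_matches(primer, [genome])


def _pair_from(genome: GenomeSequence, left_at: int, right_at: int, k: int = 20) -> PrimerPair:
    left = PrimerCandidate(
        sequence=genome.residues[left_at : left_at + k],
        template_start=left_at, length=k, orientation="left", tm=60.0, gc=0.5,
    )
    right = PrimerCandidate(
        sequence=reverse_complement(genome.residues[right_at : right_at + k]),
        template_start=right_at, length=k, orientation="right", tm=60.0, gc=0.5,
    )
    return PrimerPair(
        left=left, right=right,
        product_length=right_at + k - left_at,
        upstream_distance=0, downstream_offset=0, pair_penalty=0.0,
    )


def test_evaluate_pair_unique_primers_pass():
    genome = _random_genome(40, length=20_000)
    pair = _pair_from(genome, 3000, 5400)
    report = evaluate_pair(pair, [genome])
    assert report.passed
    assert len(report.left_hits) == 1 and len(report.right_hits) == 1
    assert report.left_hits[0].primer_role == "left"


@pytest.mark.parametrize("n_extra,should_pass", [(2, True), (4, False)])
def test_evaluate_pair_hit_cap_is_boundary_inclusive(n_extra, should_pass):
    """With 2 planted copies the left primer has exactly 3 loci and still
    passes ('maximum of 3'); with 4 extra copies (5 loci) it fails."""
    genome = _random_genome(41, length=30_000)
    pair = _pair_from(genome, 3000, 5400)
    planted, _ = plant_offtarget_copies(
        [genome], pair.left.sequence, n_extra, identity=0.85,
        rng=np.random.default_rng(7), avoid={"c": [(2000, 7000)]},
    )
    report = evaluate_pair(pair, planted)
    assert len(report.left_hits) == 1 + n_extra
    assert report.passed is should_pass


def test_amplicon_mode_counts_convergent_placements():
    genome = _random_genome(42, length=20_000)
    pair = _pair_from(genome, 3000, 5400)
    report = evaluate_pair(pair, [genome], mode="amplicon")
    assert report.passed and report.mode == "amplicon"
    assert count_amplicons(report.left_hits, report.right_hits) == 1


def test_self_hit_present_for_designed_pairs(batch_designs):
    """Each accepted primer's hit list contains its own template locus."""
    for tpl, outcome in batch_designs:
        if not outcome.accepted:
            continue
        report = outcome.pair.specificity
        src = tpl.source_interval
        for hits, cand in ((report.left_hits, outcome.pair.left),
                           (report.right_hits, outcome.pair.right)):
            if src.strand == "+":
                genome_start = src.start + cand.template_start
                want_strand = "+" if cand.orientation == "left" else "-"
            else:
                genome_start = src.end - (cand.template_start + cand.length)
                want_strand = "-" if cand.orientation == "left" else "+"
            assert any(
                l.start == genome_start and l.strand == want_strand and l.identity == 1.0
                for l in hits
            )


def test_write_bed(tmp_path):
    genome = _random_genome(43)
    primer = genome.residues[100:120]
    loci = brute_force_matches(primer, [genome])
    path = tmp_path / "hits.bed"
    write_bed(loci, len(primer), str(path))
    fields = path.read_text().strip().split("\t")
    assert fields[0] == "c" and int(fields[1]) == 100 and int(fields[2]) == 120
    assert fields[5] == "+"
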