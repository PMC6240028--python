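"""STS marker placement, chromosome assignment and order concordance."""

import numpy as np
import pytest

from finishkit.assembly import Assembly, Scaffold, reverse_complement
from finishkit.errors import ConsistencyError
from finishkit.rhmap import (
    CONCORDANT,
    MISORIENTED,
    UNASSESSABLE,
    Marker,
    MarkerHit,
    assign_scaffolds,
    cross_assembly_partition,
    pair_concordance,
    place_all,
    place_marker,
)

FWD = "ACGTTGCAACGGTACGATCA"
REV = "TTGACCAGTACGGATTACCA"
rng = np.random.default_rng(11)


def random_seq(n):
    return "".join(rng.choice(list("ACGT"), n))


def toy_genome(insert, name="s1", pad=300):
    """A random scaffold with `insert` embedded after `pad` bases."""
    return Assembly("toy", [Scaffold(name, random_seq(pad) + insert + random_seq(pad))])


def marker(fwd=FWD, rev=REV, mid="m1", chrom="chr1", pos=1.0):
    return Marker(mid, chrom, pos, fwd, rev)


def test_placement_inward_facing_amplicon():
    asm = toy_genome(FWD + random_seq(30) + reverse_complement(REV))
    hit = place_marker(marker(), asm)
    assert hit.placed and hit.strand == "+"
    assert hit.amplicon_length == 70  # 20 + 30 + 20


def test_placement_on_minus_strand():
    """The mirrored arrangement places with '-' strand and same amplicon."""
    insert = FWD + random_seq(30) + reverse_complement(REV)
    asm = toy_genome(reverse_complement(insert))
    hit = place_marker(marker(), asm)
    assert hit.placed and hit.strand == "-"
    assert hit.amplicon_length == 70


def test_duplicate_primer_is_non_unique():
    asm = toy_genome(FWD + random_seq(30) + reverse_complement(REV) + random_seq(20) + FWD)
    assert place_marker(marker(), asm).status == "non_unique"


def test_missing_primer():
    asm = toy_genome(FWD + random_seq(30))
    assert place_marker(marker(), asm).status == "missing_primer"


def test_outward_facing_is_bad_orientation():
    # both primers unique on + strand, facing outward
    asm = toy_genome(FWD + random_seq(30) + REV)
    assert place_marker(marker(), asm).status == "bad_orientation"


def test_oversized_amplicon():
    asm = toy_genome(FWD + random_seq(2000) + reverse_complement(REV))
    assert place_marker(marker(), asm, max_amplicon=1000).status == "oversized"


def test_strand_symmetry_of_placement(truth):
    """Reverse-complementing the whole assembly preserves status and span."""
    flipped = Assembly(
        "rc",
        [Scaffold(s.name, reverse_complement(s.sequence)) for s in truth.assembly],
    )
    for m in truth.markers:
        a = place_marker(m, truth.assembly)
        b = place_marker(m, flipped)
        assert a.status == b.status
        if a.placed:
            assert a.amplicon_length == b.amplicon_length
            assert a.strand != b.strand


def hit(mid, scaffold, start, end, strand="+"):
    return MarkerHit(mid, "placed", scaffold, start, end, strand)


def markers_on(chrom, n, start_id=1):
    return [marker(mid=f"m{i}", chrom=chrom, pos=float(i)) for i in range(start_id, start_id + n)]


def test_assign_majority_order_orientation():
    ms = markers_on("chr1", 3) + [marker(mid="m4", chrom="chr2", pos=1.0)] + markers_on("chr1", 3, start_id=5)
    hits = {
        # scaffold A: markers m1,m2 (chr1) + m4 (chr2) -> majority chr1
        "m1": hit("m1", "A", 100, 200),
        "m2": hit("m2", "A", 300, 400),
        "m4": hit("m4", "A", 500, 600),
        # scaffold B: m5..m7 with map positions increasing, coords decreasing
        "m5": hit("m5", "B", 900, 1000),
        "m6": hit("m6", "B", 500, 600),
        "m7": hit("m7", "B", 100, 200),
    }
    assignments = {a.scaffold: a for a in assign_scaffolds(hits, ms)}
    assert assignments["A"].chromosome == "chr1"
    assert assignments["B"].chromosome == "chr1"
    assert assignments["B"].orientation == "-"  # rank-correlation sign
    assert assignments["A"].orientation == "+"
    # A holds map positions {1,2}, B holds {5,6,7}: A precedes B on chr1
    assert assignments["A"].order == 0 and assignments["B"].order == 1


def test_assign_tie_is_unassigned():
    ms = [marker(mid="m1", chrom="chr1"), marker(mid="m2", chrom="chr2")]
    hits = {"m1": hit("m1", "A", 0, 10), "m2": hit("m2", "A", 50, 60)}
    (a,) = assign_scaffolds(hits, ms)
    assert a.tie and a.chromosome is None


def test_pair_concordance_basic_order():
    ms = markers_on("chr1", 3)
    hits = {
        "m1": hit("m1", "A", 100, 120),
        "m2": hit("m2", "A", 200, 220),
        "m3": hit("m3", "A", 150, 170),  # out of order vs m2
    }
    conc = pair_concordance(ms, hits)
    assert conc[("m1", "m2")] == CONCORDANT
    assert conc[("m2", "m3")] == MISORIENTED


def test_unplaced_marker_makes_pair_unassessable():
    ms = markers_on("chr1", 2)
    hits = {"m1": hit("m1", "A", 100, 120), "m2": MarkerHit("m2", "missing_primer")}
    conc = pair_concordance(ms, hits)
    assert conc[("m1", "m2")] == UNASSESSABLE


def test_planted_inversion_flags_exactly_boundary_pairs(truth):
    """A single planted inversion is diagnosed by its two boundary pairs."""
    hits_a = place_all(truth.markers, truth.assembly)
    hits_b = place_all(truth.markers, truth.inverted_assembly)
    conc_a = pair_concordance(truth.markers, hits_a)
    conc_b = pair_concordance(truth.markers, hits_b)
    assert set(conc_a.values()) == {CONCORDANT}
    flagged = {k for k, v in conc_b.items() if v == MISORIENTED}
    assert flagged == set(truth.inversion_boundary_pairs)
    assert all(
        v == CONCORDANT for k, v in conc_b.items() if k not in flagged
    ), "interior pairs of the inversion must remain concordant"


def paper_partition_fixture():
    """Pair universes built from the published per-assembly aggregate counts."""
    total_b_mis, total_a_mis, shared = 395, 391, 352
    b_only_a_unassessable, a_only_b_unassessable = 36, 18
    conc_a, conc_b = {}, {}
    pair_no = 0

    def add(cat_a, cat_b, n):
        nonlocal pair_no
        for _ in range(n):
            key = (f"p{pair_no}", f"p{pair_no + 1}")
            conc_a[key] = cat_a
            conc_b[key] = cat_b
            pair_no += 2

    add(MISORIENTED, MISORIENTED, shared)
    add(UNASSESSABLE, MISORIENTED, b_only_a_unassessable)
    add(CONCORDANT, MISORIENTED, total_b_mis - shared - b_only_a_unassessable)
    add(MISORIENTED, UNASSESSABLE, a_only_b_unassessable)
    add(MISORIENTED, CONCORDANT, total_a_mis - shared - a_only_b_unassessable)
    add(CONCORDANT, CONCORDANT, 2000)  # background of agreeing pairs
    return conc_a, conc_b


def test_cross_assembly_partition_reproduces_published_arithmetic():
    conc_a, conc_b = paper_partition_fixture()
    counts = cross_assembly_partition(conc_a, conc_b)
    assert counts.misoriented_b_total == 395
    assert counts.misoriented_a_total == 391
    assert counts.both_misoriented == 352
    assert counts.b_only_total == 43
    assert counts.b_only_a_unassessable == 36
    assert counts.b_only_a_concordant == 7
    assert counts.a_only_b_concordant == 21
    assert counts.a_only_b_unassessable == 18
    # partition completeness: subcategories reconcile with the totals
    assert counts.misoriented_b_total == counts.both_misoriented + counts.b_only_total
    assert counts.misoriented_a_total == counts.both_misoriented + counts.a_only_total


def test_partition_requires_matching_universes():
    conc_a, conc_b = paper_partition_fixture()
    conc_b.popitem()
    with pytest.raises(ConsistencyError):
        cross_assembly_partition(conc_a, conc_b)
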