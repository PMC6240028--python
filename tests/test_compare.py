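"""Cross-assembly read classification and its statistics."""

import math
import itertools

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hs

from finishkit.compare import (
    ProjectionRecord,
    binomial_one_tailed,
    classify_reads,
    format_p,
    split_gene_candidates,
    wilcoxon_signed_rank,
)
from finishkit.errors import InputFormatError


def write_sam(path, records, ref="chr1", ln=10_000):
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{ref}\tLN:{ln}"]
    for name, flag, pos, seq in records:
        rname, mapq, cigar = (ref, 60, f"{len(seq)}M") if not flag & 4 else ("*", 0, "*")
        pos_out = pos if not flag & 4 else 0
        lines.append(
            f"{name}\t{flag}\t{rname}\t{pos_out}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestClassifyReads:
    def test_two_by_two_counts(self, tmp_path):
        a = write_sam(
            tmp_path / "a.sam",
            [("r1", 0, 100, "ACGT"), ("r2", 0, 200, "ACGT"),
             ("r3", 4, 0, "ACGT"), ("r4", 4, 0, "ACGT")],
        )
        b = write_sam(
            tmp_path / "b.sam",
            [("r1", 0, 100, "ACGT"), ("r2", 4, 0, "ACGT"),
             ("r3", 0, 300, "ACGT"), ("r4", 4, 0, "ACGT")],
        )
        res = classify_reads(a, b)
        assert (res.both, res.a_only, res.b_only, res.neither) == (1, 1, 1, 1)
        assert res.total == 4

    def test_secondary_only_counts_as_unmapped(self, tmp_path):
        a = write_sam(
            tmp_path / "a.sam",
            [("r1", 256, 100, "ACGT"), ("r1", 4, 0, "ACGT")],  # secondary + unmapped primary
        )
        b = write_sam(tmp_path / "b.sam", [("r1", 0, 100, "ACGT")])
        res = classify_reads(a, b)
        assert (res.both, res.b_only) == (0, 1)

    def test_exclusive_set_mean_gc(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [("r1", 4, 0, "ATATATATAT"), ("r2", 4, 0, "GCGCGCGCAT")])
        b = write_sam(
            tmp_path / "b.sam",
            [("r1", 0, 100, "ATATATATAT"), ("r2", 0, 200, "GCGCGCGCAT")],
        )
        res = classify_reads(a, b)
        assert res.b_only_mean_gc == pytest.approx((0.0 + 0.8) / 2)
        assert res.a_only_mean_gc is None

    def test_duplicate_primary_rejected(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "ACGT"), ("r1", 0, 200, "ACGT")])
        b = write_sam(tmp_path / "b.sam", [("r1", 0, 100, "ACGT")])
        with pytest.raises(InputFormatError, match="duplicate"):
            classify_reads(a, b)

    def test_missing_read_counts_unmapped_with_warning(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "ACGT")])
        b = write_sam(tmp_path / "b.sam", [("r1", 0, 100, "ACGT"), ("r2", 0, 5, "ACGT")])
        with pytest.warns(UserWarning, match="one stream only"):
            res = classify_reads(a, b)
        assert (res.both, res.b_only) == (1, 1)

    def test_swapping_streams_transposes_table(self, tmp_path):
        a = write_sam(
            tmp_path / "a.sam",
            [("r1", 0, 1, "ACGT"), ("r2", 4, 0, "ACGT"), ("r3", 0, 9, "ACGT")],
        )
        b = write_sam(
            tmp_path / "b.sam",
            [("r1", 4, 0, "ACGT"), ("r2", 0, 2, "ACGT"), ("r3", 0, 7, "ACGT")],
        )
        ab, ba = classify_reads(a, b), classify_reads(b, a)
        assert (ab.a_only, ab.b_only) == (ba.b_only, ba.a_only)
        assert (ab.both, ab.neither) == (ba.both, ba.neither)


class TestSignTest:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(3, 13, 697 / 65536), (5, 5, 638 / 1024)],
    )
    def test_exact_examples(self, a, b, expected):
        assert binomial_one_tailed(a, b) == pytest.approx(expected, abs=0)

    def test_tiny_p_formatted_as_floor(self):
        assert format_p(binomial_one_tailed(0, 200)) == "< 2.2e-16"

    def test_matches_enumeration_oracle_for_all_small_tables(self):
        """Independent oracle: scipy's binomial survival function."""
        for n in range(1, 17):
            for b in range(0, n + 1):
                ours = binomial_one_tailed(n - b, b)
                oracle = st.binom.sf(b - 1, n, 0.5)
                assert ours == pytest.approx(oracle, rel=1e-12)

    def test_two_tails_overlap_exactly_at_shared_midpoint_term(self):
        """P(X >= b) + P(X >= a) = 1 + P(X = b) when a + b = n and p = 1/2."""
        for a, b in [(3, 13), (5, 5), (0, 7), (10, 2)]:
            n = a + b
            total = binomial_one_tailed(a, b) + binomial_one_tailed(b, a)
            assert total >= 1
            assert total == pytest.approx(1 + math.comb(n, b) / 2**n, rel=1e-12)

    def test_normal_regime_continuity_corrected(self):
        p = binomial_one_tailed(4000, 16001)
        z = (16001 - 20001 / 2 - 0.5) / math.sqrt(20001 / 4)
        assert p == pytest.approx(st.norm.sf(z))


class TestWilcoxon:
    def test_thirteen_uniform_improvements_normal_cc(self):
        """All 13 samples improving gives p = 0.0017 to two significant figures."""
        p = wilcoxon_signed_rank([1.0] * 13, mode="normal_cc")
        assert f"{p:.2g}" == "0.0017"
        # z = (0.5 - 45.5)/sqrt(204.75)
        assert p == pytest.approx(2 * st.norm.sf(45 / math.sqrt(204.75)), rel=1e-12)

    def test_thirteen_uniform_improvements_exact(self):
        assert wilcoxon_signed_rank([1.0] * 13, mode="exact") == pytest.approx(2 / 8192, abs=0)

    def test_two_value_enumeration(self):
        assert wilcoxon_signed_rank([2, -1], mode="exact") == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0, 0, 0])

    @given(
        hs.lists(
            hs.integers(-50, 50).filter(lambda x: x != 0), min_size=2, max_size=10
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_exact_mode_agrees_with_full_enumeration(self, diffs):
        """Oracle: brute-force enumeration over all 2^n sign assignments."""
        d = np.array(diffs, dtype=float)
        ranks = st.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        total = ranks.sum()
        hits = 0
        n = len(d)
        for signs in itertools.product([0, 1], repeat=n):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            if w_plus <= w_obs + 1e-9 or w_plus >= total - w_obs - 1e-9:
                hits += 1
        oracle = min(1.0, hits / 2**n)
        assert wilcoxon_signed_rank(diffs, mode="exact") == pytest.approx(oracle, rel=1e-12)

    def test_exact_matches_scipy_when_no_ties(self):
        for diffs in ([3, -1, 4, 2, -5], [1, 2, 3, 4, 5, -6, 7]):
            ours = wilcoxon_signed_rank(diffs, mode="exact")
            ref = st.wilcoxon(np.array(diffs, dtype=float), mode="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)


class TestSplitGenes:
    def proj(self, tid, target, start, stop):
        return ProjectionRecord(tid, target, start, stop)

    def test_near_identical_extents_on_distinct_targets_flagged(self):
        projections = [
            self.proj("T1", "contigA", 1, 500),
            self.proj("T1", "contigB", 3, 498),
            self.proj("T2", "contigA", 1, 500),
            self.proj("T3", "contigA", 10, 90),
            self.proj("T3", "contigA", 12, 88),  # same contig: not split
        ]
        assert split_gene_candidates(projections) == ["T1"]

    @pytest.mark.parametrize("delta,flagged", [(10, True), (11, False)])
    def test_tolerance_boundary(self, delta, flagged):
        projections = [
            self.proj("T", "A", 100, 600),
            self.proj("T", "B", 100 + delta, 600),
        ]
        assert (split_gene_candidates(projections, tol=10) == ["T"]) is flagged

    def test_adjacent_mode_flags_tiling_pieces(self):
        projections = [
            self.proj("T", "A", 1, 300),
            self.proj("T", "B", 305, 600),
        ]
        assert split_gene_candidates(projections, mode="extent") == []
        assert split_gene_candidates(projections, mode="adjacent") == ["T"]
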