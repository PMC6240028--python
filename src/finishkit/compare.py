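"""Cross-assembly read-mapping comparison and its statistics.

Two SAM streams over the same read universe are reduced to per-read
primary-mapping status against assemblies A and B, yielding the 2x2
mapped/unmapped table, per-assembly proper-pair totals, and GC summaries of
the exclusively-mapped read sets. The discordant counts feed an exact sign
test (reads mapping to only one assembly, under a fair-coin null), and
per-sample mapping differences feed a paired Wilcoxon signed-rank test.
A transcript-projection screen flags candidate split genes: transcripts
projected to multiple target sequences with near-identical source extents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pysam
from scipy import stats

from .errors import InputFormatError

P_FLOOR = 2.2e-16


@dataclass
class ReadMapRecord:
    read_id: str
    mapped_primary_a: bool = False
    mapped_primary_b: bool = False
    proper_pair_a: bool = False
    proper_pair_b: bool = False
    gc_fraction: float | None = None
    length: int = 0


@dataclass
class CompareResult:
    both: int = 0
    a_only: int = 0
    b_only: int = 0
    neither: int = 0
    proper_pairs_a: int = 0
    proper_pairs_b: int = 0
    a_only_mean_gc: float | None = None
    b_only_mean_gc: float | None = None
    records: dict[str, ReadMapRecord] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


def _is_proper_pair(rec: pysam.AlignedSegment) -> bool:
    """Both mates primary-mapped to the same reference in FR orientation."""
    if not rec.is_paired or rec.is_unmapped or rec.mate_is_unmapped:
        return False
    if rec.reference_id != rec.next_reference_id:
        return False
    if rec.is_reverse == rec.mate_is_reverse:
        return False
    left_pos, left_rev = (
        (rec.reference_start, rec.is_reverse)
        if rec.reference_start <= rec.next_reference_start
        else (rec.next_reference_start, rec.mate_is_reverse)
    )
    return not left_rev


def _read_primary(path: str) -> dict[str, tuple[bool, bool, float | None, int]]:
    out: dict[str, tuple[bool, bool, float | None, int]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            rid = rec.query_name
            if rec.is_paired:
                rid += "/1" if rec.is_read1 else "/2"
            if rid in out:
                raise InputFormatError(f"duplicate primary record for read {rid} in {path}")
            seq = rec.query_sequence
            gc = None
            length = 0
            if seq:
                length = len(seq)
                acgt = sum(seq.count(b) for b in "ACGT")
                if acgt:
                    gc = (seq.count("G") + seq.count("C")) / acgt
            out[rid] = (not rec.is_unmapped, _is_proper_pair(rec), gc, length)
    return out


def classify_reads(sam_a: str, sam_b: str) -> CompareResult:
    """Classify every read by primary-mapping status on assemblies A and B.

    Reads present in only one stream are counted unmapped in the other (with
    a warning); reads with only secondary/supplementary records never count
    as mapped.
    """
    prim_a = _read_primary(sam_a)
    prim_b = _read_primary(sam_b)
    only_a = set(prim_a) - set(prim_b)
    only_b = set(prim_b) - set(prim_a)
    if only_a or only_b:
        warnings.warn(
            f"{len(only_a) + len(only_b)} read ids present in one stream only; "
            "counted unmapped in the missing stream"
        )
    result = CompareResult()
    for rid in set(prim_a) | set(prim_b):
        ma, pa, gca, la = prim_a.get(rid, (False, False, None, 0))
        mb, pb, gcb, lb = prim_b.get(rid, (False, False, None, 0))
        gc = gca if gca is not None else gcb
        rec = ReadMapRecord(rid, ma, mb, pa, pb, gc, max(la, lb))
        result.records[rid] = rec
        result.proper_pairs_a += pa
        result.proper_pairs_b += pb
        if ma and mb:
            result.both += 1
        elif ma:
            result.a_only += 1
        elif mb:
            result.b_only += 1
        else:
            result.neither += 1
    a_gc = [r.gc_fraction for r in result.records.values()
            if r.mapped_primary_a and not r.mapped_primary_b and r.gc_fraction is not None]
    b_gc = [r.gc_fraction for r in result.records.values()
            if r.mapped_primary_b and not r.mapped_primary_a and r.gc_fraction is not None]
    result.a_only_mean_gc = float(np.mean(a_gc)) if a_gc else None
    result.b_only_mean_gc = float(np.mean(b_gc)) if b_gc else None
    return result


def binomial_one_tailed(a_only: int, b_only: int) -> float:
    """One-tailed sign test on discordant reads: P(X >= b_only | n, p=1/2).

    Exact for n <= 10^4 (integer arithmetic), normal approximation with
    continuity correction above. The construction treats each discordant
    read as a fair-coin trial under the null of no mapability difference.
    """
    if a_only < 0 or b_only < 0 or a_only + b_only < 1:
        raise ValueError("need at least one discordant read")
    n, b = a_only + b_only, b_only
    if n <= 10_000:
        c = math.comb(n, b)
        total = 0
        for k in range(b, n + 1):
            total += c
            c = c * (n - k) // (k + 1)
        return float(Fraction(total, 1 << n))
    z = (b - n / 2 - 0.5) / math.sqrt(n / 4)
    return float(stats.norm.sf(z))


def format_p(p: float, floor: float = P_FLOOR) -> str:
    """Render a p-value, flooring tiny values as ``< 2.2e-16``."""
    if p < floor:
        return f"< {floor:.1e}".replace("e-", "e-")
    return f"{p:.4g}"


def _signed_rank_stat(differences) -> tuple[np.ndarray, float, float]:
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    if d.size == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return ranks, w_plus, w_minus


def wilcoxon_signed_rank(differences, mode: str = "normal_cc") -> float:
    """Two-sided paired Wilcoxon signed-rank test on the differences.

    Zeros are dropped and tied magnitudes mid-ranked. ``normal_cc`` uses the
    normal approximation with a 1/2 continuity correction toward the mean
    (no tie correction in the variance); ``exact`` enumerates the null
    distribution of the positive-rank sum over all 2^n sign assignments
    (n <= 20).
    """
    ranks, w_plus, w_minus = _signed_rank_stat(differences)
    n = ranks.size
    w = min(w_plus, w_minus)
    if mode == "normal_cc":
        mu = n * (n + 1) / 4
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        if sigma == 0 or w == mu:
            return 1.0
        z = (w - mu + 0.5) / sigma  # w <= mu by construction
        return min(1.0, 2 * float(stats.norm.sf(-z)))
    if mode == "exact":
        if n > 20:
            raise ValueError("exact mode supports at most 20 nonzero differences")
        # distribution of 2*W+ (integer) by iterative convolution over ranks
        scaled = np.rint(2 * ranks).astype(int)
        total = int(scaled.sum())
        dist = np.zeros(total + 1, dtype=float)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = (dist + shifted) / 2.0
        lo = int(np.rint(2 * w))
        hi = total - lo
        p = dist[: lo + 1].sum() + dist[hi:].sum()
        return min(1.0, float(p))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ProjectionRecord:
    transcript: str
    target: str
    source_start: int
    source_stop: int

    def __post_init__(self) -> None:
        if self.source_start >= self.source_stop:
            raise InputFormatError(
                f"projection of {self.transcript}: start must precede stop"
            )


def split_gene_candidates(
    projections: list[ProjectionRecord], tol: int = 10, mode: str = "extent"
) -> list[str]:
    """Flag transcripts projected to multiple targets with near-equal extents.

    mode="extent" (default): two projections on distinct target sequences
    whose source starts differ by <= tol and source stops differ by <= tol.
    mode="adjacent": the alternative reading — one projection's source stop
    within tol of the other's source start (pieces tiling the transcript).
    """
    if mode not in ("extent", "adjacent"):
        raise ValueError(f"unknown mode {mode!r}")
    by_transcript: dict[str, list[ProjectionRecord]] = {}
    for p in projections:
        by_transcript.setdefault(p.transcript, []).append(p)
    flagged = []
    for tid, projs in by_transcript.items():
        hit = False
        for i in range(len(projs)):
            for j in range(i + 1, len(projs)):
                a, b = projs[i], projs[j]
                if a.target == b.target:
                    continue
                if mode == "extent":
                    close = (
                        abs(a.source_start - b.source_start) <= tol
                        and abs(a.source_stop - b.source_stop) <= tol
                    )
                else:
                    close = (
                        abs(a.source_stop - b.source_start) <= tol
                        or abs(b.source_stop - a.source_start) <= tol
                    )
                if close:
                    hit = True
                    break
            if hit:
                break
        if hit:
            flagged.append(tid)
    return sorted(flagged)


def read_projection_tsv(path: str) -> list[ProjectionRecord]:
    """Read projections from TSV: transcript, target, source_start, source_stop."""
    out: list[ProjectionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (
                lineno == 1 and line.startswith("transcript\t")
            ):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputFormatError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                ProjectionRecord(parts[0], parts[1], int(parts[2]), int(parts[3]))
            )
    return out


def compare_tsv(result: CompareResult) -> str:
    rows = [
        ("both", result.both),
        ("a_only", result.a_only),
        ("b_only", result.b_only),
        ("neither", result.neither),
        ("proper_pairs_a", result.proper_pairs_a),
        ("proper_pairs_b", result.proper_pairs_b),
        ("a_only_mean_gc", "." if result.a_only_mean_gc is None else f"{result.a_only_mean_gc:.6f}"),
        ("b_only_mean_gc", "." if result.b_only_mean_gc is None else f"{result.b_only_mean_gc:.6f}"),
    ]
    if result.a_only + result.b_only >= 1:
        p = binomial_one_tailed(result.a_only, result.b_only)
        rows.append(("sign_test_p_b_vs_a", format_p(p)))
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
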