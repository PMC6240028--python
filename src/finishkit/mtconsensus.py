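"""Iterative reference-guided consensus for a circular mitochondrial genome.

Reads are aligned to the current reference (circularly doubled, so reads
crossing the origin align contiguously), per-site base counts are tallied,
and each site is re-called by a coverage/agreement filter: the majority base
is accepted only with at least ``min_cov``-fold coverage and at least
``min_frac`` agreement, otherwise the site becomes N. The called consensus
seeds the next round; iteration stops at a fixed point or after ``rounds``
rounds.

The aligner is a pluggable contract ``aligner(read, reference) -> (score,
[(ref_pos, read_base | None), ...])`` so pre-computed alignments can stand in
for the built-in one. The built-in aligner is a vectorised Smith-Waterman
(match +1, mismatch -1, gap -2) over the full matrix; at the scales this
module targets the full-width dynamic program is fast and has no band- or
seed-placement failure mode. Reads are tried on both strands and the better
scoring orientation is tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assembly import reverse_complement
from .errors import AdjudicationError

DEFAULT_MIN_COV = 10
DEFAULT_MIN_FRAC = 0.90
DEFAULT_ROUNDS = 3

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
DELETION = 4  # row index for deletions in a counts matrix (A,C,G,T,del)


def consensus_call(
    counts, min_cov: int = DEFAULT_MIN_COV, min_frac: float = DEFAULT_MIN_FRAC
) -> str:
    """Call one site from (A, C, G, T, deletion) counts.

    Returns the majority base iff total coverage >= ``min_cov`` and the
    majority fraction >= ``min_frac``; otherwise N. Deletion-majority sites
    are N as well: the consensus is substitution-only. The call is
    scale-free above threshold (only the fraction matters).
    """
    counts = list(counts)
    coverage = sum(counts)
    if coverage < min_cov:
        return "N"
    best = max(range(5), key=lambda i: counts[i])
    if best == DELETION:
        return "N"
    if counts[best] / coverage < min_frac:
        return "N"
    return _BASES[best]


def smith_waterman(
    read: str, reference: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, list[tuple[int, str | None]]]:
    """Best local alignment of ``read`` against ``reference``.

    Returns the score and aligned columns as ``(ref_pos, read_base)`` pairs;
    ``read_base`` is None where the reference base is deleted in the read.
    Read insertions consume no reference position and are not reported.
    """
    m, n = len(read), len(reference)
    if m == 0 or n == 0:
        return 0, []
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    rd = np.frombuffer(read.encode(), dtype=np.uint8)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    idx = np.arange(n, dtype=np.int32)
    ge = -gap  # positive per-column gap cost for the prefix-scan trick
    for i in range(1, m + 1):
        sub = np.where(ref == rd[i - 1], match, mismatch).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        e = np.maximum(np.maximum(diag, up), 0)
        # linear horizontal gaps via running max of e[j'] - ge*(j - j')
        H[i, 1:] = np.maximum.accumulate(e + ge * idx) - ge * idx
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = int(H[i, j])
    pairs: list[tuple[int, str | None]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if read[i - 1] == reference[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            pairs.append((j - 1, read[i - 1]))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1  # insertion in the read; no reference column
        else:
            pairs.append((j - 1, None))
            j -= 1
    pairs.reverse()
    return score, pairs


def align_both_strands(read: str, reference: str):
    """Align read and its reverse complement; keep the better orientation."""
    fwd = smith_waterman(read, reference)
    rev = smith_waterman(reverse_complement(read), reference)
    return fwd if fwd[0] >= rev[0] else rev


def tally_counts(
    reads: list[str], reference: str, circular: bool = True, aligner=None
) -> np.ndarray:
    """Per-site (A,C,G,T,del) counts of all reads against ``reference``."""
    if aligner is None:
        aligner = align_both_strands
    length = len(reference)
    target = reference + reference if circular else reference
    counts = np.zeros((length, 5), dtype=np.int64)
    for read in reads:
        _, pairs = aligner(read, target)
        for ref_pos, base in pairs:
            site = ref_pos % length if circular else ref_pos
            row = DELETION if base is None else _BASE_INDEX.get(base)
            if row is not None:
                counts[site, row] += 1
    return counts


def iterate_consensus(
    reads: list[str],
    reference: str,
    rounds: int = DEFAULT_ROUNDS,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
    circular: bool = True,
    aligner=None,
) -> tuple[str, np.ndarray]:
    """Iteratively re-call the consensus from read alignments.

    Each round aligns every read to the current consensus, tallies site
    counts, applies :func:`consensus_call` per site and feeds the result to
    the next round; stops early on a fixed point. Returns the final
    consensus and its coverage track (per-site counts from the last round).
    """
    if not reads:
        warnings.warn("no reads supplied; consensus is all N")
        return "N" * len(reference), np.zeros((len(reference), 5), dtype=np.int64)
    current = reference
    counts = np.zeros((len(reference), 5), dtype=np.int64)
    for _ in range(rounds):
        counts = tally_counts(reads, current, circular=circular, aligner=aligner)
        called = "".join(
            consensus_call(counts[i], min_cov, min_frac) for i in range(len(current))
        )
        if called == current:
            break
        current = called
    return current, counts


def coverage_tsv(counts: np.ndarray) -> str:
    lines = ["position\tA\tC\tG\tT\tdel\tcoverage"]
    for i, row in enumerate(counts):
        lines.append(
            f"{i}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t{row[4]}\t{int(row.sum())}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RepeatRegion:
    """A tandem 8-mer repeat region between two unique flanking anchors."""

    left_flank: str
    right_flank: str
    unit: str
    copy_number: int

    def __post_init__(self) -> None:
        if len(self.unit) != 8:
            raise ValueError("repeat unit must be 8 bases")
        if self.unit in self.left_flank or self.unit in self.right_flank:
            raise ValueError("flanks must not contain the repeat unit")


def adjudicate_repeat_count(spanning_read: str, region: RepeatRegion) -> int:
    """Count tandem repeat copies from a read spanning both flanks.

    The read must contain each flank exactly once, left before right
    (otherwise ``ValueError``); the interior must be an integral tandem of
    the unit (otherwise :class:`AdjudicationError`). Returns the copy count.
    """
    for name, flank in (("left", region.left_flank), ("right", region.right_flank)):
        if spanning_read.count(flank) != 1:
            raise ValueError(f"{name} flank not found exactly once in read")
    left_end = spanning_read.index(region.left_flank) + len(region.left_flank)
    right_start = spanning_read.index(region.right_flank)
    if right_start < left_end:
        raise ValueError("flanks out of order in read")
    interior = spanning_read[left_end:right_start]
    n, rem = divmod(len(interior), len(region.unit))
    if rem != 0 or interior != region.unit * n:
        raise AdjudicationError(
            f"interior of length {len(interior)} is not an integral tandem of the unit"
        )
    return n
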