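"""Low-complexity masking and exact k-mer contamination screening.

Microbial reference sequences are DUST-masked (so ubiquitous low-complexity
sequence cannot cause spurious hits), decomposed into canonical 32-mers, and
assembly contigs carrying at least one exact canonical 32-mer match are
flagged as contaminants. Matching is a hash-set membership test: exact, and
strand-independent through k-mer canonicalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .assembly import (
    Assembly,
    Scaffold,
    DEFAULT_MIN_GAP,
    reverse_complement,
    segment_contigs,
)

DEFAULT_K = 32
DEFAULT_DUST_WINDOW = 64
DEFAULT_DUST_THRESHOLD = 2.0


@dataclass(frozen=True)
class MaskInterval:
    sequence: str
    start: int
    end: int


@dataclass
class KmerDB:
    """Canonical k-mer set with per-source k-mer counts."""

    k: int
    kmers: set[str] = field(default_factory=set)
    source_counts: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class ContigFlag:
    scaffold: str
    start: int
    end: int
    first_match_offset: int  # contig-relative offset of the first matching k-mer


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def dust_mask(
    sequence: str,
    name: str = "<sequence>",
    window: int = DEFAULT_DUST_WINDOW,
    threshold: float = DEFAULT_DUST_THRESHOLD,
) -> list[MaskInterval]:
    """Symmetric-DUST-style low-complexity masking.

    Every length-``window`` window (step 1; a single shorter window for short
    sequences) is scored ``S = sum_t c_t (c_t - 1) / 2 / (n_trip - 1)`` over
    its triplet counts ``c_t`` (triplets containing N are ignored); windows
    with ``S > threshold`` are masked, and overlapping masked windows are
    merged. The default threshold 2.0 approximates the common DUST level of
    20, whose scores are scaled tenfold; exactness against any particular
    masker binary is not claimed.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    seq = sequence
    n = len(seq)
    if n < 3:
        return []
    wlen = min(window, n)
    triplets = [seq[i : i + 3] for i in range(n - 2)]
    valid = ["N" not in t for t in triplets]
    counts: Counter = Counter()
    n_valid = 0
    pair_sum = 0  # sum of c*(c-1)/2 over current counts
    masked: list[list[int]] = []

    def add(i: int, sign: int) -> None:
        nonlocal n_valid, pair_sum
        if not valid[i]:
            return
        t = triplets[i]
        c = counts[t]
        pair_sum -= c * (c - 1) // 2
        counts[t] = c + sign
        c += sign
        pair_sum += c * (c - 1) // 2
        n_valid += sign

    n_trip_window = wlen - 2
    for i in range(n_trip_window):
        add(i, +1)
    for start in range(0, n - wlen + 1):
        if start > 0:
            add(start - 1, -1)
            add(start + n_trip_window - 1, +1)
        if n_valid >= 2:
            score = pair_sum / (n_valid - 1)
            if score > threshold:
                if masked and masked[-1][1] >= start:
                    masked[-1][1] = start + wlen
                else:
                    masked.append([start, start + wlen])
    return [MaskInterval(name, s, e) for s, e in masked]


def _unmasked_intervals(length: int, masks: list[MaskInterval]) -> list[tuple[int, int]]:
    out = []
    cursor = 0
    for m in sorted(masks, key=lambda m: m.start):
        if m.start > cursor:
            out.append((cursor, m.start))
        cursor = max(cursor, m.end)
    if cursor < length:
        out.append((cursor, length))
    return out


def build_kmer_db(
    sources: list[tuple[str, str]],
    masks: dict[str, list[MaskInterval]] | None = None,
    k: int = DEFAULT_K,
) -> KmerDB:
    """Collect every canonical k-mer of the sources outside masked intervals.

    ``sources`` is ``[(name, sequence), ...]``; ``masks`` maps source name to
    intervals (sources absent from the map are unmasked). k-mers containing
    N are skipped.
    """
    db = KmerDB(k=k)
    masks = masks or {}
    for name, seq in sources:
        for lo, hi in _unmasked_intervals(len(seq), masks.get(name, [])):
            segment = seq[lo:hi]
            for i in range(len(segment) - k + 1):
                kmer = segment[i : i + k]
                if "N" in kmer:
                    continue
                db.kmers.add(canonical(kmer))
                db.source_counts[name] += 1
    return db


def mask_sources(
    sources: list[tuple[str, str]],
    window: int = DEFAULT_DUST_WINDOW,
    threshold: float = DEFAULT_DUST_THRESHOLD,
) -> dict[str, list[MaskInterval]]:
    return {name: dust_mask(seq, name, window, threshold) for name, seq in sources}


def screen_contigs(
    assembly: Assembly,
    db: KmerDB,
    min_gap: int = DEFAULT_MIN_GAP,
    drop: bool = False,
) -> tuple[list[ContigFlag], Assembly]:
    """Flag contigs sharing at least one canonical k-mer with the database.

    By default a flagged contig inside a multi-contig scaffold is replaced by
    an equal-length N run (scaffold coordinates preserved) and a scaffold
    that was a single flagged contig is dropped; with ``drop=True`` flagged
    contig sequence is excised entirely. Scaffolds left without any non-N
    base are dropped in both modes.
    """
    k = db.k
    flags: list[ContigFlag] = []
    new_scaffolds: list[Scaffold] = []
    for scaf in assembly:
        contigs, _ = segment_contigs(scaf, min_gap)
        seq = bytearray(scaf.sequence, "ascii")
        cut: list[tuple[int, int]] = []
        for contig in contigs:
            segment = scaf.sequence[contig.start : contig.end]
            offset = None
            for i in range(len(segment) - k + 1):
                kmer = segment[i : i + k]
                if "N" in kmer:
                    continue
                if canonical(kmer) in db.kmers:
                    offset = i
                    break
            if offset is None:
                continue
            flags.append(ContigFlag(scaf.name, contig.start, contig.end, offset))
            if drop:
                cut.append((contig.start, contig.end))
            else:
                seq[contig.start : contig.end] = b"N" * contig.length
        if drop:
            for start, end in reversed(cut):
                del seq[start:end]
        new = seq.decode("ascii")
        if new and new.count("N") < len(new):
            new_scaffolds.append(Scaffold(scaf.name, new))
    return flags, Assembly(assembly.name, new_scaffolds)


def flags_tsv(flags: list[ContigFlag]) -> str:
    lines = ["scaffold\tcontig_start\tcontig_end\tfirst_match_offset"]
    for f in flags:
        lines.append(f"{f.scaffold}\t{f.start}\t{f.end}\t{f.first_match_offset}")
    return "\n".join(lines) + "\n"


def masks_bed(masks: dict[str, list[MaskInterval]]) -> str:
    lines = []
    for name in sorted(masks):
        for m in masks[name]:
            lines.append(f"{m.sequence}\t{m.start}\t{m.end}")
    return "\n".join(lines) + ("\n" if lines else "")
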