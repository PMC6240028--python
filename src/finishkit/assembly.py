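"""Gapped-assembly containers, contig segmentation and contiguity statistics.

An assembly is an ordered set of named scaffolds over the alphabet
``{A, C, G, T, N}``. Runs of at least ``min_gap`` Ns are treated as gaps of
known order but unsequenced content; shorter N runs stay inside contigs and
do not break contiguity. All coordinates are 0-based, half-open; 1-based
coordinates appear only at VCF boundaries.
"""

from __future__ import annotations

import io
import os
import re
import tempfile
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputFormatError

DEFAULT_MIN_GAP = 25
DEFAULT_MIN_SCAFFOLD_LENGTH = 3000

_VALID_RE = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_sequence(sequence: str, name: str = "<sequence>") -> str:
    """Upper-case ``sequence`` and reject anything outside A/C/G/T/N.

    Lower-case input is accepted and upper-cased; IUPAC ambiguity codes other
    than N are rejected with the 0-based offending position in the message.
    """
    seq = sequence.upper()
    m = _VALID_RE.search(seq)
    if m is not None:
        raise InputFormatError(
            f"invalid character {m.group()!r} at position {m.start()} in {name}"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Scaffold:
    """A named nucleotide sequence, possibly containing N gaps."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, self.name)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of uniquely named scaffolds."""

    name: str
    scaffolds: list[Scaffold] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.scaffolds]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise InputFormatError(f"duplicate scaffold name {dup!r} in {self.name}")

    def __iter__(self):
        return iter(self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def scaffold(self, name: str) -> Scaffold:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.scaffolds]

    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def copy(self, name: str | None = None) -> "Assembly":
        return Assembly(
            name if name is not None else self.name,
            [Scaffold(s.name, s.sequence) for s in self.scaffolds],
        )


@dataclass(frozen=True)
class Contig:
    """Maximal scaffold stretch free of gap-sized N runs (may hold short runs)."""

    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gap:
    """A run of >= min_gap Ns separating two contigs (or flanking one)."""

    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StatsReport:
    contig_n50: int
    scaffold_n50: int
    contig_count: int
    scaffold_count: int
    gap_count: int
    gap_bases: int
    non_n_bases: int
    gc_fraction: float
    gc_defined: bool = True


_N_RUN_RE = re.compile(r"N+")


def segment_contigs(
    scaffold: Scaffold, min_gap: int = DEFAULT_MIN_GAP
) -> tuple[list[Contig], list[Gap]]:
    """Split a scaffold into contigs and gaps.

    N runs of length >= ``min_gap`` become :class:`Gap` records; shorter runs
    are retained inside contigs, so concatenating contigs and gaps in
    coordinate order reproduces the scaffold exactly.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    seq = scaffold.sequence
    if not seq:
        return [], []
    gaps = [
        Gap(scaffold.name, m.start(), m.end())
        for m in _N_RUN_RE.finditer(seq)
        if m.end() - m.start() >= min_gap
    ]
    contigs: list[Contig] = []
    cursor = 0
    for g in gaps:
        if g.start > cursor:
            contigs.append(Contig(scaffold.name, cursor, g.start))
        cursor = g.end
    if cursor < len(seq):
        contigs.append(Contig(scaffold.name, cursor, len(seq)))
    return contigs, gaps


def n50(lengths) -> int:
    """Largest L such that pieces of length >= L hold at least half the total.

    When half the total is reached exactly at a piece boundary, the piece
    reaching the threshold defines N50 (``>=`` comparison).
    """
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length collection is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("all lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in lengths:
        acc += l
        if 2 * acc >= total:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_stats(assembly: Assembly, min_gap: int = DEFAULT_MIN_GAP) -> StatsReport:
    """Contiguity and composition summary of an assembly.

    Scaffold lengths include internal Ns; gap counts cover threshold gaps
    only; GC is the fraction of non-N bases that are G or C (reported as 0
    with ``gc_defined=False`` when there are no non-N bases).
    """
    contig_lengths: list[int] = []
    scaffold_lengths: list[int] = []
    gap_count = gap_bases = 0
    gc = non_n = 0
    for scaf in assembly:
        scaffold_lengths.append(len(scaf))
        contigs, gaps = segment_contigs(scaf, min_gap)
        contig_lengths.extend(c.length for c in contigs)
        gap_count += len(gaps)
        gap_bases += sum(g.length for g in gaps)
        seq = scaf.sequence
        non_n += len(seq) - seq.count("N")
        gc += seq.count("G") + seq.count("C")
    return StatsReport(
        contig_n50=n50(contig_lengths) if contig_lengths else 0,
        scaffold_n50=n50([l for l in scaffold_lengths if l > 0])
        if any(scaffold_lengths)
        else 0,
        contig_count=len(contig_lengths),
        scaffold_count=len(scaffold_lengths),
        gap_count=gap_count,
        gap_bases=gap_bases,
        non_n_bases=non_n,
        gc_fraction=gc / non_n if non_n else 0.0,
        gc_defined=non_n > 0,
    )


def filter_small_scaffolds(
    assembly: Assembly, min_len: int = DEFAULT_MIN_SCAFFOLD_LENGTH
) -> tuple[Assembly, list[tuple[str, int]]]:
    """Drop scaffolds strictly shorter than ``min_len`` bases.

    Returns the filtered assembly (input order preserved) and a report of
    ``(name, length)`` for each removed scaffold. A scaffold of exactly
    ``min_len`` bases is retained.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept, removed = [], []
    for s in assembly:
        if len(s) < min_len:
            removed.append((s.name, len(s)))
        else:
            kept.append(Scaffold(s.name, s.sequence))
    return Assembly(assembly.name, kept), removed


# ---------------------------------------------------------------------------
# FASTA and report I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str, name: str | None = None) -> Assembly:
    """Read a (multi-line) FASTA file into an :class:`Assembly`."""
    if not os.path.exists(path):
        raise InputFormatError(f"no such file: {path}")
    scaffolds = [
        Scaffold(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    return Assembly(name or os.path.basename(path), scaffolds)


def write_fasta(assembly: Assembly, path: str) -> None:
    """Write an assembly as FASTA wrapped at 60 columns, atomically."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description="") for s in assembly
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    write_text_atomic(path, buf.getvalue())


def write_text_atomic(path: str, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in the same dir."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".finishkit-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def stats_tsv(report: StatsReport) -> str:
    """One-row TSV rendering of a :class:`StatsReport` with a header line."""
    fields = [
        "contig_n50",
        "scaffold_n50",
        "contig_count",
        "scaffold_count",
        "gap_count",
        "gap_bases",
        "non_n_bases",
        "gc_fraction",
        "gc_defined",
    ]
    values = [getattr(report, f) for f in fields]
    values = [f"{v:.6f}" if isinstance(v, float) else str(v) for v in values]
    return "\t".join(fields) + "\n" + "\t".join(values) + "\n"
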