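"""Physical-map marker placement, scaffold anchoring and order concordance.

STS markers from a radiation-hybrid (RH) map are located on an assembly by
exact matching of their primer pairs: a marker is placed only when both
primers occur exactly once genome-wide, on one scaffold, facing inward, with
an amplicon no longer than ``max_amplicon``. Placed markers drive chromosome
assignment (majority vote per scaffold, ordering by median map position,
orientation by rank correlation) and a per-chromosome concordance analysis
of map-adjacent marker pairs, including the cross-assembly partition of
misoriented pairs.

Pair orientation is strand-aware: a placed amplicon has a strand, and a
map-adjacent pair is concordant when the two markers share a strand and
their assembly order matches the map order under that strand (both reversed
is a locally consistent, inverted placement). A planted inversion therefore
flags exactly its two boundary pairs, the signature used to diagnose
misassemblies against the map.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .assembly import Assembly, reverse_complement, validate_sequence
from .errors import ConsistencyError, InputFormatError

DEFAULT_MAX_AMPLICON = 1000

PLACED = "placed"
MISSING_PRIMER = "missing_primer"
NON_UNIQUE = "non_unique"
BAD_ORIENTATION = "bad_orientation"
OVERSIZED = "oversized"

CONCORDANT = "concordant"
MISORIENTED = "misoriented"
UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class Marker:
    """An STS marker: a primer pair with a map chromosome and position."""

    id: str
    map_chromosome: str
    map_position: float
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        for p in (self.fwd_primer, self.rev_primer):
            if not p or set(p) - set("ACGT"):
                raise InputFormatError(f"marker {self.id}: invalid primer {p!r}")


@dataclass
class MarkerHit:
    marker_id: str
    status: str
    scaffold: str | None = None
    amplicon_start: int | None = None  # 0-based half-open
    amplicon_end: int | None = None
    strand: str | None = None

    @property
    def placed(self) -> bool:
        return self.status == PLACED

    @property
    def amplicon_length(self) -> int | None:
        if not self.placed:
            return None
        return self.amplicon_end - self.amplicon_start

    @property
    def position(self) -> float | None:
        """Amplicon midpoint on the scaffold."""
        if not self.placed:
            return None
        return (self.amplicon_start + self.amplicon_end) / 2


@dataclass
class ScaffoldAssignment:
    scaffold: str
    chromosome: str | None
    order: int | None
    orientation: str | None
    n_markers: int
    tie: bool = False
    orientation_flagged: bool = False


@dataclass
class PartitionCounts:
    """Cross-assembly partition of misoriented map-adjacent marker pairs."""

    both_misoriented: int = 0
    b_only_a_concordant: int = 0
    b_only_a_unassessable: int = 0
    a_only_b_concordant: int = 0
    a_only_b_unassessable: int = 0

    @property
    def misoriented_a_total(self) -> int:
        return self.both_misoriented + self.a_only_b_concordant + self.a_only_b_unassessable

    @property
    def misoriented_b_total(self) -> int:
        return self.both_misoriented + self.b_only_a_concordant + self.b_only_a_unassessable

    @property
    def b_only_total(self) -> int:
        return self.b_only_a_concordant + self.b_only_a_unassessable

    @property
    def a_only_total(self) -> int:
        return self.a_only_b_concordant + self.a_only_b_unassessable


def _occurrences(assembly: Assembly, pattern: str) -> list[tuple[str, int, int, str]]:
    """Exact occurrences of ``pattern`` on both strands, as (scaffold, start, end, strand)."""
    hits = []
    rc = reverse_complement(pattern)
    for scaf in assembly:
        seq = scaf.sequence
        for probe, strand in ((pattern, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append((scaf.name, start, start + len(probe), strand))
                start = seq.find(probe, start + 1)
    if pattern == rc:  # palindromic primer: both strand probes find the same loci
        hits = sorted(set((s, a, b, "+") for s, a, b, _ in hits))
    return hits


def place_marker(
    marker: Marker, assembly: Assembly, max_amplicon: int = DEFAULT_MAX_AMPLICON
) -> MarkerHit:
    """Place one marker by exact primer-pair matching.

    Placed iff each primer occurs exactly once genome-wide (either strand),
    both on one scaffold, facing inward, with amplicon span <= max_amplicon.
    Failures are statuses on the returned hit, never exceptions.
    """
    occ_f = _occurrences(assembly, marker.fwd_primer)
    occ_r = _occurrences(assembly, marker.rev_primer)
    if not occ_f or not occ_r:
        return MarkerHit(marker.id, MISSING_PRIMER)
    if len(occ_f) > 1 or len(occ_r) > 1:
        return MarkerHit(marker.id, NON_UNIQUE)
    (fs_scaf, fs, fe, f_strand), (rs_scaf, rs, re_, r_strand) = occ_f[0], occ_r[0]
    if fs_scaf != rs_scaf:
        return MarkerHit(marker.id, BAD_ORIENTATION)
    if f_strand == "+" and r_strand == "-" and fs < re_:
        start, end, strand = fs, re_, "+"
    elif f_strand == "-" and r_strand == "+" and rs < fe:
        start, end, strand = rs, fe, "-"
    else:
        return MarkerHit(marker.id, BAD_ORIENTATION)
    if end - start > max_amplicon:
        return MarkerHit(marker.id, OVERSIZED)
    return MarkerHit(marker.id, PLACED, fs_scaf, start, end, strand)


def place_all(
    markers: list[Marker], assembly: Assembly, max_amplicon: int = DEFAULT_MAX_AMPLICON
) -> dict[str, MarkerHit]:
    return {m.id: place_marker(m, assembly, max_amplicon) for m in markers}


def map_order(markers: list[Marker]) -> list[Marker]:
    """Markers sorted by (chromosome, map position, id); id breaks ties."""
    return sorted(markers, key=lambda m: (m.map_chromosome, m.map_position, m.id))


def assign_scaffolds(
    hits: dict[str, MarkerHit], markers: list[Marker]
) -> list[ScaffoldAssignment]:
    """Assign scaffolds to chromosomes from their placed markers.

    Majority chromosome wins (tie -> unassigned, flagged); scaffolds are
    ordered along each chromosome by the median map position of their
    markers; orientation is the sign of the Spearman rank correlation
    between map position and scaffold coordinate ('+' when zero/undefined,
    flagged).
    """
    by_marker = {m.id: m for m in markers}
    per_scaffold: dict[str, list[MarkerHit]] = {}
    for hit in hits.values():
        if hit.placed:
            per_scaffold.setdefault(hit.scaffold, []).append(hit)
    if not per_scaffold:
        raise ValueError("no placed markers to assign from")

    assignments: list[ScaffoldAssignment] = []
    for scaffold, scaf_hits in per_scaffold.items():
        chroms = Counter(by_marker[h.marker_id].map_chromosome for h in scaf_hits)
        (top, top_n), *rest = chroms.most_common()
        if rest and rest[0][1] == top_n:
            assignments.append(
                ScaffoldAssignment(scaffold, None, None, None, len(scaf_hits), tie=True)
            )
            continue
        on_chrom = [
            h for h in scaf_hits if by_marker[h.marker_id].map_chromosome == top
        ]
        map_pos = [by_marker[h.marker_id].map_position for h in on_chrom]
        coords = [h.position for h in on_chrom]
        orientation, flagged = "+", False
        if len(on_chrom) >= 2 and len(set(map_pos)) > 1 and len(set(coords)) > 1:
            rho = stats.spearmanr(map_pos, coords).statistic
            if rho < 0:
                orientation = "-"
            elif not rho > 0:  # zero or NaN
                flagged = True
        else:
            flagged = True
        assignments.append(
            ScaffoldAssignment(
                scaffold,
                top,
                order=None,
                orientation=orientation,
                n_markers=len(scaf_hits),
                orientation_flagged=flagged,
            )
        )
    # order along each chromosome by median map position (ties by name)
    import statistics as _st

    def median_map(a: ScaffoldAssignment) -> float:
        vals = [
            by_marker[h.marker_id].map_position
            for h in per_scaffold[a.scaffold]
            if by_marker[h.marker_id].map_chromosome == a.chromosome
        ]
        return _st.median(vals)

    for chrom in sorted({a.chromosome for a in assignments if a.chromosome}):
        group = sorted(
            (a for a in assignments if a.chromosome == chrom),
            key=lambda a: (median_map(a), a.scaffold),
        )
        for i, a in enumerate(group):
            a.order = i
    return assignments


def pair_concordance(
    markers: list[Marker],
    hits: dict[str, MarkerHit],
    assignments: list[ScaffoldAssignment] | None = None,
) -> dict[tuple[str, str], str]:
    """Classify each map-adjacent marker pair on one or more chromosomes.

    A marker is assessable when placed on a scaffold assigned to its map
    chromosome. For an assessable pair, scaffold orientation is applied
    (flipping both coordinate order and amplicon strand on '-' scaffolds);
    the pair is concordant iff both markers then share a strand and their
    assembly order matches the map order under that strand, misoriented
    otherwise, and unassessable when either marker cannot be assessed.
    """
    if assignments is None:
        assignments = assign_scaffolds(hits, markers)
    assign_by_scaffold = {a.scaffold: a for a in assignments}
    scaffold_rank = {a.scaffold: a.order for a in assignments}

    def global_placement(m: Marker):
        hit = hits.get(m.id)
        if hit is None or not hit.placed:
            return None
        a = assign_by_scaffold.get(hit.scaffold)
        if a is None or a.chromosome != m.map_chromosome:
            return None
        if a.orientation == "-":
            coord = -hit.position
            strand = "-" if hit.strand == "+" else "+"
        else:
            coord = hit.position
            strand = hit.strand
        return (scaffold_rank[hit.scaffold], coord), strand

    result: dict[tuple[str, str], str] = {}
    ordered = map_order(markers)
    for m1, m2 in zip(ordered, ordered[1:]):
        if m1.map_chromosome != m2.map_chromosome:
            continue
        key = (m1.id, m2.id)
        p1, p2 = global_placement(m1), global_placement(m2)
        if p1 is None or p2 is None:
            result[key] = UNASSESSABLE
            continue
        (k1, s1), (k2, s2) = p1, p2
        if s1 == s2 and ((k1 < k2) if s1 == "+" else (k2 < k1)):
            result[key] = CONCORDANT
        else:
            result[key] = MISORIENTED
    return result


def cross_assembly_partition(
    conc_a: dict[tuple[str, str], str], conc_b: dict[tuple[str, str], str]
) -> PartitionCounts:
    """Partition misoriented pairs by their status on the other assembly.

    Both inputs must cover the same marker-pair universe. The per-assembly
    misoriented totals always reconcile with the sums of their
    sub-categories (disjoint by construction).
    """
    if set(conc_a) != set(conc_b):
        raise ConsistencyError("concordance collections cover different pair universes")
    counts = PartitionCounts()
    for pair, a in conc_a.items():
        b = conc_b[pair]
        if a == MISORIENTED and b == MISORIENTED:
            counts.both_misoriented += 1
        elif b == MISORIENTED and a == CONCORDANT:
            counts.b_only_a_concordant += 1
        elif b == MISORIENTED and a == UNASSESSABLE:
            counts.b_only_a_unassessable += 1
        elif a == MISORIENTED and b == CONCORDANT:
            counts.a_only_b_concordant += 1
        elif a == MISORIENTED and b == UNASSESSABLE:
            counts.a_only_b_unassessable += 1
    return counts


# ---------------------------------------------------------------------------
# Marker TSV I/O
# ---------------------------------------------------------------------------

def read_marker_tsv(path: str) -> list[Marker]:
    """Read markers from TSV: id, chromosome, map position, fwd, rev primer."""
    markers: list[Marker] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("id\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise InputFormatError(f"{path}:{lineno}: expected 5 columns")
            mid, chrom, pos, fwd, rev = parts
            markers.append(
                Marker(mid, chrom, float(pos),
                       validate_sequence(fwd, mid), validate_sequence(rev, mid))
            )
    return markers


def placements_tsv(hits: dict[str, MarkerHit]) -> str:
    lines = ["marker\tstatus\tscaffold\tstart\tend\tstrand"]
    for mid in sorted(hits):
        h = hits[mid]
        lines.append(
            f"{mid}\t{h.status}\t{h.scaffold or '.'}\t"
            f"{h.amplicon_start if h.placed else '.'}\t"
            f"{h.amplicon_end if h.placed else '.'}\t{h.strand or '.'}"
        )
    return "\n".join(lines) + "\n"


def assignments_tsv(assignments: list[ScaffoldAssignment]) -> str:
    lines = ["scaffold\tchromosome\torder\torientation\tn_markers\tflags"]
    for a in assignments:
        flags = ",".join(
            f for f, on in (("tie", a.tie), ("orientation", a.orientation_flagged)) if on
        ) or "."
        lines.append(
            f"{a.scaffold}\t{a.chromosome or '.'}\t"
            f"{a.order if a.order is not None else '.'}\t{a.orientation or '.'}\t"
            f"{a.n_markers}\t{flags}"
        )
    return "\n".join(lines) + "\n"


def concordance_tsv(conc: dict[tuple[str, str], str]) -> str:
    lines = ["marker_1\tmarker_2\tcategory"]
    for (m1, m2), cat in sorted(conc.items()):
        lines.append(f"{m1}\t{m2}\t{cat}")
    return "\n".join(lines) + "\n"
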