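"""Seeded synthetic-data generators with exact ground truth.

Every input the pipeline consumes can be generated here at desk scale: a
diploid genome with gapped scaffolds, heterozygous sites grouped into phase
blocks (one haplotype designated population-major), planted single-base
reference errors, a genotyped cohort sharing allele frequencies with the
focal animal, STS markers with unique primer pairs (plus a copy of the
assembly carrying one inversion spanning a known marker run), microbial
reference sequences with injected contaminant contigs, a circular
mitochondrial genome containing a tandem 8-mer repeat, and error-bearing
shotgun reads. All planted features are recorded with exact coordinates in
a :class:`TruthBundle`; regeneration under the same (config, seed) is
byte-identical.

Each generator stage draws from its own RNG stream derived from
``(master seed, stage name)`` so stages can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .assembly import Assembly, Scaffold, reverse_complement
from .errors import ConfigError
from .haploidize import PhaseBlock, PhasedSite
from .mtconsensus import RepeatRegion
from .rhmap import Marker

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for one generator stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass
class SimConfig:
    """Study conditions for the synthetic truth.

    Defaults give a three-scaffold 60 kb genome with ~1 heterozygous SNV per
    kb grouped into 2-8-site phase blocks, two >=25 N gaps per scaffold, 20
    planted reference errors plus 5 cohort-blocked look-alikes per scaffold,
    twelve
    markers with 50-500 bp amplicons on the first scaffold, one inversion
    spanning markers 5-8, three 500 bp contaminant contigs drawn from three
    5 kb microbial references, and a 600 bp circular mitochondrial genome
    with four copies of an 8-mer repeat — a cohort of four animals carrying
    the major haplotype at frequency 0.9 with 5% missing genotypes.
    """

    n_scaffolds: int = 3
    scaffold_length: int = 20_000
    variant_density: float = 1e-3  # het SNVs per bp (exact count per scaffold)
    block_sites_min: int = 2
    block_sites_max: int = 8
    gaps_per_scaffold: int = 2
    gap_length_min: int = 25
    gap_length_max: int = 200
    n_reference_errors: int = 20
    n_blocked_errors: int = 5  # error-like sites the cohort vetoes
    n_markers: int = 12
    primer_length: int = 20
    amplicon_min: int = 50
    amplicon_max: int = 500
    inversion_marker_span: tuple[int, int] | None = (5, 8)  # 1-based marker indices
    n_microbial_refs: int = 3
    microbial_length: int = 5_000
    n_contaminants: int = 3
    contaminant_length: int = 500
    mito_length: int = 600
    mito_repeat_copies: int = 4
    mito_start_differences: int = 5  # substitutions between truth and starting ref
    cohort_size: int = 4
    major_freq: float = 0.9
    missing_rate: float = 0.05


@dataclass(frozen=True)
class HetSite:
    scaffold: str
    position: int  # 1-based
    hap1: str
    hap2: str
    ref_choice: str  # the arbitrary pseudo-haploid allele currently in the reference
    block_id: int
    major_hap: int  # 1 or 2


@dataclass(frozen=True)
class PlantedError:
    scaffold: str
    position: int  # 1-based
    true_base: str
    error_base: str
    cohort_blocks: bool  # True when the cohort carries the reference (error) allele


@dataclass
class TruthBundle:
    config: SimConfig
    seed: int
    assembly: Assembly  # pseudo-haploid reference with gaps + planted errors
    haplotypes: dict[str, tuple[str, str]]  # scaffold -> (hap1, hap2), no errors
    het_sites: list[HetSite]
    blocks: list[PhaseBlock]
    block_major: dict[str, int]  # block id -> major hap (1 or 2)
    errors: list[PlantedError]
    markers: list[Marker]
    marker_truth: dict[str, tuple[str, int, int, str]]  # id -> scaffold,start,end,strand
    inverted_assembly: Assembly | None
    inversion: tuple[str, int, int] | None  # scaffold, 0-based half-open interval
    inversion_boundary_pairs: list[tuple[str, str]]
    microbial_refs: list[tuple[str, str]]
    screen_assembly: Assembly  # reference + injected contaminant scaffolds
    contaminant_names: list[str]
    mito_truth: str
    mito_start_ref: str
    mito_repeat: RepeatRegion
    mito_spanning_read: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_truth(config: SimConfig | None = None, seed: int = 0) -> TruthBundle:
    """Generate the full ground-truth bundle for one (config, seed)."""
    config = config or SimConfig()
    _validate_config(config)
    genome = _simulate_genome(config, seed)
    markers = _simulate_markers(config, seed, genome)
    contam = _simulate_contaminants(config, seed, genome["assembly"])
    mito = _simulate_mito(config, seed)
    return TruthBundle(
        config=config,
        seed=seed,
        assembly=genome["assembly"],
        haplotypes=genome["haplotypes"],
        het_sites=genome["het_sites"],
        blocks=genome["blocks"],
        block_major=genome["block_major"],
        errors=genome["errors"],
        markers=markers["markers"],
        marker_truth=markers["truth"],
        inverted_assembly=markers["inverted_assembly"],
        inversion=markers["inversion"],
        inversion_boundary_pairs=markers["boundary_pairs"],
        microbial_refs=contam["refs"],
        screen_assembly=contam["screen_assembly"],
        contaminant_names=contam["names"],
        mito_truth=mito["truth"],
        mito_start_ref=mito["start_ref"],
        mito_repeat=mito["repeat"],
        mito_spanning_read=mito["spanning_read"],
    )


def _validate_config(c: SimConfig) -> None:
    if c.gap_length_min < 25:
        raise ConfigError("gap lengths below 25 would not register as gaps")
    if c.amplicon_max + 2 * c.primer_length > c.scaffold_length // 2:
        raise ConfigError("marker amplicons do not fit on a scaffold")
    if c.amplicon_min < 2 * c.primer_length:
        raise ConfigError("amplicon must be at least as long as both primers")
    if not 0 <= c.major_freq <= 1 or not 0 <= c.missing_rate <= 1:
        raise ConfigError("major_freq and missing_rate must lie in [0, 1]")
    if c.mito_length < 100:
        raise ConfigError("mitochondrial genome too short to simulate")
    if c.inversion_marker_span is not None:
        lo, hi = c.inversion_marker_span
        if not (1 < lo <= hi < c.n_markers):
            raise ConfigError("inversion must span interior markers only")


def _simulate_genome(c: SimConfig, seed: int) -> dict:
    rng = stage_rng(seed, "genome")
    scaffolds: list[Scaffold] = []
    haplotypes: dict[str, tuple[str, str]] = {}
    het_sites: list[HetSite] = []
    errors: list[PlantedError] = []
    blocks: list[PhaseBlock] = []
    block_major: dict[str, int] = {}
    block_counter = 0
    for s in range(c.n_scaffolds):
        name = f"scaffold_{s + 1}"
        seq = np.frombuffer(_random_seq(rng, c.scaffold_length).encode(), dtype=np.uint8).copy()
        # gaps: non-overlapping N runs, kept away from the scaffold ends
        gap_zones: list[tuple[int, int]] = []
        attempts = 0
        while len(gap_zones) < c.gaps_per_scaffold:
            attempts += 1
            if attempts > 1000:
                raise ConfigError("could not place gaps without overlap")
            glen = int(rng.integers(c.gap_length_min, c.gap_length_max + 1))
            start = int(rng.integers(100, c.scaffold_length - glen - 100))
            if all(start + glen + 2 < a or start > b + 2 for a, b in gap_zones):
                gap_zones.append((start, start + glen))
        for a, b in gap_zones:
            seq[a:b] = ord("N")
        # candidate positions for variants/errors: non-N with a 2 bp margin
        is_n = seq == ord("N")
        near_n = np.convolve(is_n.astype(int), np.ones(5, dtype=int), mode="same") > 0
        candidates = np.flatnonzero(~near_n)
        candidates = candidates[(candidates > 50) & (candidates < c.scaffold_length - 50)]
        n_het = round(c.variant_density * c.scaffold_length)
        n_need = n_het + c.n_reference_errors + c.n_blocked_errors
        if len(candidates) < n_need * 3:
            raise ConfigError("not enough gap-free sequence for requested variants")
        chosen = np.sort(rng.choice(candidates, size=n_need, replace=False))
        rng.shuffle(chosen)
        het_pos = np.sort(chosen[:n_het])
        err_pos = chosen[n_het:]
        hap1 = seq.copy()
        hap2 = seq.copy()
        ref = seq.copy()
        # heterozygous sites grouped into phase blocks of consecutive sites
        i = 0
        scaffold_sites: list[HetSite] = []
        while i < len(het_pos):
            size = int(rng.integers(c.block_sites_min, c.block_sites_max + 1))
            members = het_pos[i : i + size]
            i += size
            block_counter += 1
            major = int(rng.integers(1, 3))
            bsites = []
            for p in members:
                base = chr(seq[p])
                alt = _other_base(rng, base)
                hap2[p] = ord(alt)
                ref_allele = base if rng.random() < 0.5 else alt
                ref[p] = ord(ref_allele)
                site = HetSite(name, int(p) + 1, base, alt, ref_allele, block_counter, major)
                scaffold_sites.append(site)
                bsites.append(PhasedSite(name, int(p) + 1, base, alt, ref_allele))
            blocks.append(PhaseBlock(str(block_counter), name, bsites))
            block_major[str(block_counter)] = major
        het_sites.extend(scaffold_sites)
        # planted reference errors: reference differs from both haplotypes
        per_scaffold_errors = np.sort(err_pos)
        for k, p in enumerate(per_scaffold_errors):
            true = chr(seq[p])
            wrong = _other_base(rng, true)
            ref[p] = ord(wrong)
            errors.append(
                PlantedError(name, int(p) + 1, true, wrong, cohort_blocks=k >= c.n_reference_errors)
            )
        haplotypes[name] = (hap1.tobytes().decode(), hap2.tobytes().decode())
        scaffolds.append(Scaffold(name, ref.tobytes().decode()))
    return {
        "assembly": Assembly("synthetic_reference", scaffolds),
        "haplotypes": haplotypes,
        "het_sites": het_sites,
        "blocks": blocks,
        "block_major": block_major,
        "errors": errors,
    }


def _count_occurrences(assembly: Assembly, pattern: str) -> int:
    rc = reverse_complement(pattern)
    n = 0
    for scaf in assembly:
        n += scaf.sequence.count(pattern)
        if rc != pattern:
            n += scaf.sequence.count(rc)
    return n


def _simulate_markers(c: SimConfig, seed: int, genome: dict) -> dict:
    rng = stage_rng(seed, "markers")
    assembly: Assembly = genome["assembly"]
    scaf = assembly.scaffolds[0]  # the map chromosome under study
    seq = scaf.sequence
    occupied_hi = 200
    markers: list[Marker] = []
    truth: dict[str, tuple[str, int, int, str]] = {}
    span_needed = (c.amplicon_max + 300) * c.n_markers + 400
    if span_needed > len(seq):
        raise ConfigError("scaffold too short for the requested marker count")
    attempts = 0
    while len(markers) < c.n_markers:
        attempts += 1
        if attempts > 200 * c.n_markers:
            raise ConfigError("could not place unique marker primer pairs")
        alen = int(rng.integers(c.amplicon_min, c.amplicon_max + 1))
        start = occupied_hi + int(rng.integers(50, 150))
        end = start + alen
        if end > len(seq) - 100:
            raise ConfigError("ran out of scaffold while placing markers")
        window = seq[start:end]
        if "N" in window:
            occupied_hi = end
            continue
        fwd = window[: c.primer_length]
        rev = reverse_complement(window[-c.primer_length:])
        if _count_occurrences(assembly, fwd) != 1 or _count_occurrences(assembly, rev) != 1:
            occupied_hi = end
            continue
        mid = f"M{len(markers) + 1:03d}"
        markers.append(Marker(mid, "chr1", float(len(markers) + 1) * 10.0, fwd, rev))
        truth[mid] = (scaf.name, start, end, "+")
        occupied_hi = end
    inverted_assembly = None
    inversion = None
    boundary_pairs: list[tuple[str, str]] = []
    if c.inversion_marker_span is not None:
        lo, hi = c.inversion_marker_span  # 1-based marker indices
        left_end = truth[markers[lo - 2].id][2]
        left_start = truth[markers[lo - 1].id][1]
        right_end = truth[markers[hi - 1].id][2]
        right_start = truth[markers[hi].id][1]
        inv_a = (left_end + left_start) // 2
        inv_b = (right_end + right_start) // 2
        inv_seq = seq[:inv_a] + reverse_complement(seq[inv_a:inv_b]) + seq[inv_b:]
        inv_scaffolds = [
            Scaffold(s.name, inv_seq if s.name == scaf.name else s.sequence)
            for s in assembly
        ]
        inverted_assembly = Assembly("synthetic_inverted", inv_scaffolds)
        inversion = (scaf.name, inv_a, inv_b)
        boundary_pairs = [
            (markers[lo - 2].id, markers[lo - 1].id),
            (markers[hi - 1].id, markers[hi].id),
        ]
    return {
        "markers": markers,
        "truth": truth,
        "inverted_assembly": inverted_assembly,
        "inversion": inversion,
        "boundary_pairs": boundary_pairs,
    }


def _simulate_contaminants(c: SimConfig, seed: int, assembly: Assembly) -> dict:
    rng = stage_rng(seed, "contaminants")
    refs = [
        (f"microbe_{i + 1}", _random_seq(rng, c.microbial_length))
        for i in range(c.n_microbial_refs)
    ]
    scaffolds = [Scaffold(s.name, s.sequence) for s in assembly]
    names = []
    for i in range(c.n_contaminants):
        _, src = refs[i % len(refs)]
        start = int(rng.integers(0, len(src) - c.contaminant_length))
        name = f"contam_{i + 1}"
        scaffolds.append(Scaffold(name, src[start : start + c.contaminant_length]))
        names.append(name)
    return {
        "refs": refs,
        "screen_assembly": Assembly("synthetic_screen", scaffolds),
        "names": names,
    }


def _simulate_mito(c: SimConfig, seed: int) -> dict:
    rng = stage_rng(seed, "mito")
    unit_len = 8
    flank_len = 30
    attempts = 0
    while True:
        attempts += 1
        if attempts > 1000:
            raise ConfigError("could not build a clean mitochondrial repeat region")
        backbone = _random_seq(rng, c.mito_length - unit_len * c.mito_repeat_copies)
        unit = _random_seq(rng, unit_len)
        insert_at = len(backbone) // 2
        left = backbone[insert_at - flank_len : insert_at]
        right = backbone[insert_at : insert_at + flank_len]
        truth = (
            backbone[:insert_at] + unit * c.mito_repeat_copies + backbone[insert_at:]
        )
        # flanks must anchor uniquely and must not contain the unit
        if truth.count(left) != 1 or truth.count(right) != 1:
            continue
        if unit in left or unit in right:
            continue
        break
    repeat = RepeatRegion(left, right, unit, c.mito_repeat_copies)
    start_ref = list(truth)
    diff_pos = rng.choice(
        np.r_[0:insert_at - flank_len, insert_at + unit_len * c.mito_repeat_copies + flank_len : len(truth)],
        size=c.mito_start_differences,
        replace=False,
    )
    for p in diff_pos:
        start_ref[p] = _other_base(rng, start_ref[p])
    span_start = insert_at - flank_len
    span_end = insert_at + unit_len * c.mito_repeat_copies + flank_len
    return {
        "truth": truth,
        "start_ref": "".join(start_ref),
        "repeat": repeat,
        "spanning_read": truth[span_start:span_end],
    }


# ---------------------------------------------------------------------------
# Cohort VCF
# ---------------------------------------------------------------------------

def simulate_cohort(
    truth: TruthBundle,
    n_animals: int | None = None,
    major_freq: float | None = None,
    missing_rate: float | None = None,
    seed: int | None = None,
    focal_name: str = "focal",
) -> str:
    """Render a multi-sample VCF (text) for the focal animal plus cohort.

    Heterozygous truth sites appear with the focal genotype phased (``a|b``
    with a PS tag naming the phase block); each cohort allele is the major
    haplotype's allele with probability ``major_freq`` and missing with
    probability ``missing_rate``. Planted reference errors appear as focal
    homozygous-ALT sites whose cohort is homozygous for the true base —
    except the cohort-blocked ones, where one cohort animal carries the
    reference (error) allele.
    """
    c = truth.config
    n_animals = c.cohort_size if n_animals is None else n_animals
    major_freq = c.major_freq if major_freq is None else major_freq
    missing_rate = c.missing_rate if missing_rate is None else missing_rate
    rng = stage_rng(truth.seed if seed is None else seed, "cohort")
    animals = [f"cohort_{i + 1}" for i in range(n_animals)]

    rows = []
    for site in truth.het_sites:
        ref = site.ref_choice
        alt = site.hap2 if ref == site.hap1 else site.hap1
        alleles = {ref: "0", alt: "1"}
        major_allele = site.hap1 if site.major_hap == 1 else site.hap2
        minor_allele = site.hap2 if site.major_hap == 1 else site.hap1
        focal_gt = f"{alleles[site.hap1]}|{alleles[site.hap2]}:{site.block_id}"
        gts = [focal_gt]
        for _ in animals:
            if rng.random() < missing_rate:
                gts.append("./.:.")
                continue
            pair = [
                major_allele if rng.random() < major_freq else minor_allele
                for _ in range(2)
            ]
            gts.append(f"{alleles[pair[0]]}/{alleles[pair[1]]}:{site.block_id}")
        rows.append((site.scaffold, site.position, ref, alt, gts))
    for err in truth.errors:
        gts = [f"1/1:."]
        for k in range(n_animals):
            if err.cohort_blocks and k == 0:
                gts.append("0/1:.")  # this animal carries the reference allele
            else:
                gts.append("1/1:.")
        rows.append((err.scaffold, err.position, err.error_base, err.true_base, gts))

    rows.sort(key=lambda r: (r[0], r[1]))
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
    ]
    for scaf in truth.assembly:
        lines.append(f"##contig=<ID={scaf.name},length={len(scaf)}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join([focal_name] + animals)
    )
    for chrom, pos, ref, alt, gts in rows:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:PS\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    sequence: str,
    coverage: float,
    error_rate: float,
    read_len: int,
    seed: int = 0,
    circular: bool = False,
    both_strands: bool = True,
    stage: str = "reads",
) -> list[tuple[str, str, int, str]]:
    """Uniform shotgun reads as ``(name, read_seq, true_start, strand)``.

    Read count is ``round(coverage * len(sequence) / read_len)``;
    substitution errors are i.i.d. at ``error_rate``; circular mode lets
    reads wrap the origin. ``true_start`` is the 0-based position of the
    read's leftmost base on the forward strand of ``sequence``.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    if not 0 <= error_rate < 0.5:
        raise ConfigError("error_rate must lie in [0, 0.5)")
    length = len(sequence)
    if not circular and read_len > length:
        raise ConfigError("read_len exceeds sequence length in linear mode")
    rng = stage_rng(seed, stage)
    n_reads = round(coverage * length / read_len)
    doubled = sequence + sequence
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, length if circular else length - read_len + 1))
        fragment = doubled[start : start + read_len] if circular else sequence[start : start + read_len]
        strand = "+"
        if both_strands and rng.random() < 0.5:
            strand = "-"
        arr = list(fragment)
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < error_rate)
            for p in errs:
                arr[p] = _other_base(rng, arr[p])
        read_seq = "".join(arr)
        if strand == "-":
            read_seq = reverse_complement(read_seq)
        reads.append((f"read_{i + 1}", read_seq, start, strand))
    return reads


def reads_fastq(reads: list[tuple[str, str, int, str]], quality: str = "I") -> str:
    chunks = []
    for name, seq, _, _ in reads:
        chunks.append(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")
    return "".join(chunks)


def reads_sam(
    reads: list[tuple[str, str, int, str]], reference_name: str, reference_length: int
) -> str:
    """SAM text of the true placements (primary records only)."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{reference_name}\tLN:{reference_length}",
    ]
    for name, seq, start, strand in reads:
        flag = 16 if strand == "-" else 0
        out_seq = reverse_complement(seq) if strand == "-" else seq
        lines.append(
            f"{name}\t{flag}\t{reference_name}\t{start + 1}\t60\t{len(seq)}M\t*\t0\t0\t"
            f"{out_seq}\t*"
        )
    return "\n".join(lines) + "\n"


def marker_tsv(markers: list[Marker]) -> str:
    lines = ["id\tchromosome\tposition\tfwd_primer\trev_primer"]
    for m in markers:
        lines.append(
            f"{m.id}\t{m.map_chromosome}\t{m.map_position:g}\t{m.fwd_primer}\t{m.rev_primer}"
        )
    return "\n".join(lines) + "\n"
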