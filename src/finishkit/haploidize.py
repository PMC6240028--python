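"""Population-guided pseudo-haploidization of phased heterozygous sites.

A pseudo-haploid reference holds an arbitrary one of the two alleles at each
heterozygous site. Given phase blocks (from a phased VCF with phase-set
annotations) and allele counts from a small cohort, this module rewrites the
reference so each block carries the haplotype whose alleles are most common
in the cohort — making the reference closer to the population average. A
per-site mode applies the same majority rule independently at every site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from cyvcf2 import VCF

from .assembly import Assembly, Scaffold
from .errors import ConsistencyError, InputFormatError


@dataclass
class PhasedSite:
    scaffold: str
    position: int  # 1-based
    hap1_allele: str
    hap2_allele: str
    current_ref: str

    def __post_init__(self) -> None:
        if self.hap1_allele == self.hap2_allele:
            raise ConsistencyError(
                f"site {self.scaffold}:{self.position} is not heterozygous"
            )


@dataclass
class PhaseBlock:
    id: str
    scaffold: str
    sites: list[PhasedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if positions != sorted(set(positions)):
            raise ConsistencyError(f"phase block {self.id}: positions not increasing")
        if any(s.scaffold != self.scaffold for s in self.sites):
            raise ConsistencyError(f"phase block {self.id}: sites on multiple scaffolds")


# Allele counts per (scaffold, 1-based position): Counter of allele -> count.
CohortAlleleCounts = dict


def read_phase_blocks(
    vcf_path: str, sample: str
) -> tuple[list[PhaseBlock], list[tuple[str, int]]]:
    """Collect phased heterozygous SNV sites of ``sample`` into phase blocks.

    Blocks are keyed by (scaffold, PS tag). Unphased heterozygous sites are
    skipped and returned as ``(scaffold, position)`` for logging. Indel
    records and homozygous sites are ignored.
    """
    vcf = VCF(vcf_path)
    if sample not in vcf.samples:
        raise InputFormatError(f"sample {sample!r} not in VCF {vcf_path}")
    idx = vcf.samples.index(sample)
    grouped: dict[tuple[str, str], list[PhasedSite]] = {}
    unphased: list[tuple[str, int]] = []
    for v in vcf:
        a, b, *rest = v.genotypes[idx]
        phased = bool(rest[-1]) if rest else False
        if a < 0 or b < 0 or a == b:
            continue
        alleles = [v.REF] + list(v.ALT)
        h1, h2 = alleles[a], alleles[b]
        if len(h1) != 1 or len(h2) != 1 or len(v.REF) != 1:
            continue
        if not phased:
            unphased.append((v.CHROM, v.POS))
            continue
        ps = v.format("PS")
        ps_val = str(ps[idx][0]) if ps is not None else "0"
        grouped.setdefault((v.CHROM, ps_val), []).append(
            PhasedSite(v.CHROM, v.POS, h1, h2, v.REF)
        )
    blocks = [
        PhaseBlock(f"{chrom}:{ps}", chrom, sites)
        for (chrom, ps), sites in grouped.items()
    ]
    return blocks, unphased


def cohort_allele_counts(
    vcf_path: str, exclude_samples: tuple[str, ...] = ()
) -> CohortAlleleCounts:
    """Tally cohort allele counts per site (2 per non-missing genotype)."""
    vcf = VCF(vcf_path)
    keep = [i for i, s in enumerate(vcf.samples) if s not in exclude_samples]
    counts: CohortAlleleCounts = {}
    for v in vcf:
        alleles = [v.REF] + list(v.ALT)
        c: Counter = Counter()
        for i in keep:
            a, b = v.genotypes[i][0], v.genotypes[i][1]
            if a < 0 or b < 0:
                continue
            c[alleles[a]] += 1
            c[alleles[b]] += 1
        if c:
            counts[(v.CHROM, v.POS)] = c
    return counts


def score_block(block: PhaseBlock, counts: CohortAlleleCounts) -> tuple[int, int]:
    """Summed cohort support for each haplotype of a block.

    Sites absent from ``counts`` contribute 0 to both scores.
    """
    s1 = s2 = 0
    for site in block.sites:
        c = counts.get((site.scaffold, site.position), Counter())
        s1 += c.get(site.hap1_allele, 0)
        s2 += c.get(site.hap2_allele, 0)
    return s1, s2


def choose_and_apply(
    assembly: Assembly,
    blocks: list[PhaseBlock],
    counts: CohortAlleleCounts,
    mode: str = "block",
) -> tuple[Assembly, list[dict]]:
    """Rewrite the reference to the cohort-majority allele choice.

    mode="block": the whole block takes the higher-scoring haplotype's
    alleles; mode="site": each site independently takes its most common
    allele. Ties keep the current reference base. Returns the edited
    assembly and provenance rows (one per edited site).
    """
    if mode not in ("block", "site"):
        raise ValueError(f"unknown mode {mode!r}")
    occupied: set[tuple[str, int]] = set()
    for b in blocks:
        for s in b.sites:
            key = (s.scaffold, s.position)
            if key in occupied:
                raise ConsistencyError(f"overlapping phase blocks at {key}")
            occupied.add(key)

    sequences = {s.name: bytearray(s.sequence, "ascii") for s in assembly}
    provenance: list[dict] = []
    for block in blocks:
        s1, s2 = score_block(block, counts)
        for site in block.sites:
            seq = sequences[site.scaffold]
            current = chr(seq[site.position - 1])
            if current not in (site.hap1_allele, site.hap2_allele):
                raise ConsistencyError(
                    f"assembly base {current!r} at {site.scaffold}:{site.position} "
                    f"matches neither phased allele"
                )
            if mode == "block":
                if s1 > s2:
                    chosen, new = "hap1", site.hap1_allele
                elif s2 > s1:
                    chosen, new = "hap2", site.hap2_allele
                else:
                    chosen, new = "tie", current
            else:
                c = counts.get((site.scaffold, site.position), Counter())
                c1, c2 = c.get(site.hap1_allele, 0), c.get(site.hap2_allele, 0)
                if c1 > c2:
                    chosen, new = "hap1", site.hap1_allele
                elif c2 > c1:
                    chosen, new = "hap2", site.hap2_allele
                else:
                    chosen, new = "tie", current
            if new != current:
                seq[site.position - 1] = ord(new)
                provenance.append(
                    {
                        "block": block.id,
                        "scaffold": site.scaffold,
                        "position": site.position,
                        "old_base": current,
                        "new_base": new,
                        "chosen_hap": chosen,
                        "score_h1": s1,
                        "score_h2": s2,
                    }
                )
    edited = Assembly(
        assembly.name,
        [Scaffold(s.name, sequences[s.name].decode("ascii")) for s in assembly],
    )
    return edited, provenance


def provenance_tsv(rows: list[dict]) -> str:
    cols = [
        "block",
        "scaffold",
        "position",
        "old_base",
        "new_base",
        "chosen_hap",
        "score_h1",
        "score_h2",
    ]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"
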