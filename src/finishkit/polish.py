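"""Cohort-corroborated correction of homozygous reference/read disagreements.

When the resequencing data of the very animal an assembly was built from is
genotyped against that assembly, a homozygous genotype differing from the
reference base is either a reference error or a genotyping artifact. The rule
implemented here corrects the reference only when no other animal in a small
cohort carries the reference allele: if any cohort genotype contains the
reference allele, the base is presumed real (the focal animal's second allele
was undersampled) and left untouched.

Only single-nucleotide substitutions are considered; indel records are
excluded so downstream coordinates stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass

from cyvcf2 import VCF

from .assembly import Assembly, Scaffold
from .errors import ConsistencyError, InputFormatError

DECISIONS = (
    "applied",
    "skipped_ref_in_cohort",
    "skipped_not_homozygous",
    "skipped_indel",
)


@dataclass(frozen=True)
class GenotypeCall:
    """One animal's diploid genotype at one site (allele strings)."""

    animal: str
    allele_a: str
    allele_b: str
    missing: bool = False

    def carries(self, allele: str) -> bool:
        return not self.missing and allele in (self.allele_a, self.allele_b)


@dataclass
class PolishSite:
    """A candidate correction: focal animal homozygous for a SNV ALT."""

    scaffold: str
    position: int  # 1-based VCF coordinate
    ref_allele: str
    alt_allele: str
    focal: GenotypeCall
    cohort: list[GenotypeCall]


@dataclass(frozen=True)
class ChangeRecord:
    scaffold: str
    position: int
    old_base: str
    new_base: str
    decision: str


def _allele_string(variant, index: int) -> str:
    return variant.REF if index == 0 else variant.ALT[index - 1]


def _genotype_call(variant, sample: str, idx: int) -> GenotypeCall:
    a, b = variant.genotypes[idx][0], variant.genotypes[idx][1]
    if a < 0 or b < 0:
        return GenotypeCall(sample, ".", ".", missing=True)
    return GenotypeCall(sample, _allele_string(variant, a), _allele_string(variant, b))


def find_candidate_sites(
    vcf_path: str,
    assembly: Assembly,
    focal_sample: str,
) -> tuple[list[PolishSite], list[ChangeRecord]]:
    """Scan a multi-sample VCF for focal homozygous-ALT SNVs.

    Returns the candidate sites plus skip records for focal-divergent sites
    that are not candidates (heterozygous focal genotypes and indel records).
    Every VCF REF field is checked against the assembly base; a mismatch
    raises :class:`ConsistencyError` naming the scaffold and position.
    """
    vcf = VCF(vcf_path)
    if focal_sample not in vcf.samples:
        raise InputFormatError(f"focal sample {focal_sample!r} not in VCF {vcf_path}")
    focal_idx = vcf.samples.index(focal_sample)
    cohort = [(i, s) for i, s in enumerate(vcf.samples) if s != focal_sample]

    sites: list[PolishSite] = []
    skips: list[ChangeRecord] = []
    for v in vcf:
        try:
            scaf = assembly.scaffold(v.CHROM)
        except KeyError:
            raise ConsistencyError(f"VCF scaffold {v.CHROM!r} absent from assembly")
        ref = v.REF
        pos0 = v.POS - 1
        if scaf.sequence[pos0 : pos0 + len(ref)] != ref:
            raise ConsistencyError(
                f"VCF REF {ref!r} does not match assembly at {v.CHROM}:{v.POS}"
            )
        gt = v.genotypes[focal_idx]
        a, b = gt[0], gt[1]
        if a < 0 or b < 0:
            continue
        if a == 0 and b == 0:
            continue
        if a != b or a == 0:
            # heterozygous (carries at least one ALT) -> not a candidate
            skips.append(
                ChangeRecord(v.CHROM, v.POS, ref, ".", "skipped_not_homozygous")
            )
            continue
        alt = v.ALT[a - 1]
        if len(ref) != 1 or len(alt) != 1:
            skips.append(ChangeRecord(v.CHROM, v.POS, ref, alt, "skipped_indel"))
            continue
        sites.append(
            PolishSite(
                scaffold=v.CHROM,
                position=v.POS,
                ref_allele=ref,
                alt_allele=alt,
                focal=_genotype_call(v, focal_sample, focal_idx),
                cohort=[_genotype_call(v, s, i) for i, s in cohort],
            )
        )
    return sites, skips


def corroborate_and_apply(
    sites: list[PolishSite], assembly: Assembly
) -> tuple[Assembly, list[ChangeRecord]]:
    """Apply each candidate unless a cohort genotype carries the REF allele.

    A site is corrected iff no non-missing cohort genotype contains the
    reference allele (missing genotypes detect nothing and do not block).
    Returns a polished copy of the assembly and one :class:`ChangeRecord` per
    candidate. Scaffold lengths are conserved: all edits are substitutions.
    """
    if sites and not sites[0].cohort:
        raise ValueError("polishing requires a cohort of at least one animal")
    seen: set[tuple[str, int]] = set()
    for s in sites:
        key = (s.scaffold, s.position)
        if key in seen:
            raise ConsistencyError(
                f"overlapping candidate sites at {s.scaffold}:{s.position}"
            )
        seen.add(key)

    sequences = {s.name: bytearray(s.sequence, "ascii") for s in assembly}
    records: list[ChangeRecord] = []
    for site in sites:
        if any(call.carries(site.ref_allele) for call in site.cohort):
            records.append(
                ChangeRecord(
                    site.scaffold,
                    site.position,
                    site.ref_allele,
                    site.ref_allele,
                    "skipped_ref_in_cohort",
                )
            )
            continue
        sequences[site.scaffold][site.position - 1] = ord(site.alt_allele)
        records.append(
            ChangeRecord(
                site.scaffold,
                site.position,
                site.ref_allele,
                site.alt_allele,
                "applied",
            )
        )
    polished = Assembly(
        assembly.name,
        [Scaffold(s.name, sequences[s.name].decode("ascii")) for s in assembly],
    )
    return polished, records


def changelog_tsv(records: list[ChangeRecord]) -> str:
    lines = ["scaffold\tposition\told_base\tnew_base\tdecision"]
    for r in records:
        lines.append(f"{r.scaffold}\t{r.position}\t{r.old_base}\t{r.new_base}\t{r.decision}")
    return "\n".join(lines) + "\n"
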