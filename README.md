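# finishkit

Finishing and assessment toolkit for reference genome assemblies.

Modern reference assemblies are built by external assemblers and
scaffolders, but a long tail of bespoke decision rules turns their output
into a finished reference: gap-aware contiguity accounting, correcting the
reference where the source animal's own resequencing data disagrees with
it, choosing which haplotype a pseudo-haploid reference should carry,
anchoring scaffolds to chromosomes with a radiation-hybrid (RH) marker map,
screening contigs against microbial databases, iterating a circular
mitochondrial consensus, and quantifying how two assembly versions compare
as read-mapping targets. `finishkit` implements those rules as a tested,
reusable Python library with a CLI, together with seeded synthetic-data
generators that carry exact ground truth, so every stage can be exercised
and verified at desk scale.

## What is implemented

| Stage | Rule |
|---|---|
| `assembly` | contigs = maximal runs between gaps of ≥ 25 Ns; N50 = largest `L` with pieces ≥ `L` covering half the total; scaffolds < 3000 bp removed |
| `polish` | a focal homozygous-ALT SNV replaces the reference base iff no cohort genotype carries the reference allele |
| `haploidize` | each phase block rewritten to the haplotype whose alleles are most common in a cohort (per-site mode optional) |
| `rhmap` | markers placed by unique, inward-facing exact primer pairs; scaffolds assigned by marker majority; map-adjacent pair orientation concordance and its cross-assembly partition |
| `screen` | DUST-masked microbial references → canonical 32-mer set; any contig with one exact match is flagged |
| `mtconsensus` | iterative circular consensus; sites need ≥ 10× coverage and ≥ 90% agreement or become N; tandem 8-mer copy number adjudicated from a flank-spanning read |
| `compare` | primary-alignment 2×2 mapping table, exact sign test on discordant reads, paired Wilcoxon signed-rank (normal-with-continuity-correction and exact modes), split-gene candidate screen |
| `synthetic` | seeded generators for all of the above with exact recorded truth |

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Generate a synthetic bundle, polish the reference against its cohort VCF,
and summarize contiguity:

```sh
finishkit simulate --seed 17 --out bundle/
finishkit polish --fasta bundle/reference.fa --vcf bundle/cohort.vcf \
    --focal focal --out polished.fa --changelog changes.tsv
finishkit stats --fasta polished.fa
```

The polish step logs

```
INFO finishkit: 75 candidates, 60 applied
```

— of 75 focal homozygous-ALT candidates, the 60 planted reference errors
are corrected (no cohort animal carries the erroneous reference allele)
and 15 are skipped because a cohort animal does carry it; the changelog
also records 60 heterozygous records that were never candidates. The
stats step prints one TSV row:

```
contig_n50	scaffold_n50	contig_count	scaffold_count	gap_count	gap_bases	non_n_bases	gc_fraction	gc_defined
8372	20000	9	3	6	638	59362	0.497372	True
```

i.e. three 20 kb scaffolds broken by six gaps (638 Ns) into nine contigs
with a contig N50 of 8372 bp and near-balanced GC. The same operations are
available as library calls (`finishkit.find_candidate_sites`,
`finishkit.assembly_stats`, ...), which is the intended interface for
anything beyond one-off runs.

Other subcommands: `finishkit haploidize`, `finishkit rhmap
place|assign|concord`, `finishkit screen`, `finishkit mtcons`, `finishkit
compare`, `finishkit splitgenes`.

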