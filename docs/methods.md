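# Methods

`finishkit` re-implements, as a tested library, the decision layers used to
finish and assess a modern vertebrate reference assembly: the arithmetic and
filtering rules are executed on desk-scale inputs (real or synthetic) rather
than on the multi-terabyte data the original assembly projects consume. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## Sequence model and contiguity statistics

An assembly is an ordered set of scaffolds over `{A,C,G,T,N}`; lower-case
input is upper-cased and any other character is rejected at parse with its
position. A *gap* is a run of at least `min_gap` Ns (default 25, the common
gap-summary convention); shorter N runs are treated as sequence uncertainty
inside contigs and do not break contiguity. Contigs and gaps therefore tile
each scaffold exactly, which is asserted as a property test.

N50 is the largest length `L` such that pieces of length ≥ `L` cover at
least half the total; when half the total is hit exactly at a boundary the
piece reaching the threshold defines N50 (`≥` comparison, matching the
brute-force cumulative-sum definition). Scaffold lengths include internal
Ns — the alternative (non-N span) would make scaffold N50 depend on the gap
threshold, which no common tool does. GC content is computed over non-N
bases only and flagged undefined for all-N inputs. Scaffolds shorter than
`min_scaffold_length` (default 3000 bp) are removed by a strict `<`
comparison: a 2999 bp scaffold goes, a 3000 bp scaffold stays.

## Cohort-corroborated polishing

When the animal an assembly was built from is resequenced and genotyped
against that assembly, a homozygous-ALT SNV is either a reference error or a
genotyping artifact. The correction rule: apply the substitution only if
**no** non-missing cohort genotype contains the reference allele. Design
choices:

- SNVs only; indel records are logged `skipped_indel`. Substitutions keep
  every downstream coordinate valid within the pipeline.
- Missing cohort genotypes do not block a change: the rule fires on
  *detection* of the reference allele, and absent data detects nothing.
- In multi-allelic records the focal homozygous ALT defines the
  replacement; a different ALT carried by a cohort animal is not the
  reference allele and does not block.
- The genotyper is consumed, never invoked: input is any well-formed
  multi-sample VCF whose REF fields are checked against the FASTA (mismatch
  is a consistency error, exit code 3 at the CLI).

## Population-guided pseudo-haploidization

Phased heterozygous sites are read from a VCF (`|`-separated genotypes,
grouped by the PS phase-set tag; unphased het sites are left untouched and
logged). For each phase block the two haplotypes are scored by summed cohort
allele counts (two alleles per non-missing genotype), and the block is
rewritten to the higher-scoring haplotype. The per-block rule is the
default because a phase block is the unit at which haplotype identity is
known; a per-site mode (independent argmax per site, which can mix
haplotypes) is offered behind `--mode site` since both readings of the
procedure are defensible. Ties keep the current reference base — the
minimal-change, deterministic behavior.

## RH-map anchoring and order concordance

A marker is *placed* when its forward and reverse primers each match
exactly once genome-wide (either strand, exact substring matching — for
short exact primers this is equivalent to an exact-match aligner for unique
hits), both on one scaffold, facing inward, with an amplicon span of at most
`max_amplicon` (default 1000 bp; configurable, as no published bound
exists). The marker position is the amplicon midpoint, and the amplicon
carries a strand.

Scaffolds are assigned to the chromosome holding the majority of their
placed markers (ties unassigned and flagged), ordered along the chromosome
by median marker map position, and oriented by the sign of the Spearman
rank correlation between map position and scaffold coordinate (zero or
undefined correlation defaults to `+` and is flagged).

"Marker pair" means consecutive markers in map order on one chromosome
(map-position ties broken by marker id). Pair orientation is
**strand-aware**: after applying scaffold orientation, a pair is concordant
iff both amplicons share a strand and their coordinate order matches the
map order under that strand — both-reversed is a locally consistent
(inverted-segment) placement. This is what makes an inversion diagnosable:
a planted inversion spanning markers *i..j* flags exactly the two boundary
pairs (*i−1, i*) and (*j, j+1*) where strands disagree, while interior
pairs (reversed order *and* reversed strand) stay concordant. An
order-only rule would instead flag every interior pair and neither
boundary, which matches neither the notion of "oriented differently" nor
inversion-breakpoint diagnosis. The cross-assembly partition then counts,
for the pairs misoriented on each assembly, whether the other assembly is
misoriented, concordant, or unassessable (one of the markers unplaced);
the five categories are disjoint and reconcile exactly with the
per-assembly totals.

## Contamination screening

Microbial reference sequences are first masked with a symmetric-DUST-style
score: in every 64 bp window (step 1), `S = Σ_t c_t(c_t−1)/2 / (n_trip−1)`
over triplet counts; windows with `S > 2.0` are masked and merged. The
threshold approximates the common DUST level 20 (whose scores are scaled
tenfold); bit-exactness against any particular masker binary is not
claimed. Unmasked source sequence is decomposed into canonical 32-mers
(lexicographic minimum of a k-mer and its reverse complement), held in a
hash set — exactness over memory at desk scale. A contig with at least one
exact canonical 32-mer match is flagged. By default flagged contigs inside
multi-contig scaffolds are replaced by equal-length N runs (coordinates
preserved) and single-contig contaminant scaffolds are dropped; `--drop`
excises flagged sequence for removal-style behavior. A random 32-mer
collision has probability ≪ 10⁻⁹ per k-mer, so screening on synthetic data
is expected to be exact — and is, in the tests (perfect recall, zero false
flags on 1000 random 200 bp contigs).

## Mitochondrial consensus

The circular genome is handled by doubling the reference and folding
alignment coordinates modulo its length. Each round aligns every read
(both orientations, better score kept) to the current consensus, tallies
per-site A/C/G/T/deletion counts, and re-calls every site: the majority
base iff coverage ≥ 10 and agreement ≥ 0.90, else N; deletion-majority
sites are N (the consensus is substitution-only, so length is stable).
Iteration (default 3 rounds) stops at a fixed point.

The built-in aligner is a vectorised Smith–Waterman with match +1,
mismatch −1, gap −2 (linear gaps via a running-maximum prefix scan). The
full dynamic-programming matrix is computed: at the few-hundred-bp scales
this module targets, full width is fast and avoids the seed-placement
failure mode of a banded heuristic. The aligner is a pluggable contract,
so pre-computed alignments (e.g. from a SAM file) can substitute.

The coverage/agreement filter deliberately emits N where errors cluster:
at 40× coverage and 1% substitution error, a site with ~28 reads and 3
errors falls to 0.89 agreement and is filtered. Consensus accuracy is
therefore assessed as identity over *called* sites (≥ 99.9% required in
the acceptance study, empirically 100%), with the N count reported
separately and bounded at 1% of sites (empirically 0–1 per 600 bp).

Tandem-repeat copy number in the control region is adjudicated from a
single read spanning both flanks of the repeat: each flank must occur
exactly once, in order (precondition errors otherwise), and the interior
must be an integral tandem of the 8-mer unit (otherwise an adjudication
failure is reported and no update is made).

## Read-mapping comparison statistics

Reads are classified by primary-alignment status in two SAM streams over
the same read universe (secondary/supplementary records never count;
duplicate primary records are an input error; ids present in one stream
only are counted unmapped in the other, with a warning). Proper pairs
require both mates primary-mapped to one reference sequence in FR
orientation; insert-size limits are not enforced. Exclusive sets (mapped
to exactly one assembly) carry counts and mean read GC.

The discordant counts feed a one-tailed exact sign test — each read
mapping to exactly one assembly is a fair-coin trial under the null of no
mapability difference; `P(X ≥ b_only)` is computed by integer arithmetic
for `n ≤ 10⁴` and by a continuity-corrected normal approximation above.
Values below 2.2 × 10⁻¹⁶ format as `< 2.2e-16` while the raw value is
returned.

The paired Wilcoxon signed-rank test (two-sided) drops zeros and
mid-ranks ties. The default `normal_cc` mode uses
`z = (W − n(n+1)/4 + ½)/√(n(n+1)(2n+1)/24)` with `W` the smaller rank sum
(no tie correction in the variance); for 13 uniformly improved samples it
gives p = 0.0017. The `exact` mode enumerates the null distribution of the
positive-rank sum over all 2ⁿ sign assignments (n ≤ 20, by convolution
over doubled ranks so mid-ranks stay integral) and gives 2/8192 ≈ 0.00024
for the same data; the approximate mode is the default because it is the
variant whose value the comparison study is expected to reproduce.

Split-gene candidates are transcripts with ≥ 2 projections on *distinct*
target sequences whose source-coordinate starts and stops each differ by
at most 10 bp (a gene present once but placed on two contigs); an
alternative "adjacent" reading (pieces tiling the transcript) is available
behind a flag.

## Synthetic data: what it emulates, and what it does not

The generators produce every input above with exact recorded truth, one
RNG stream per stage derived from `(master seed, stage name)` so stages
regenerate independently; identical (config, seed) reproduces identical
bytes.

Default study conditions: 3 scaffolds × 20 kb; heterozygous SNVs at
10⁻³/bp (exact count), grouped into phase blocks of 2–8 consecutive sites,
one haplotype per block designated population-major; 2 gaps (25–200 Ns)
per scaffold; 20 planted reference errors per scaffold (reference differs
from both haplotypes) plus 5 per scaffold that one cohort animal vetoes;
a cohort of 4 animals drawing each allele copy from the major haplotype
with probability 0.9 and 5% missing genotypes — the size of cohort this
kind of polishing has used in practice; 12 markers with
unique 20 bp primer pairs and 50–500 bp amplicons on the first scaffold,
with a second assembly copy carrying one inversion spanning markers 5–8;
3 microbial references of 5 kb donating 3 contaminant contigs of 500 bp;
a 600 bp circular mitochondrial genome with 4 copies of an 8-mer repeat
and a starting reference 5 substitutions away. Shotgun reads are uniform,
strand-sampled, with i.i.d. substitution errors (no indels, constant
quality, no ancient-DNA damage model).

These scales are chosen so the full suite and the acceptance study run in
seconds on one core while every decision rule is exercised at its
boundary. What passing shows: the *rules* are implemented exactly (the
boundary tests), and each stage recovers planted truth under its stated
conditions. What it does not show: behavior on real repeat structure,
segmental duplication, alignment ambiguity, indel errors, or genome-scale
inputs — the upstream assemblers and aligners that confront those are out
of scope here by design.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; 1-based only at VCF
  boundaries.
- Empty scaffolds segment to empty collections; N50 of an empty collection
  is a `ValueError`; all-N assemblies report GC 0 with a defined-ness flag.
- Consensus ties at 50/50 fail the 90% rule and yield N; haploidization
  score ties keep the reference; map-position ties order by marker id;
  palindromic primers are counted once per locus.
- Zero reads yield an all-N consensus with a warning rather than an error.
- All CLI outputs are written atomically (temp file + rename); reruns with
  the same seed and inputs are byte-identical.
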