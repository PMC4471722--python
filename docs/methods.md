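# Methods

This note documents the models, conventions and numerical choices behind
`chromosurvey`, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Survey statistics

Reads are modelled as independently, uniformly placed intervals of
length L on a chromosome of size S. A fixed position is missed by one
read with probability 1 − L/S, so with N reads the representation
probability is 1 − (1 − L/S)^N. Sorting purity p (the fraction of sorted
particles that are the target chromosome) can enter two ways:

- **outer** (default): `P = p · [1 − (1 − L/S)^N]` — a position is only
  representable if its locus was sorted; conditional on that, coverage
  follows the uniform model. P is bounded by p.
- **exponent**: `P = 1 − (1 − L/S)^(N·p)` — purity thins the effective
  read count; P → 1 as N grows.

With the survey-scale inputs (N = 4,289,539, L = 357.1 bp, S = 840 Mbp,
p = 0.9524) the outer convention gives 0.799 and the exponent convention
0.824. Reports emit both; the ~3 % gap is inherent to the two readings of
where purity acts, and neither is "wrong" — outer is the default because
it treats off-target reads as unable to rescue unsorted loci, the more
conservative physical picture. For small L/S the exponent form converges
to the Poisson-coverage limit 1 − exp(−N·p·L/S); the package exposes that
limit for numerical cross-checks (agreement < 1e-6 at survey scale).

The combined mean read length follows the survey-table convention: the
unweighted arithmetic mean of the per-library means (294.8, 357.2, 419.2
→ 357.1), not total bases over total reads (which gives 367.0). Both are
available; the unweighted value is what appears in the combined table
row, the weighted one via `weighted_mean_length`.

## Read triage

Categories are assigned with fixed precedence repeat > chloroplast >
mitochondrion > rRNA > low-copy. The sources being excluded jointly, the
order is a convention chosen to make counts reproducible; it only affects
reads with multiple lines of evidence. E-value cutoffs are 1e-15 for
both organellar genomes and 1e-5 for rRNA, inclusive. Repetitive
fraction is measured two ways: base-level (union of masked intervals over
total read bases — robust to read-length variation) and read-level
(fraction of reads carrying any repeat annotation); real surveys phrase
this number either way, so both are emitted.

All interval arithmetic is 1-based inclusive, and masked-base totals are
computed on the union of intervals per read, so overlapping or abutting
annotations are never double-counted. Per-family cumulative bases are
unioned within each family, so a base annotated by two different
families credits each family once but the total only once.

The bundled `lightweight_mask` (exact 15-mer seeding, ungapped extension
tolerating ≤3 consecutive mismatches, 50 bp minimum) exists so synthetic
data can be masked end-to-end; real analyses ingest RepeatMasker `.out`
files. At zero divergence it recovers ≥90 % of planted repeat bases; its
losses are read-boundary fragments shorter than the 50 bp minimum.

## Gene space

All threshold comparisons are inclusive. Per-reference profiles:
model-grass proteomes e ≤ 1e-6, length ≥ 30, %positives ≥ 75 (barley:
≥ 90; UniProt: ≥ 100); UniGene e ≤ 1e-30, length ≥ 90, %identity ≥ 98.
"Best" hit = lowest e-value, ties by highest bitscore, then
lexicographically smallest subject id — a stated convention, since
tie-breaking is otherwise undefined. Reciprocal-best-hit filtering keeps
(q, s) iff each is the other's best in the opposite search direction.

Redundant-singleton elimination collapses singletons whose
(subject, sstart, send) coincide exactly, keeping the longest aligned
query (ties lexicographic); contigs are never removed. This guards
against MDA copy bias inflating apparent independent evidence.

Gene models merge mapped segments per reference CDS, longest segment
first; unmapped reference positions become `n`. Overlaps are reconciled
by trimming the smaller segment to unclaimed positions; if a trimmed
region disagreed with the kept bases, the model's `conflict` flag is
raised rather than silently discarding data. Protein-space coordinates
convert to CDS nucleotides as 3(aa−1)+1 … 3aa. The genic fraction is
n_models × mean CDS length (default 2,000 bases) / chromosome size, and
the genome-wide gene estimate scales that fraction to the genome size and
floors to an integer.

## Synteny

Gene positions are annotated-gene midpoints. Densities use half-open
windows starting at position 1 (defaults: 500 kb tumbling for density
tracks, 1 Mb for block calling, 50 kb step for heatmap-style sliding
windows). Block calling is strict — a window qualifies with **more
than** `min_members` (default 100) — and adjacent qualifying windows are
merged with summed membership. For desk-scale synthetic runs the demo
uses a scaled threshold (default 3), since the 100-member rule is meant
for gene sets three orders of magnitude larger.

The inter-model synteny map (which model-genome chromosomes are mutually
colinear) is an input table; the bundled default carries the wheat
group-5 relationships (Bd1–Os3–Sb1, Bd4–Os9–Sb2, Bd4–Os12), which also
define the orthologous chromosome sets Bd {1,4}, Os {3,9,12}, Sb {1,2}.
A gene is `syntenic` when every available species places it on an
orthologous chromosome; `moved_in_wheat` when all species agree on
non-orthologous but mutually colinear chromosomes (the rearrangement
happened in the wheat lineage); `moved_in_other:<sp>` when exactly one
species deviates; `unresolved` otherwise.

## miRNA discovery

The homology scan reports every ungapped match of each mature miRNA and
its reverse complement with ≤ `max_mismatches` substitutions (default 2;
T ≡ U). Candidate windows extend 200 nt each side of the hit, truncated
at sequence ends.

Folding is a pluggable contract `sequence -> (dot-bracket, MFE)`.
The bundled engine is a pair-energy dynamic program: GC −3.0, AU −2.0,
GU −1.0 kcal/mol, a −0.5 stacking bonus for directly nested pairs, a
+8.0 penalty when a pair closes anything other than a stacked pair
(the analogue of loop-initiation terms in nearest-neighbour models), and
a minimum hairpin loop of 3 nt. The loop penalty keeps isolated pairs
and scattered short helices unprofitable, which places random-sequence
energies near the scale a full thermodynamic folder reports (verified
against RNAfold in the test suite) while leaving long planted stems
deeply negative. Absolute energies are still approximate; analyses that
need thermodynamic MFEs should supply external fold output through the
engine contract. The DP is O(n³) via per-diagonal numpy vectorisation —
about 0.7 s for a 420 nt window — so defaults keep folding tractable.

After folding, the candidate is trimmed to the hairpin enclosing the
mature (the span of the mature and its pairing partners, extended
outward through closing pairs) and re-folded; MFE, GC and MFEI are
computed on the trimmed precursor. Acceptance requires: mature within
one arm (a mature containing both "(" and ")" spans the terminal loop →
rejected), ≤4 unpaired mature positions, precursor length 60–300 nt,
and MFEI ≥ 0.67 — chosen just above the reported MFEI ranges of tRNA
(0.64), rRNA (0.59) and mRNA (0.62–0.66), all configurable. Overlapping
accepted candidates for the same mature collapse to the best-MFEI locus.
The first failing criterion is recorded as the rejection reason.

## SNP pipeline

Transcript selection: ≥1 match at e ≤ 1e-30 and identity ≥ 98 %
(inclusive). Transcripts with ≥2 strong matches carry a homoeolog-risk
flag: in a polyploid background, near-identical homoeologous or
paralogous copies can pass the identity filter, so their SNPs deserve
caution.

Variant calling counts every mapped read base per position (read depth,
not base-quality weighted — matching how 454-era mappers counted);
positions inside alignment gaps contribute nothing. A site is a variant
when the strict-majority read base differs from the transcript base;
majority ties emit no call (the calling rule inside legacy mappers being
unspecified, strict majority is the conservative convention). Filters:
depth within [3, 10] inclusive, then proximity — any two surviving calls
on one transcript ≤3 bp apart are **both** removed, transitively over
clusters. Removing the whole cluster (rather than thinning it) is the
symmetric, conservative reading of ">3 bp between SNPs" and guards
against alignment-artifact clusters; the filter is idempotent. SNP
frequency is total selected-transcript length / retained SNP count, and
is reported as absent (not zero) when no SNP survives.

Position transfer to the second genotype uses global pairwise alignment
(match 2, mismatch −1, gap open −5, extend −1) between each
SNP-carrying transcript and its best-bitscore match passing the
transcript filter; multi-match transcripts are resolved to the best
bitscore with an ambiguity flag. Classification requires coverage in all
five samples (drought + control per genotype, plus the chromosome
consensus) and drought/control consistency within each genotype; the
three groups are then mutually exclusive and — whenever TR differs from
the chromosome base — exhaustive (verified by enumeration over all 4³
base triples).

## Synthetic data: what it emulates, and what it does not

The generator plants, with full ground truth: a repeat-dominated
chromosome (default 85 % repetitive, Gypsy-heavy superfamily weights,
copies drawn from a bundled synthetic repeat library at configurable
divergence), gene loci (900–2,400 bp, a proxy for single/multi-exon
fragments), miRNA precursors (a 20 nt stem extension + mature + 18 nt
loop + reverse complement, so the mature sits fully paired in the 5'
arm), organellar/rRNA contaminant reads from bundled ~2 kb synthetic
decoys, log-normal per-locus MDA-like copy-bias multipliers (σ = 0.5
over 10 kb loci), and transcript quartets (two genotypes × two
conditions) with variants planted by group archetype at a default
density of 1/1,000 bases, ≥12 bp apart and ≥150 bp from transcript ends.
Read lengths are normal (default mean 357, sd 120) truncated to
[50, 1200] bases; base composition is GC 0.46, grass-like. Features are
laid out non-overlapping in shuffled order with the non-repetitive
remainder distributed multinomially between them, so the realised repeat
fraction equals the configured one up to the final copy's truncation and
a capacity error is raised when features cannot fit.

Deliberately not emulated: platform-specific error profiles (homopolymer
errors), indels (synthetic reads are edit-free, so the internal mappers
can be exact-seed and ungapped), assembly (contigs/singletons enter as
sequences), chimeric MDA artefacts, and real repeat-library sequence
content. Consequently, passing tests demonstrate that the *rules* —
thresholds, filters, classifications, formulas — behave exactly as
specified on data satisfying the stated statistical structure; they do
not demonstrate robustness to base-calling error, indel alignment or
diverged repeat detection, which real runs delegate to the external
tools whose outputs this package ingests.

Every generator is seed-deterministic (numpy `default_rng`); the demo
pipeline derives per-stage seeds from the run seed by fixed offsets and
is byte-identical across repeats. Demo problem sizes (200 kb chromosome,
2,000 reads, 10–12 genes, 5–6 precursors) were chosen so the full
end-to-end run completes in well under a minute while every stage still
has enough planted signal to measure recall exactly.

## Known limitations

- The bundled folding engine ranks hairpins correctly but its absolute
  MFEs are approximate; MFEI thresholds were set against its own scale
  (validated against RNAfold on random and hairpin sequences).
- The minimal SAM reader handles single-segment records only; BAM/CRAM
  and paired-end semantics are out of scope.
- `classify_moved` reasons at whole-chromosome granularity; it does not
  detect intra-chromosomal rearrangements or use gene order.
- The internal mappers (k-mer seed, ungapped) are for edit-free
  synthetic data; real alignments should come from a dedicated mapper
  via SAM.
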