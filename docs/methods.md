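# Methods

## Elongation model

`vpseq` treats contig extension as iterated local consensus calling. A
*virtual primer* — the terminal 20 bases of the contig — is searched against a
read store holding all (cleaned) reads without pairing information. Each
primer occurrence anchors its read so that the occurrence coincides with the
contig terminus; read bases overhanging the end form pileup columns at
positions 1, 2, … beyond the terminus. Bases are called outward one position
at a time and appended until the calling rule abstains or support runs out; a
single round can add at most read_length − 20 bases per end. After each round
the primers are redesigned from the new termini and the process repeats
(5′ end, then 3′ end per round) until a full pass adds nothing, or a safety
cap of 100 rounds. The engine contains no randomness: identical inputs give
identical output, and contigs are processed independently, so batch order is
irrelevant. The 5′ end is extended as the 3′ end of the reverse-complemented
contig, which guarantees exact end symmetry. The input contig always survives
verbatim as a contiguous substring of the output (`core_span` records where):
mismatch allowances affect read recruitment only, never the template.

### Posterior and calling rule

With counts `N(nt|i)` over {A,C,G,T} and depth `N(i)`:

    Pr(nt, i) = (N(nt|i) + n/4) / (N(i) + n),   n = 20.

The pseudo-count keeps empty columns at the uniform prior 0.25 and the four
posteriors always sum to 1 (the implementation compares exact rationals, so
threshold boundaries are not at the mercy of floating point). A two-base
ambiguity code's posterior is the sum of its components. The call is: argmax
base if ≥ 0.8; else argmax eligible code if ≥ 0.8 and the previous call was an
unambiguous base; else stop. Ties break lexicographically (A<C<G<T;
R<Y<K<M<S<W). Two consequences worth knowing:

* **Minimum calling depth.** A unanimous pileup reaches 0.8 only at depth 55
  ((N+5)/(N+20) ≥ 0.8 ⟺ N ≥ 55), and in general a threshold p requires
  N ≥ (p·n − n/4)/(1 − p). The method is deliberately conservative at low
  coverage; transcripts below ≈ 55× effective depth do not elongate, which is
  also why recovery collapses at 10× in the depth-dependence test.
* **Code eligibility.** A code may only be called when *both* component bases
  are observed in the pileup. Without this, the pseudo-count arithmetic would
  promote a unanimous depth-54 pileup to a code (e.g. {A:54}: Pr(R) = 64/74 ≥
  0.8), i.e. the rule would be *less* conservative just below the calling
  depth than at it. A code asserts two observed alleles; zero-count support
  for the second allele contradicts that meaning.

The ban on successive ambiguity codes is implemented as "the previous call
must be a plain base", including across round boundaries: the first new
position of a round takes the contig's current terminal character as its
predecessor, so a terminus ending in a code cannot be followed by another.

### Read recruitment

Reads are stored in a single concatenated buffer with every 10-mer (half the
primer) indexed exactly by its 2-bit code (numpy searchsorted over a sorted
code array). A primer occurrence with ≤ 1 mismatch must contain at least one
exact 10-mer half (pigeonhole), so looking up both halves and verifying
candidates by full IUPAC-aware comparison is complete. Only the forward
strand is indexed; the reverse strand is searched with the reverse-complement
primer, which is equivalent and halves the index. Minus-strand hits
contribute the read's reverse complement to the pileup. One mismatch is
allowed in round 1 only (tolerating a sequencing error or allele inside the
original assembler-derived primer); later rounds match exactly but their
primers may carry ambiguity codes, each of which accepts both component
bases. Ambiguous primer positions are expanded into concrete lookup keys per
half, capped at 16 expansions (a half with > 2 ambiguous positions contributes
no keys; the adjacent-code ban keeps ambiguity density low in practice). An
'N' in a read matches nothing — pileup counts are over {A,C,G,T} only.
Reads with multiple primer occurrences contribute one anchoring per
occurrence, the unbiased convention for the count model.

## Read cleaning

Two reads are PCR duplicates when their first 10 bases are identical and
positional identity over min(len) strictly exceeds 0.90; within a prefix
bucket the first occurrence is kept. Identity is positional (no alignment):
fixed-length short-read data does not warrant gapped comparison. Trimming
starts at the first window of five Phred scores strictly above 30 and stops
at the first position where the cumulative fraction of accurate bases
(Phred ≥ 30, the same threshold — no second one is defined) drops to ≤ 0.5;
reads with no start window or fewer than 10 surviving bases (the duplicate
key length) are dropped. The cumulative-versus-windowed reading of the stop
rule is a documented choice, as is adapter removal being delegated upstream.

## ORF classification

With a protein hit (blastx outfmt-6 tabular, best hit by e-value then
bitscore), classification works in the hit's frame: 3′-complete iff an
in-frame stop codon starts at/after the aligned span; 5′-complete iff an
in-frame ATG precedes the span *and* either an in-frame stop lies upstream of
that ATG or the subject alignment begins within 15 aa of the protein
N-terminus. Without a hit, candidates over all six frames are the
between-stops segments carrying an ATG and/or a terminating stop, ranked by
length (measured from the first ATG when present); start evidence is an
upstream in-frame stop or ≥ 30 nt of 5′ UTR. The 15-aa and 30-nt defaults are
exposed parameters; they stand in for the cited classifier's unpublished
internals and make no claim of bit-compatibility with it.

## Redundancy distance

distance = 1 − M / min(len a, len b), with M the matched positions in the
best end-gap-free overlap alignment of a against b and against revcomp(b)
(match +1, mismatch −1, gap −2; IUPAC-compatible pairs count as matches;
Biopython's PairwiseAligner does the DP). Three numerical choices matter:

* End-gap freedom is granted to exactly one sequence per edge — dovetail in
  either direction or containment (4 configurations, best score wins).
  Freeing both sequences at both edges degenerates into local alignment,
  whose spurious cores make unrelated sequences look ~30 % similar.
* Overlaps scoring below 20 are discarded (M = 0): the best chance dovetail
  window between unrelated 300–600 bp fragments scores ~4 yet can carry ~17–35
  matched columns, which would cap the "no overlap" distance near 0.94
  instead of 1. Real overlaps of ≥ 20 net matching bases are unaffected.
* Each pair is canonicalized (lexicographic minimum over swapping and joint
  reverse complement) before aligning, making the distance exactly symmetric
  and strand-invariant despite tie-breaking among co-optimal tracebacks.

Normalization by the shorter sequence makes containment distance 0, so a
fragment identical over its full length is redundant with its full contig.
Clustering is single-linkage over pairs with distance ≤ d_max (default 0.05,
tolerant of ambiguity codes and rare variants); all-vs-all comparison is
pruned to pairs sharing an exact 20-mer. When pre- and post-extension contig
sets are both supplied, pairs distant before extension but redundant after it
are reported as asymmetric fragments — disjoint 5′/3′ pieces of one
transcript joined up by elongation.

## Quantification and enrichment

Reads are assigned to contigs by exact 20-mer seeds at 10-bp strides plus
full verification, allowing one penalized mismatch; mismatches at read
positions with Phred < 20 are free. For 101-bp reads and ≤ 1 true mismatch
some seed window is error-free, so seeding is complete for the intended
match class. A read matching k contigs equally well contributes 1/k to each;
FPKM = 10⁹ · count / (length · total assigned). Differential classes use an
FPKM floor of 0.1 and log2-ratio cuts of ±2, with a pseudo-FPKM of 0.01
inside the ratio to avoid log(0). GO enrichment between sets A and B is
log2 of the ratio of per-set term frequencies with 0.05 added to the
numerator counts only (it exists to rescue zero numerators; set totals are
far from 0.05). Both orientations are reported rather than fixing a
direction convention.

## UPGMA and tree cutting

Distances are consumed, not computed (protein alignment and distance
estimation live upstream). UPGMA merges the closest pair, places the node at
half the merge distance, and updates distances as size-weighted means; ties
break on the lexicographically smallest pair of cluster labels, making the
tree deterministic. cut_tree partitions below a height h (merges at ≥ h are
undone) or into exactly k clusters (the k−1 highest merges undone). The
species tally categorizes clusters as singleton / one / two / three / all
species and tabulates marginals per species combination; bootstrap support is
out of scope since alignment columns are not held here.

## Synthetic data generator

The generator emulates the data regime the method assumes: transcripts of
0.9–3 kb with a planted ORF (ATG … in-frame stop, 100-nt UTRs, an in-frame
stop just upstream of the ATG), optional 50/50 biallelic sites at a per-bp
rate (default 5 × 10⁻⁴), 101-bp reads from both strands at a chosen coverage
with uniform substitution errors (default 10⁻³) and high-quality Phred
strings decaying over the last 15 cycles, and contigs truncated 150 bp at
each end. Read start positions are drawn past the transcript boundaries and
clipped (minimum 20 bp): random fragmentation of full-length molecules
produces terminal fragments abutting the transcript ends, so real libraries
pile fragment edges up at the termini; without this the pileup depth would
ramp down linearly over the last read-length and terminal bases could never
reach the calling depth. What the generator does *not* model: indels
(substitution-only errors, matching short-read platforms' dominant mode),
coverage bias along the transcript, intron retention or alternative
isoforms, and chimeric assembly artifacts beyond end-truncation. Passing
tests therefore demonstrate the consensus arithmetic, recruitment
completeness and end-to-end recovery under the method's stated assumptions —
not robustness to structurally misassembled input.

Evaluation against the gold standard scores: fraction of truncated bases
recovered (capped at the truncation), per-base identity of elongated spans
(an ambiguity code is correct iff its base set covers the true alleles;
overshoot past the template counts as error), het-site code accuracy, and
ORF class before/after extension.

## Problem sizes and budgets

The acceptance experiments run at the study conditions: 50 transcripts of
0.9–3 kb at 200× error-free coverage with 150 bp truncations for the recovery
check (~180 k reads, ≈ 15 s end to end); 20 transcripts with het rate
5 × 10⁻³ for heterozygote coding (the default rate would plant too few sites
in elongated spans for a stable fraction; the elevated rate is an experiment
design choice, not a generator default); a 10-transcript dataset downsampled
to 10/50/100/200× for depth dependence (nested read subsets, so monotonicity
is not confounded by re-simulation); and 1.5 kb templates with 600 bp
disjoint fragments for the redundancy flip. The acceptance script uses 30
transcripts at the default error rate. All randomness flows from explicit
seeds; reruns are bit-identical.

## Known limitations

* Elongation cannot cross a region whose effective depth is below the calling
  depth; it stops rather than guessing.
* Tandem repeats with period ≤ 20 can recruit self-similar reads
  indefinitely; the rounds cap (default 100) bounds the damage but the
  extension into such repeats is not trustworthy.
* More than two alleles at a site, or allele ratios far from 50/50, fall
  below the code-calling threshold and stop elongation at that end.
* The no-hit ORF classifier ranks partial coding stretches against complete
  ORFs by length; adversarial sequences can make a spurious open stretch
  outrank a short genuine ORF.
* The read-assignment seeder is heuristic for reads with > 1 mismatch plus
  additional low-quality mismatches; externally computed count tables can be
  supplied instead.
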