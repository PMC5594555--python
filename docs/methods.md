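# Methods

This note documents the models and procedures implemented in `famscan`,
the defaults that matter, and what the synthetic benchmarks do and do not
demonstrate about real genome data.

## The synthetic family generator

`famscan.simulate` plants a CEA-family expansion with known ground truth.
Each gene is a cassette of phase-0 exons separated by GT…AG introns:

| exon | length (nt) | content |
|---|---|---|
| leader | 102 | starts ATG |
| N (IgV-like) | 321 | one N-X-T glycosylation sequon at aa 20 |
| A1 / B / A2 (IgC-like) | 279 | three subtypes diverged ~22% each from one IgC ancestor |
| TM | 108 | two reference types ~35% apart (CEACAM1-like vs CEACAM3-like lineage) |
| Cyt (inhibitory) | 90 | two ITIMs, or one ITIM + one ITSM |
| Cyt (activating) | 150 | one ITAM |

Exon lengths are configurable; the defaults are multiples of 3 so that
frame logic stays exact under phase-0 junctions. Intron lengths are drawn
uniformly from 200–1200 nt; introns and spacers are random sequence at
40% GC with the canonical dinucleotides placed explicitly. Coordinates
are 0-based half-open internally; GFF3 output is 1-based inclusive.
Genes are plus-strand by default; a flag reverse-complements cassettes at
random.

Architectures: secreted PSGs are leader+N+A2 with an in-frame stop planted
in the IgC exon — within the final 6 codons for two-domain PSGs, at codon
28–67 for one-domain PSGs (deep enough that the AATAAA polyadenylation
signal placed just downstream of the exon stays within 200 nt of the
stop). Receptor genes carry the full leader…Cyt layout. Pseudogenes get a
stop planted in the N exon. Donor-mutated receptors have the GT after the
TM exon replaced by AT and are truth-labeled nonfunctional.

Paralogs diverge from their subgroup ancestor by i.i.d. per-site
substitution (default rate 0.10, uniform over alternative bases, no
indels by default). Mutations that would create an in-frame stop are
reverted, and motif- and sequon-coding positions are protected, so the
planted truth labels stay exactly decodable from the emitted sequence —
that invariant is what makes downstream scoring exact. N exons descend
from three ancestors (CEACAM, PSG-I, PSG-II; pairwise ~20–35% apart),
giving the three-subgroup structure the phylogeny stage must recover.

Default proportions emulate a strongly expanded vespertilionid-scale
family: 100 genes, 50% pseudogenes (matching the roughly one-to-one ratio
of N exons with and without ORF in the most expanded genomes), 90% PSGs
(membrane receptors are a ~10% minority), activating:inhibitory receptors
1:1, a quarter of inhibitory tails carrying ITIM+ITSM, and 30% of
receptor genes with a mutated donor (about the reported 3-in-8 fraction).
Same spec + seed ⇒ byte-identical FASTA/GFF3/TSV.

**What the generator does not emulate:** repeats, segmental-duplication
mosaics, assembly gaps/artifacts, GC heterogeneity, indel divergence
(available as an extension point, off by default), alternative splice-site
usage, and real intron/intergenic length distributions. Passing the
recovery benchmarks therefore demonstrates correctness of the algorithms
under clean divergence, not robustness to fragmented assemblies.

`evolve_codon_sequences` provides a separate codon-level benchmark
generator: a continuous-time chain over the 61 sense codons in which each
single-base neighbor is reachable at relative rate 1 (synonymous) or ω
(nonsynonymous) and stop codons are unreachable. Rates are normalized so
one unit of branch length equals one expected substitution per codon
averaged over sense codons — ω then shifts the substitution spectrum
without inflating total divergence, which keeps parsimony-based counting
in its accurate regime.

## Exon mining

Seeding uses exact k-mers (default word size 11) against a sorted k-mer
table per contig; seed diagonals are clustered into candidate windows and
each window is aligned with local Smith–Waterman (Biopython's
PairwiseAligner; match +2, mismatch −3, gap open −5 plus −2 per gapped
position; N mismatches everything). Because only the window placement is
heuristic, hits agree with an exhaustive Smith–Waterman scan whenever any
seed word survives in the homologous region; at the default word size
that holds comfortably to ~15% divergence and decays beyond ~25% — which
is exactly why mining iterates through intermediate paralogs.

Significance gates: surrogate E-value `E = K·m·n·exp(−λS)` with pinned
K = 0.1, λ = 0.33 (m = query length, n = total search space), threshold
1e−10, and query cover > 0.5. The constants are calibration-free
surrogates: any monotone transform of the score reproduces the same
decision rule, and pinning them makes the gates deterministic and
testable. On gene-free random contigs the expected false-positive count
at 1e−10 is zero.

Boundary refinement scores candidate (acceptor, donor) pairs around the
homology-projected exon ends (raw alignment ends extended by the
unaligned query overhang — seed queries are complete exons). Candidate
badness is `2·|length − expected| + |ends − projected| + 3 per
non-canonical boundary`, with expected lengths per domain (Cyt admits
both 90 and 150 nt) and tolerance ±6 nt. Non-canonical candidates keep
mutated splice sites representable: a receptor whose donor is mutated is
refined to its homology-projected end and flagged, rather than snapped to
the nearest spurious GT. One ambiguity is irreducible: a random GT at
exactly the expected donor position (probability 1/16 per junction) is
indistinguishable from a canonical donor; the simulation-recovery bounds
absorb this.

Iterative mining adds each round's called exon sequences to the query set
(novel sequences only), masks already-called loci so later rounds only
pay for genuinely new windows, searches 2 kb windows downstream of every
TM call with the cytoplasmic queries, and stops at a fixed point or after
`max_rounds` (default 6 — generous because post-fixed-point rounds are
nearly free, while sparse families can need a chain of intermediates).

## Gene models and architectures

Calls on one contig/strand are chained in transcription order under the
domain grammar leader < N < A1 < B < A2 < TM < Cyt: a model extends only
while the rank strictly increases and the genomic gap stays below 25 kb
(configurable; the bound must exceed intron lengths). The rank rule
enforces the single-N-exon property and separates tandem genes that gap
thresholds cannot (inter-gene spacers can be shorter than introns).

A stop is "terminal" in the IgC exon when the first in-frame stop falls
within the final 6 codons (two-domain PSG); anything earlier truncates
the IgC domain (one-domain PSG). The cutoff operationalizes the
end-of-exon vs within-exon dichotomy, which has no published numeric
boundary. An exon-level ORF is intact when no stop precedes the final
codon. Translation uses the standard nuclear code throughout.

## Motif detection and receptor classes

The consensus patterns (ITIM `[ILVS].Y..[ILV]`, ITSM `T.Y..[VI]`, ITAM
`Y..[LI].{6,12}Y..[LI]`) are configuration, not constants — they are the
standard immunology definitions and can be overridden per call; the ITAM
spacer bounds 6–12 follow common usage. Two specificity rules order
overlapping hits: a tyrosine engaged by an ITAM half-site (under any
admissible spacer, not just the greedy match) is not separately reported
as ITIM/ITSM, and an ITIM sharing its tyrosine with an ITSM is reported
as ITSM only. Signaling classification: ITIM+ITSM ⇒ inhibitory-ITSM,
ITIM ⇒ inhibitory, else ITAM ⇒ activating; a mutated donor junction
downstream of the TM exon overrides everything to nonfunctional, as does
a tail with no motif at all. TM type is the best local-alignment score
against the CEACAM1/CEACAM3 TM references (the miner's scoring scheme,
for consistency); ties break by lexical reference order and are recorded.

## Phylogenetics

Tree building is distance-based by design: every decision downstream of
the tree (subgroup membership, counting ancestors) depends on clustering
structure, not branch likelihoods, and neighbor joining is exact on
additive matrices — a property the test suite exercises directly.
Likelihood tree search is a deliberate non-goal; the NJ tree is the
extension point where one could be plugged in.

Progressive alignment follows a k-mer-distance guide (UPGMA-style merge
order) with affine-gap profile–profile alignment (nucleotide scoring as
in the miner; BLOSUM62 with −11/−1 gaps for proteins). Codon mode aligns
translations and threads nucleotide triplets back through the gapped
protein rows, so no codon is ever split; rows with internal stops are
aligned but flagged. Distances: p-distance and Jukes–Cantor (saturated
proportions clamped just below 3/4). Neighbor joining comes from
scikit-bio; negative branch-length estimates are clamped to zero with a
warning. Bootstrap resamples alignment columns (whole codons for codon
alignments), default 500 replicates, seeded; supports are bipartition
frequencies in [0,1], written as internal node labels. Subgroups are
assigned by smallest patristic distance to anchor leaves, which makes the
labels invariant to rerooting; a monophyly flag per label reports whether
the group forms a clade.

## Selection analysis

Site counts: per codon position the synonymous fraction is synonymous
single-base changes over non-stop single-base changes, so each codon
contributes exactly 3 sites (the stop-path renormalization). Pair counts
average Sd/Nd over all orderings of the differing positions that avoid
stop intermediates; if every ordering is blocked the average falls back
to all orderings. The pairwise dN/dS applies the Jukes–Cantor correction
to pS and pN and reports NaN on saturation (p ≥ 3/4) or dS = 0, alongside
the uncorrected counting ratio pN/pS.

The tree-aware analysis reconstructs ancestral codons per site by Fitch
parsimony with ties broken by lexical codon order — a deterministic,
reproducible substitute for likelihood-based ancestor counting, and the
package's declared deviation from likelihood machinery. On a two-leaf
tree the branch counts collapse to the pairwise counts exactly, and the
mean equals the uncorrected pairwise ratio (the counting equivalence; the
JC-corrected pairwise ratio differs by the multiple-hit correction, which
the tree-wide mean deliberately does not apply). Codon columns containing
any gap are skipped (complete deletion; pairwise deletion is a flag), and
rows with internal stops are excluded and logged. Per-site classification
uses a two-tailed binomial test of the (rounded) nonsynonymous count
against the neutral expectation EN/3, at raw α = 0.1, with
Benjamini–Hochberg q-values reported alongside; it is a counting
substitute for random-effects likelihood site models and is labeled as
such in outputs, and no recombination screening is performed (a warning
says so). The cumulative profile averages per-pair, per-codon Sd and Nd
(pairwise deletion) so its final values equal the mean pairwise totals;
the indel curve counts gap openings per codon position.

Known biases: parsimony undercounts multiple hits, attenuating dN/dS at
high divergence — the benchmark tree (total length ≈ 1 substitution per
codon) stays in the regime where ω = 1 is recovered within ±0.2 and ω = 3
clearly exceeds 1.5. The binomial site test ignores branch-length
heterogeneity and is less powerful than likelihood site models.

## Problem sizes and determinism

The simulation benchmarks run 200 planted genes (≈650 kb of contigs) for
recovery scoring, 600-codon alignments on a fixed 8-taxon tree for the
ω-recovery check, and 20-to-60-gene genomes for the unit fixtures —
sizes at which every stage completes in seconds to a couple of minutes on
one CPU while keeping counting statistics tight. All randomness flows
from a single seed (`numpy.random.default_rng`); the pipeline derives
per-stage sub-seeds from it, writes a manifest of parameter values and
output content hashes, and identical configurations reproduce
byte-identical tracked outputs.

## Limitations

Real wgs assemblies bring fragmentation (genes split across contigs are
retained only as partial models), sequencing N runs (alignments treat N
as mismatch; calls containing N are flagged), and non-canonical splice
sites beyond the mutated-donor case modeled here. The architecture rules
assume the family's canonical domain grammar; heavily rearranged loci
fall out as orphan models rather than being forced into a class. UTR
structure beyond the polyadenylation-signal check, promoter analysis and
expression validation are out of scope.
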