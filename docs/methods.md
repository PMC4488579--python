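# Methods

## Overview

`estqtl` implements a desk-scale version of an expressed-sequence /
QTL-integration analysis for water-deficit stress genetics in cotton. The
pipeline is: (1) cluster EST reads into tentative consensus sequences (TCs);
(2) anchor TCs to a 13-chromosome consensus genetic map by homology to
sequence-tagged-site (STS) markers; (3) merge trait-linked 2-LOD QTL
confidence intervals into disjoint genomic regions and mark TCs whose
anchored loci fall inside them; (4) test stress-gene enrichment inside the
regions with an exact binomial tail; (5) grade candidate genes by evidence
level; (6) project regions onto syntenic reference-genome segments. A
seeded generator produces synthetic studies with known ground truth so each
stage, and the chain of all of them, can be validated.

## Alignment model

Both the assembler and the anchorer use a *gap-free* placement model: read
b is slid across read a at every offset, in both orientations, and a
placement is scored by its matching bases over the overlapped span (`N`
never matches). A placement is accepted when the span reaches the minimum
overlap and identity (matches/span) reaches the minimum identity:

* assembly: identity ≥ 0.90 over ≥ 80 bp;
* anchoring: identity ≥ 0.90 over ≥ 100 bp.

Rationale for gap-free: the acceptance rule is expressed purely in identity
and overlap terms, substitution-only mutation makes an exhaustive-offset
oracle exact, and the brute-force scan then *is* the specification of the
operation — the production path must agree with it bit for bit, which the
test suite enforces on random instances. The cost is that indels are not
realigned (a non-goal), and chimeric reads whose flanks disagree dilute
overlap identity rather than being clipped, which is the conservative
direction for clustering.

Among accepted placements the assembler keeps the one with most matches
(ties: higher identity, then smaller offset); the anchorer ranks by
identity, then overlap length, then forward orientation — anchoring asks
"how similar", assembly asks "how much shared sequence".

### Exact seeding

Scanning every offset for every pair is quadratic, so candidate offsets are
restricted to diagonals carrying a shared exact k-mer. By pigeonhole, an
accepted placement of span L with m mismatches contains an exact run of
ceil((L−m)/(m+1)) bases; minimised over admissible L this gives the longest
seed that cannot miss a qualifying placement — 8 bp for 0.90/80 bp and 9 bp
for 0.90/100 bp. Requested seed sizes are clamped to this bound, making the
filter provably lossless rather than heuristically safe. The bound is
computed with the same floating-point comparison the scanner uses, so
boundary cases (exactly 90% identity) are treated identically.

## Assembly

Clusters are single-linkage components of the accepted-overlap graph:
deterministic, order-independent, and equal to "one cluster per transcript"
on clean data. One consensus is called per cluster by breadth-first offset
propagation from the longest member (ties by read id), orientation-
normalised to that anchor; non-tree overlaps disagreeing with the layout by
more than 5 bp are reported as layout warnings and the spanning-tree
offsets kept. Columns are called by majority base with lexicographic
tie-break (A < C < G < T), so consensus builds are reproducible. The
consensus is reported in the anchor read's orientation; strand of origin is
unknowable for a cDNA cluster, and downstream anchoring searches both
strands anyway.

## Anchoring and colocalization

All threshold-passing (TC, marker) pairs are retained — no best-hit
pruning — because multi-locus transcripts are a real feature of a
palaeopolyploid consensus map and the analysis explicitly reports them.
Summary statistics (TCs mapped, loci hit, multi-TC loci, multi-locus TCs)
are set cardinalities over the hit table.

QTL confidence intervals are merged per chromosome by transitive union of
overlapping *or touching* closed intervals; merging is idempotent and the
result is disjoint. A locus colocalizes with a region when its cM position
lies in the closed interval — boundary-inclusive, because printed candidate
tables place loci exactly on interval edges (a locus at 122 inside
77.5–122.2, a region starting at a locus position of 36.7). Coordinates are
handled at the 0.1 cM precision they are printed with. Per-region summary
rows count a multi-region TC once per region; the global contingency
deduplicates, and with disjoint regions whose TC sets do not overlap the
two conventions agree.

## Enrichment

The contingency partitions mapped TCs into inside/outside zones, counting
annotated (non-empty function label) and stress-annotated transcripts. The
headline statistic is the exact one-sided upper tail P(X ≥ x) for
X ~ Bin(n, p): x = inside stress count, n = inside annotated count,
p = outside stress rate. Terms are evaluated through log-gamma, rescaled by
the largest log term, and summed with compensated (`math.fsum`) summation —
relative error stays near machine precision down to 1e-15 tails, verified
against a 60-digit arbitrary-precision oracle at 1e-12 relative tolerance.

The default background rate is the unrounded outside ratio; a
`report_3dp` mode rounds p to three decimals first, matching the convention
of quoting the rate to three decimals in a report (the tail value at this
magnitude is sensitive to that rounding: 0.145 gives 1.4812e-15,
160/1104 gives 1.4383e-15). Percentages are printed at one decimal,
half-away-from-zero. Two cross-checks are provided but never the default:
a stress-label permutation null (empirical p = (1 + #{null ≥ obs})/(B + 1),
ties counted conservatively) and a hypergeometric (Fisher-style) tail.
Multiple-testing across traits is out of scope — one global test is
performed.

## Candidate classification

Three binary evidence categories — unique to stress-treated libraries,
differentially expressed, QTL-colocalized — map to levels: one category is
Level I, two Level II, three Level III; a prime mark (I′, II′) flags
stress-related gene ontology and is independent of the level. Transcripts
with no category are retained with level "none" so reports can audit the
full universe. Because the final short-list in a real study involves
judgement beyond these flags, the module exposes a small, safe filter
expression language (`level >= I and (prime or differentially_expressed)`)
instead of hard-coding a selection rule.

## Synteny projection

Syntenic segments arrive as input intervals on the cotton map tagged with
reference block ids and reference gene annotations; synteny *detection* is
out of scope. A region matches every segment overlapping its closed
interval on the same chromosome, including single-point abutment —
consistent with the colocalization boundary rule. Reference genes are
deduplicated within a region across its matched segments. Because
"associated with a region" can mean any overlap or full containment,
reports carry both counts.

## Synthetic-data generator

The generator emulates the structure of the motivating study at desk scale:
13 chromosomes of 160 cM; STS markers (default 300, 400 bp random
sequences) at uniform positions; trait-coded QTLs (default 12) with
interval widths uniform in 6–20 cM, matching the spread of printed
confidence intervals; ten cDNA libraries with the study's tissue/treatment
design (etiolated cotyledon, seedling under control/drought/chilling,
ovary, irrigated and droughted bolls, stem); reads (default 60 per library,
150–500 bp) sampled from gene templates with substitution errors (default
1%) and random strand; differential-expression labels with the
induced/repressed/reciprocal class split of the study's 2106 stress-
responsive transcripts (879:1163:64); and syntenic segments with annotated
reference genes.

Gene models (default 200) sit *on* markers: the 600–2000 bp template embeds
the marker sequence, so anchoring can recover the true locus, and the
gene's truth position is the marker's cM position. Templates are long
enough for 100 bp anchoring overlaps and multi-read coverage. The one
generative effect the analysis is meant to detect is explicit: with
baseline inside-region placement probability p0 (the inside fraction of
markers), a stress-annotated gene's inside odds are p0/(1−p0) multiplied by
θ (`enrichment_odds`); θ = 1 is the null. This makes the generative odds
ratio identifiable by the downstream contingency, and the test suite checks
monotone recovery over θ ∈ {1, 2, 4, 8} and bootstrap-CI coverage at
n = 5000 genes.

Stress-treated libraries oversample stress genes ×3 by default — the real
sampling model behind stress-library-unique transcripts is unknown, so the
factor is a free parameter, not an inference target. Reads are
reverse-complemented with probability 0.5 to force strand handling
downstream. Each stage draws from a child stream of the master seed keyed
by a fixed stage index (`numpy` `SeedSequence(seed, spawn_key=(stage,))`),
so regenerating one stage never perturbs another; identical config + seed
is byte-identical. `make_genes(..., with_templates=False)` skips template
synthesis for placement-only studies and provably leaves every truth column
unchanged, because all placement variates are drawn before any template
nucleotide.

What the generator does **not** emulate: microarray intensities and
quality scores, chromatograms, indels, chimeric reads, homoeologous
subgenome structure, and realistic marker/gene sequence composition (all
sequence is i.i.d. uniform ACGT). Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artefact of real EST data.

## Numerical and procedural choices

* Identity thresholds compare `matches/span >= min_identity` in ratio form,
  so a span at exactly the printed threshold (e.g. 9/10 at 0.90) is
  accepted regardless of binary rounding of the product form.
* Consensus ties, anchor-read ties and hit ordering all have documented
  deterministic tie-breaks; two runs of any stage are byte-identical.
* cM values print with one decimal; percentages with one decimal
  (half-away-from-zero); probabilities in scientific notation with three
  significant digits, full precision retained internally.
* Degenerate inputs: empty read sets, zero markers, zero QTLs and empty
  label tables all produce valid empty outputs; zero chromosomes, θ ≤ 0,
  read lengths exceeding templates, and QTL widths exceeding chromosomes
  are configuration errors.

## Validation scales

The test suite runs the aligner-vs-brute-force oracles on hundreds of
random pairs at 150 bp (assembly) and 120–300 bp (anchoring), clustering
oracle equivalence on ≤ 12 reads of ≤ 60 bp, locus-recovery on 100-gene
clean simulations, null calibration of the permutation and binomial tests
on 200 synthetic datasets of 1000 genes (KS uniformity at α = 0.01;
rejection-rate consistency with 5% by binomial test), and θ-recovery at
5000 genes. These sizes keep the full suite under half a minute on one CPU
while leaving each check statistically meaningful; they are the package's
chosen validation conditions, and larger studies only tighten the same
comparisons.

## Known limitations

* The gap-free model understates identity in the presence of indels; real
  EST data would need an indel-aware aligner and quality-aware consensus.
* Single-linkage clustering can chain distinct transcripts through a shared
  conserved domain; the motivating use accepts this (multi-TC loci are
  expected and reported).
* The binomial test treats the background rate as known; the permutation
  null is the appropriate cross-check when outside counts are small.
* The printed reference tail value is reproducible only as an upper bound
  on the exact tail; the package reports its own exact value alongside.
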