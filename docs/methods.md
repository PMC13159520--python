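# Methods

`inlinebc` implements the computational side of a dual in-line barcoding
workflow for amplicon sequencing: every read of a pair begins with a
5-bp leader (`GCATC`), an 8-bp sample barcode and the target-specific
16S primer, so demultiplexing happens inside the read rather than in a
separate index read. This note records the models, parameter choices and
numerical conventions behind each component, and what the synthetic data
used in testing does and does not establish.

## Construct model and catalogues

A barcoded primer is the triple (leader, barcode, primer). Leaders and
barcodes are plain `ACGT`; primers may use IUPAC degeneracy (the V3-V4
pair 338F/785R and the V4-V5 pair 519F/915R ship as constants). A
catalogue holds ordered forward and reverse primer lists; under
`full_cross` pairing it labels `|F| x |R|` samples. Catalogue invariants
(unique ids, unique barcodes per direction, one barcode length) are
enforced at construction, because every downstream guarantee — notably
the ambiguity semantics of matching — assumes them.

Two file dialects are supported. The FASTA dialect stores barcodes only,
with direction inferred from a `Forward_`/`Reverse_` id prefix and
leader/primer supplied by the caller — matching how per-domain barcode
lists are distributed in practice. The TSV dialect carries per-entry
leader and primer columns so the same machinery serves non-16S assays.

`min_primer_count(n)` solves the plate-layout arithmetic: among integer
factorizations `f * r = n` (optionally capped by pool sizes, optionally
relaxed to `f * r >= n`) it minimizes the number of unique primers
`f + r`, breaking ties toward the squarer grid and then the smaller
forward count. For `n = 96` the optimum is 8 + 12 = 20.

## Demultiplexing

Matching is sequence-only; base qualities are never consulted. The
leader is anchored at position 0 and must match exactly by default (a
tolerant variant exists but is config-only). The full barcode must be
aligned — no partial-prefix matches at read ends — and two distance
modes exist:

* **Substitutions only** (`0err`, `1err`, `2err`): Hamming distance over
  the 8-bp window after the leader.
* **With indels** (`1err+indel`, `2err+indel`): a unit-cost alignment of
  the whole barcode onto a prefix of the window (length ±`max_indels`),
  with *separate* budgets for substitutions and indels. Budgeting
  separately (1 substitution plus 1 indel, rather than 1 edit total) is
  a deliberate choice where the convention is ambiguous; it is what the
  mode labels promise.

The nearest admissible barcode wins; if two barcodes tie at the minimal
admissible distance the call is `unknown`, never an arbitrary pick —
ambiguity must not become cross-sample contamination. When both a
substitution-only and an indel interpretation explain a window equally
well, the substitution alignment is preferred so trimming coordinates
stay at the nominal barcode length. Primer trimming allows up to
`floor(0.10 * |primer|)` mismatches with IUPAC codes counted as matches;
a failed primer match flags the read (default) or rejects it.

A useful consequence of the ambiguity rule is a safety theorem: if the
minimum pairwise barcode distance within a direction exceeds twice the
error tolerance, a mate whose *actual* errors stay within the budget can
never be assigned to a wrong barcode (triangle inequality). The theorem
is conditional — a read mutated beyond the budget carries no guarantee —
and `validate_separation` reports exactly this margin for a catalogue.
Tests assert the conditional form, since per-base error injection
occasionally produces reads with more errors than the budget.

Reports tally every input pair exactly once into a (forward, reverse)
contingency table with `unknown` margins; assigned fractions are
non-decreasing along the nested-budget chains `0err ⊆ 1err ⊆ 1err+indel`
and `1err ⊆ 2err ⊆ 2err+indel`. `1err+indel` and `2err` are *not*
comparable: an indel-carrying read is assigned by the former only.

## Recovery statistics

With equal pooling, reads should spread uniformly: 1/N per barcode or
pair, and 0 for `unknown`. Observed shares are computed over *all* reads
including unknowns, so the unknown rate and per-barcode bias share one
denominator. Across samples the package reports mean ± SD (sample SD,
n−1 denominator; a single sample yields SD 0 with a warning) and flags
categories where |mean − theoretical| > 2 SD. When only a fraction `c`
of a catalogue's pairs was actually run, observed/expected ratios are
multiplied by `c`, restoring 1.0 for a uniformly covered partial panel;
this correction is an interpretation of common practice and is labelled
as such. No significance test is bundled with the core summary (a
chi-square helper exists separately); the deviations are descriptive.

## Diversity and ordination

Alpha diversity uses Hill numbers, `D_q = (Σ p_i^q)^{1/(1−q)}` with the
`q→1` limit `exp(−Σ p_i ln p_i)`; natural logarithms throughout so that
`D_1 = exp(H)` and Pielou's `J = H / ln S` are mutually consistent.
Richness counts taxa with nonzero counts after any rarefaction, not
catalogue size. `J` is undefined (NaN, not 0) for a single-taxon
library. Evenness is also reported as the Hill ratios `Eq1 = D_1/D_0`,
`Eq2 = D_2/D_0`.

Rarefaction draws a multivariate hypergeometric sample (without
replacement) per library to a common depth, dropping shallower libraries
with a warning; the draw is fully determined by the seed. The intended
depth rule is the minimum post-filter library depth of the dataset at
hand.

Bray-Curtis is `Σ|x−y| / Σ(x+y)` (scipy's implementation behind the
module's validation). The distance-to-reference summary designates one
library per sample as reference — named, or drawn seed-deterministically
and always returned so the choice is logged — and computes every
library's distance to it.

PCoA is classical metric scaling: double-center `B = −½ J (D∘D) J`,
eigendecompose, keep positive eigenvalues, scale eigenvectors by their
square roots. Negative eigenvalues (non-Euclidean dissimilarities) are
dropped without Cailliez/Lingoes correction and their summed magnitude
is reported, so the user can judge how non-Euclidean the input was.
Variance fractions are over positive eigenvalues and non-increasing.

## Panel selection

Each barcode pair is scored per sample on eight metrics in a canonical
order: PCR yield (ng/µL), `q0`, `q1`, `q2`, `J`, `Eq1`, `Eq2`, and
Bray-Curtis distance to the reference pair. Metrics have incommensurate
units, so each sample's matrix is z-scored per metric (zero-variance
columns dropped with a warning) before PCA. The smallest number of
components reaching 90% cumulative explained variance is retained,
capped at 3; k-means with k = 2 and 10 seeded restarts labels the pairs.
Clustering is per sample by default — the co-clustering definition
requires per-sample labels — with a pooled mode (all samples stacked,
one clustering) available behind a flag.

Consensus: the co-clustering frequency of two pairs is the fraction of
samples placing them in the same k-means cluster (denominator: samples
where both are unmasked). `1 − frequency` is clustered by average
linkage and the tree is cut into `n_meta = 2` metaclusters; the cut
count is a default, not a derived quantity, since no principled cut
criterion presents itself at two behavioural regimes.

**Choosing the best metacluster.** The score of a metacluster is its
mean internal co-clustering frequency. Used raw, this measure has a
trap: pairs that fail in a correlated way form a small cluster whose
members sit far from every per-sample k-means boundary, so the *failing*
cluster is systematically tighter (observed: ~0.97 vs ~0.93 for the
well-behaved majority). Cohesion gaps of that size are per-sample
label-flip noise, not evidence of better performance. The implementation
therefore treats cohesion means within 0.1 of the maximum as tied and
prefers the larger metacluster among the tied ones — among comparably
consistent groups, the majority behaviour is the robust panel. An
explicit `best=` override is available when the caller wants to
designate the reference cluster by other evidence.

**Grid search.** The panel must be a plate grid: `|F'| × |R'|` equal to
the requested panel size exactly (96 by default). Every feasible
factorization is scored by the fraction of grid pairs inside the best
metacluster. For a fixed reverse subset the optimal forward subset is
just the top rows by good-pair count (the objective is a submatrix sum),
so the exact optimum is found by enumerating subsets on the side with
fewer combinations and solving the other side greedily — exact, and
cheap for realistic pools (≤ 13 × 17 needs at most a few thousand
subsets). Only when the subset count exceeds a cap (200,000) does a
deterministic alternating greedy search take over, flagged
non-exhaustive in the result. Tie-breaks are total primer count, then
lexicographic ids, making the whole pipeline reproducible bit-for-bit
under a fixed seed.

## Synthetic data

The read generator builds each mate as leader + barcode + primer +
amplicon fragment (forward construct on mate 1, reverse on mate 2, the
fragment reverse-complemented), truncated to the read length (default
300 nt, as in 2 × 300 paired-end runs). Amplicon templates are random
sequences from a mock community — even (mirroring defined standards such
as a 21-strain gut mock), staggered over two decades, or a Dirichlet
draw; default template lengths 447/397 nt match the V3-V4 and V4-V5
amplicons. Substitutions, insertions and deletions are injected per
base, independently for the tag construct and the amplicon, and every
read's true pair, taxon and per-segment injected errors are logged in a
truth table. Tag jumping is modelled as a seeded reverse-barcode swap at
a configurable rate — the canonical post-pooling mechanism — which is a
simplification (forward jumps and chimeric causes are not modelled).
Qualities are constant Phred 35 by default because calling ignores them.

The planted-metrics generator draws good pairs from per-metric Gaussian
baselines (yield 30 ± 5 ng/µL; mock-like diversities such as q1 5.25 ±
0.6; high evenness; small reference distance) and shifts a designated
fraction of bad pairs by a given number of pooled SDs on chosen metrics
(default: q1 and the reference distance). Its default layout is six
samples — three source communities under two library protocols — at
whatever pair count the caller's catalogue implies; acceptance testing
uses the full 136-pair panel scale. Consensus recovery is strongly
sample-limited: with only three samples co-clustering frequencies are
quantized to thirds and single-sample k-means errors propagate, while at
six samples the planted split is recovered with ARI ≥ 0.9 in 100/100
seeded replicates.

What passing these tests shows — and does not. The simulator validates
the bookkeeping, the error-tolerance contracts, the statistical
machinery and the selection procedure end to end with known ground
truth. It does not emulate PCR chemistry (chimeras, polymerase bias, GC
effects), quality-dependent errors, or biologically structured
communities; conclusions about real libraries still require empirical
validation on mock communities.

## Problem sizes and determinism

Stochastic tests run at 10^5 read pairs for the round-trip and safety
properties, 10^2 seeded replicates for recovery experiments, and
full-panel scale (136-156 pairs) for selection. Every random element —
read generation, rarefaction, reference choice, k-means initialisation —
consumes an explicit integer seed, and identical inputs plus seeds give
byte-identical outputs, including FASTQ files, reports and dendrogram
heights.

## Known limitations

* No orientation rescue: forward tags are only sought on mate 1,
  reverse on mate 2, as the library structure is asymmetric by design.
* Partial assignments (one mate unknown) are reported but their reads
  are routed to the unknown bin, not salvaged.
* Primer trimming tolerates substitutions only (no indels in the primer
  segment); reads failing it are flagged rather than re-aligned.
* The grid selector produces pure grids only; irregular panels (a grid
  plus extra combinations) are out of scope.
* Hierarchical metaclustering inherits average linkage's known
  sensitivity to outlier rows; the `n_meta = 2` default should be
  revisited when more than two behavioural regimes are plausible.
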