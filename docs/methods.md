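# Methods

This note documents the models and numerical conventions behind
`ampliconkit`, the parameters that matter, the design choices that were
genuinely open, and what the synthetic-data tests do and do not show.

## Word-sharing similarity (S_ab)

Two sequences are compared by the unique overlapping 7-mers they share:
S_ab = |W_a ∩ W_b| / min(|W_a|, |W_b|). Words are taken from clean
(ACGT-only) windows; a window containing an ambiguity code contributes no
word. Skipping rather than expanding degenerate windows keeps word sets
bounded and matches word-lookup practice; a sequence consisting mostly of
Ns can therefore have very few words and a noisy score. Both query
orientations are scored and the better one kept per reference. Ranking
ties break by shared-word count, then reference id, so output order is
reproducible. The normalization by the *smaller* unique-word count makes
the score robust to partial-length queries: a fragment identical to part
of a full-length reference still scores 1.0.

## Naive Bayes classification with bootstrap confidence

Training over N sequences with genus labels builds, for every 8-mer w:

- a word prior  P_w = (n(w) + 0.5) / (N + 1), where n(w) is the number of
  training sequences containing w at least once;
- per genus g with M_g training sequences, a conditional
  P(w | g) = (m_g(w) + P_w) / (M_g + 1), where m_g(w) counts that genus's
  sequences containing w.

A query with V word positions is scored per bootstrap trial by drawing
⌊V/8⌋ positions with replacement and summing log P(w | g) over the drawn
words for every genus; the top-scoring genus receives the trial's vote.
When g genera tie for the top score the vote is split 1/g, so each trial
contributes exactly one vote regardless of tie multiplicity — without the
split, tied genera would each collect full votes and confidence would be
over-predicted. Confidence at an ancestor taxon is the summed vote
fraction of all genera beneath it, hence monotone non-decreasing toward
the root. Defaults: word size 8, 100 trials, report cutoff 0.8; a lower
cutoff (exposed as a flag) trades precision for coverage on short reads.
Classification cost scales with the number of genera, not training
sequences: the model stores one log-conditional row per genus.

The two-library comparison tests each taxon's counts x₁ of n₁ versus x₂
of n₂. When the pooled expected count in the smaller library,
(x₁+x₂)·min(n₁,n₂)/(n₁+n₂), is below 20, an exact two-sided binomial test
of x₁ out of x₁+x₂ at success probability n₁/(n₁+n₂) is used; otherwise a
2×2 chi-square without continuity correction. The two tests agree closely
when taxon counts are small relative to library sizes (the usual regime);
the exact test conditions on x₁+x₂ while the chi-square uses the full
margins, so for abundances that are a sizable fraction of the library the
approximate p can deviate — the threshold of 20 keeps the exact test in
charge precisely where that matters.

## Primer matching

Primers (≤ 64 IUPAC symbols, one machine word) are matched semi-globally —
the whole primer against any target substring — under unit-cost
Levenshtein distance using the Myers bit-vector recurrence, giving the
distance at every target end position in O(n) word operations. A primer
symbol matches a target symbol when their IUPAC expansions intersect; a
target N matches every primer position. Runs of adjacent end positions
within the distance budget are reduced to the first local minimum, so one
site is reported per locus rather than a smear of neighboring ends; the
matched span is recovered by a small reverse DP restricted to the
feasible window, and its edit distance always equals the reported one.
Minus-strand sites are found by matching the reverse-complemented primer
on the plus strand, keeping all coordinates plus-strand and 1-based.
In-silico PCR pairs plus-strand forward hits with minus-strand reverse
hits strictly downstream (and the strand-swapped case); nested and
overlapping candidate amplicons are all reported.

## Paired-end assembly

The reverse read is reverse-complemented and slid across the forward
read. With per-base error probabilities ε = 10^(−Q/10), each overlap
column contributes

- agreement:     log[(1−ε₁)(1−ε₂) + ε₁ε₂/3]
- disagreement:  log[(1−ε₁)ε₂/3 + ε₁(1−ε₂)/3 + 2ε₁ε₂/9]

and the offset with the maximum summed log-likelihood wins; exact ties go
to the smaller overlap, then the shorter amplicon (conservative). Offsets
where the reverse read starts before the forward read, or the forward
read runs past the amplicon end, are read-through layouts (the amplicon
is shorter than a read); the overhanging bases — adapter sequence — are
trimmed. This enumeration is our interpretation of "complex overlap
layouts"; scoring is implemented as one pairwise column matrix with
diagonal (offset) sums, so all offsets are evaluated exactly.

Overlap positions get posterior qualities. Agreeing bases:
ε′ = (ε₁ε₂/3) / (1 − ε₁ − ε₂ + 4ε₁ε₂/3), which always improves on both
inputs (two Q20 observations of the same base combine to ≈ Q45).
Disagreeing positions keep the higher-quality base with
ε′ = 1 − (1−ε_hi)(ε_lo/3)/Z, Z = (1−ε_hi)(ε_lo/3) + (ε_hi/3)(1−ε_lo) +
2(ε_hi/3)(ε_lo/3) — the three-hypothesis Bayes rule under a uniform base
prior — which always costs confidence (Q30 against a disagreeing Q10
drops to ≈ Q20). Posterior Q values are rounded to integers and clamped
to [2, 93] for FASTQ emission.

An assembly is rejected when no offset reaches the minimum overlap
(default 10 columns) or when the best offset's mean per-column
log-likelihood falls below −1.0: true overlaps score near 0 per column
even at moderate quality, while random alignments sit near −1.05, so the
floor separates the two regimes without rejecting low-quality but genuine
overlaps. Whole reads are summarized by the read Q score,
−10·log₁₀(mean ε) over all positions; the recommended filter range is
25–27 and the paired-mode default is 27. Because the score ties break
toward shorter overlaps, highly repetitive amplicons (e.g. long
homopolymers) can assemble at a shifted, equally consistent offset — an
inherent ambiguity of likelihood-based overlap detection, not a defect
the scorer can resolve.

## Initial processing

Paired runs are assembled first, then reads are demultiplexed by sample
tags anchored at the read start (unique best tag within the edit budget;
equal-distance ties go to the unmatched bin), tags and forward primers
are trimmed (primer located semi-globally within the first
len(primer)+max_edits bases), optionally the reverse complement of the
reverse primer is trimmed from the 3′ end, and reads are filtered in the
fixed order length → ambiguous bases → read Q so each removed read has
exactly one recorded reason. The filter report balances by construction:
input = assembly failures + tag-unmatched + per-sample (passed + removed).
Default thresholds (min length 50, max Ns 0, read Q 20 single / 27
paired) are exposed as flags; only the paired read-Q default follows the
recommended 25–27 range, the rest are ordinary practice.

## Clustering

Distances are computed on model columns only, as mismatches divided by
comparable columns (both records non-gap). Pairs with fewer than 25
comparable columns are skipped — a guard against spurious distances from
barely-overlapping partial sequences. Distances above the cutoff
(default 0.15) are dropped; the rest are bucketed by a quantization step
(default 0.0025, an eighth of the common 2% reporting increment). The
buckets are a counting sort: edges come out in ascending distance order
without an O(E log E) comparison sort, keeping the whole pipeline O(n²),
and each bucket can spill to disk independently. The outer loop accepts a
row range, and row-range partitions concatenate exactly to the single-run
result, which is the contract a multi-node run needs.

Complete linkage consumes buckets in ascending order, counting cross
edges between current clusters: A and B merge at quantized distance d the
moment the seen-edge count reaches |A|·|B| — i.e. exactly when every
cross pair is within d. Merges cascade within a level because combining
counters can complete other pairs. With distinct pairwise distances this
reproduces textbook complete linkage exactly (property-tested against an
independent implementation); when several pairs share a quantized level
the partition can depend on merge order within the level, an ambiguity
inherent to complete linkage with ties — the edge-counting order used
here is deterministic, so results are reproducible.

Dereplication (identical model-column strings collapse, counts conserved)
defines the unit of clustering. Representatives minimize the sum of
squared distances to the rest of their cluster, ties to the smaller id.
OTU tables are cluster-by-sample integer matrices; BIOM 1.0 sparse JSON
is written and read directly (it is a small documented JSON schema), and
round-trips losslessly.

## Diversity

Shannon uses the natural log (base-2 available by flag). Chao1 defaults
to the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) so zero doubletons
are well-defined; the classic form errors in that case rather than
silently dividing by zero. Jaccard and Sørensen are incidence-based (a
flag returns distances instead of similarities). Rarefaction is the exact
hypergeometric expectation E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], with
binomial coefficients in log-gamma space for stability at realistic N.

## Defined-community error rates

Reads are matched to their best reference by S_ab over both strands, then
aligned semi-globally (free end gaps on the read; match +1, mismatch −1,
gap open −4, gap extend −1 — conventional values, exposed as parameters).
Substitutions, insertions and deletions are counted inside the read's
aligned span with equal weight and also reported separately by class; the
per-read rate is errors over aligned columns, and the aggregate rate is
length-weighted. Stratifying by a read-Q threshold reproduces the
qualitative error-rate-versus-filter curve on synthetic data.

## Synthetic data: what it emulates, what it does not

The community simulator mutates a random root gene once per genus (the
genus ancestor, at the inter-genus divergence, default 3%) and each
reference from its ancestor (intra-genus divergence, default 0.5%) —
substitutions only, uniform over positions and alternative bases. The
read simulator takes primer-anchored fragments (always the reference
prefix), applies a position-dependent Q profile (default linearly
decaying 38 → 25 over 250 bases, a plain stand-in for real quality
decay), and injects substitutions at exactly the Phred-implied rates; a
truth table records every injected error. Fragments shorter than the read
exercise read-through layouts, with a fixed adapter filling the
remainder.

Deliberately absent: indel sequencing errors, chimeras, quality-dependent
base-call biases, position-correlated errors, variable fragment starts,
abundance skew, and real taxonomic structure (uneven ranks beyond the
3-level Root/domain/genus tree the simulator emits). Passing tests
therefore show the algorithms are implemented correctly and calibrated
under their own model assumptions — not that real MiSeq runs will match
the simulated error rates. The default study sizes (5 genera × 8
references of 450 bases; 2000 paired 250-base reads over 400-base
fragments) are small enough to run routinely while leaving each genus
hundreds of reads for stable recovery statistics.

## Numerical conventions and degenerate inputs

- FASTQ offsets: 33 default, 64 by flag; qualities clamped to [0, 93].
- `U` is normalized to `T` on input; case is significant only in model
  alignments.
- Alignment gaps: `-` in model columns, `.` in insert columns; both are
  gaps for distance purposes.
- Empty word sets (no clean 7-mer window) make S_ab undefined: searches
  return no hits and the intake screen discards the sequence.
- The classifier requires queries of at least the word size (8); shorter
  queries error rather than returning a meaningless root assignment.
- `lca` of an empty set, rarefaction beyond the sample total, classic
  Chao1 with F₂ = 0, and cluster cutoffs beyond the computed distance
  cutoff all raise informative errors rather than extrapolating.
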