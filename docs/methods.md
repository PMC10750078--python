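# Methods

## The classification model

TF binding is modeled with a gapped k-mer support vector machine. A
sequence is decomposed into all length-l windows; each window is read at
every choice of k informative positions (C(l, k) gap patterns), producing
(pattern, k-word) features whose counts define the feature vector φ. Counts
include the reverse complement of the sequence, so φ — and everything
downstream: kernel, decision values, k-mer weights, deltas — is exactly
strand-invariant. The kernel is the cosine similarity of feature counts.
Two independent computations are implemented: an explicit sparse feature
expansion used for batches, and the combinatorial identity
⟨φ(a), φ(b)⟩ = Σ_{u,v} C(m(u,v), k) over window pairs (m = matching
positions), which serves as the oracle in tests and acceptance runs. The
truncated kernel variant zeroes window pairs with more than d mismatches;
it is provided for parity with large-scale implementations and is tested
only against the exact kernel at desk scale.

Defaults: l = 11, k = 7, d = 3, C = 1, ε = 0.005, 5 CV folds. The SVM dual
is solved by scikit-learn's SVC on the precomputed kernel; the contract is
the soft-margin KKT conditions at tolerance ε, not a particular algorithm.
Positives are the top-1000 peaks by signal (ties broken by coordinate for
determinism); negatives are sampled windows on the same chromosome with the
same length and GC content within ±2 percentage points (the matching
tolerance is configurable; the null-generation tools this emulates do not
publish theirs), overlapping neither positives nor caller-supplied excluded
intervals. Cross-validation folds are assigned by a stable hash of the
sequence id, stratified by class, so fold membership never depends on input
order. AUROC is the tie-aware rank statistic; AUPRC is step-wise average
precision.

## k-mer weight tables, region scores, PWMs

The model's decision value over every l-mer defines a weight table keyed by
canonical l-mers (lexicographic minimum of word and reverse complement;
4^l/2 keys for odd l). Table construction exploits the structure of
single-word feature vectors — one count per gap pattern per strand, norm²
= 2·C(l,k) + 2·(patterns where the word reads the same on both strands) —
and is verified in tests to equal direct model scoring to 1e-9. A memory
guard refuses l > 13.

Region scores are sums of l-window weights (`sliding_sum`, the additive
score deltaSVM differences) or the same sum over the central 18 bp
(`center_window`), since scoring of fixed 18-bp footprint sequences is a
second legitimate reading of how footprints are scored in practice; the
default is `sliding_sum` and the choice is a flag.

The PWM is built from the top-1000 table entries by seed-anchored ungapped
alignment: each word is oriented and shifted within ±2 positions to
maximize identity with the top word, base counts are accumulated over the
overlap with a pseudocount of 0.25 per base, and rows are normalized. An
EM-based motif finder would add nothing here because all inputs are
equal-length words; the anchored alignment determines the register
directly. Ties in weight break lexicographically so the top-N set is
deterministic.

## deltaSVM and prioritization

For a single-base variant the (2l−1)-bp genomic window centered on the site
covers exactly the l windows whose score the substitution can change; the
deltaSVM score is the difference of sliding sums after substituting the
center base. "Fold change" of predicted binding is reported as this signed
difference — decision values are additive log-odds-like scores, so a ratio
of signed scores would be ill-defined. Guards: the genome base must equal
the recorded reference allele (coordinate-bug trap), and variants within
l−1 bases of a chromosome edge are rejected for lack of context. Batch
scoring reports per-variant failures rather than aborting.

Prioritization requires a candidate to carry at least one heart-tissue eQTL
pair AND pass the |Δ| criterion for at least one TF model, then ranks by
max |Δ| across models (ties by rsid). The default selection threshold is
the 99th percentile of the batch's |Δ| distribution — the study this
emulates picked a handful of extreme variants from ~14k scored SNPs without
publishing a cutoff, and a batch-quantile rule reproduces that "extremes
only" behavior at any batch size; `top_k` and a fixed threshold are
alternatives.

## Variant catalog

Variant positions are 1-based (association-catalog convention); interval
tracks are 0-based half-open (BED). All conversions happen in the readers;
a 1-based position p lies in [start, end) iff start < p ≤ end. Parsing
rejects rows with missing rsid/chromosome/position into a reported
rejection list. The trait filter is the published regex (its duplicated
`cardio` term is harmless); matching is case-insensitive by default because
catalog trait strings are mixed-case, with a flag restoring case-sensitive
behavior. "Incomplete entries" is operationalized as missing rsid,
chromosome, position, or either allele; indels are any multi-base allele.
The regulatory filter keeps a variant iff its position lies inside a
footprint and inside an enhancer (both-containment; requiring the footprint
itself to be nested is a config switch). LD expansion is strict r² > 0.8 in
at least one requested population, deduplicated by rsid with full
provenance retained; LD proxies are not re-filtered for regulatory overlap
before the eQTL join (configurable), since proxies stand in for the
association signal of their lead. The eQTL join keeps pairs in the heart
atrial appendage / left ventricle at p < 0.1 (strict), reporting pair,
unique-gene and unique-variant counts.

## EMSA quantification

Band intensities are corrected by subtracting blank-region background,
clamping at zero (blank noise routinely exceeds faint bands — clamping with
a report beats erroring). Fraction bound is bound/(bound+unbound), and the
one-site specific-binding model Y = Bmax·X/(Kd+X) is fitted by unweighted
least squares (scipy curve_fit, bounded below by zero, initialized at
Bmax₀ = max Y and Kd₀ = X nearest half-saturation, tolerances 1e-12).
Standard errors come from the Jacobian-based covariance at the optimum.
Replicates are pooled into one fit by default to preserve the error
structure; an averaged mode mirrors mean-curve plots. Bmax is unconstrained
by default with a flag capping it at 1. Degenerate inputs raise: fewer than
3 distinct concentrations, or all-equal Y (Kd unidentifiable). Direction
calls between alleles use the combined Kd standard error: lower alternate
Kd beyond that error is "increased" binding, higher is "decreased",
otherwise "unchanged".

## The synthetic study

The generator reproduces the statistical structure the pipeline assumes,
not genomic realism. Background sequence is i.i.d. (order-0) at GC 0.41 —
sufficient for kernel and classifier testing and the simplest defensible
null. Peaks are non-overlapping 100-bp windows; each receives (with
probability 1 by default) one instance sampled from the planted PWM, and
its signal is base + Gaussian noise + gain × instance log-odds, creating
the signal-sorted structure top-peak selection assumes. The planted motif
is a 9-bp homeodomain-like site (consensus GCACTTAAT) with a
near-deterministic 7-bp core (0.97 consensus probability, ~1.7
bits/position) and softer flanks (0.85): the strong-motif regime in which
a well-trained TF classifier operates around AUROC ≈ 0.95–0.98, matching
high-confidence cardiac TF sites. A weaker core (0.91) dilutes the kernel
signal over 100-bp peaks and drops CV AUROC below that regime, which is a
statement about the synthetic design, not about the classifier.

The association table plants exact counts of CVD-trait rows, indels and
malformed rows (malformed alternates between empty position — rejected at
parse — and empty alleles — removed at the SNV filter). Regulatory tracks
place a fixed number of footprints inside each enhancer plus an orphan
fraction outside all enhancers. LD tables give every lead a self-pair at
r² = 1 per population and proxies whose r² decays exponentially with
distance inside a block (zero across blocks), with per-population jitter;
in planned mode exactly one proxy per lead is guaranteed above 0.8 and the
rest are capped below it, producing a deterministic expansion count. eQTL
tables plant significant heart-tissue pairs (p log-uniform below 0.05·…
threshold) for chosen variants and emit only non-significant heart or
non-heart decoys otherwise. EMSA lanes add Gaussian noise to the true
fraction bound and a positive per-lane background to both bands, so
correction followed by the intensity ratio recovers the noisy fraction
exactly.

The coordinated study lays peaks, regulatory zones and a background zone
out in disjoint genomic intervals so every planted variant's category
(nested footprint / enhancer-only / orphan footprint / outside) is
unambiguous, plants five consensus motif instances inside chr2 nested
footprints paired with core-disrupting SNVs and significant cardiac
eQTLs, and books all per-stage counts by construction — downstream checks
compare pipeline output to this sidecar, never to re-runs of the pipeline.
The LD-expanded batch is sized (~450 variants: 225 survivors, one
qualifying proxy each) so the 99th-percentile |Δ| threshold separates the
five planted disruptions from the background distribution. Ground-truth
sidecars accompany every generated file; every generator is byte-identical
under a fixed seed, with per-generator subseeds derived by stable hashing
of the generator name so adding one generator never perturbs another.

What passing on this data does not show: robustness to higher-order
sequence composition, overlapping/weak peaks, assay-specific noise,
population LD structure beyond exponential decay, or eQTL effect-size
calibration. Results on real data depend on those properties.

## Problem sizes and numerics

Library defaults run the full design: 500/500 training sequences of 100 bp
at l = 11/k = 7 (kernel ~1 minute on one CPU), full 2,097,152-word weight
tables (~1.5 minutes), 500-run EMSA Monte-Carlo. Unit tests exercise the
identical code paths at l = 5–9 where brute-force string enumeration is
feasible. Floating-point contracts: kernel vs oracle to 1e-10; weight
table vs direct scoring to 1e-9; deltaSVM antisymmetry, substitution
consistency and strand invariance exact (same operations, same order).
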