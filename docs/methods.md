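# Methods

This note documents the models and procedures implemented in `saspipe`, the
assumptions behind them, the tunable parameters, and the choices made where
the underlying analysis conventions were genuinely open.

## Cross-platform content mapping

The mapping rule treats two platforms' probesets as measuring common content
when ≥ `min_probes` (default 6) of a probeset's probes occur with 100%
identity over their entire length within one single full-length sequence of
the other platform. Because the rule demands perfect full-length identity,
an exact substring index over the target sequences is mathematically
equivalent to an alignment search (BLAST with 100%-identity filtering) while
being deterministic and free of e-value ambiguity. The index stores forward
k-mers only; reverse-strand hits are found by querying the probe's reverse
complement, and count toward the rule with the strand recorded — an
antisense probeset must be able to match a sense full-length sequence.
Probes matching *different* sequences never pool: the per-target count is
what the threshold is applied to, and ties between equally good targets
break to the lexicographically smallest sequence id.

Classification is a two-pass procedure. Pass 1 matches platform B's
probesets against platform A's full-length sequences; a qualifying match
marks the query probeset *and every probeset backed by the hit sequence*
common. Pass 2 matches platform A's probesets against the full-length
sequences of the B probesets not yet common, with symmetric marking.
Consequences worth noting:

* a probeset with fewer than 6 probes can never qualify *as a query*, but
  can still become common when the other platform's probesets match its
  full-length sequence in pass 2 (sequence-level marking);
* one matched sequence marks all probesets it backs as common (a redundant
  gene on the generic platform flips as a block);
* probesets with no full-length sequence record are reported in an
  `excluded` set, never silently dropped, and the common/unique partition
  always sums to the per-platform total minus exclusions.

## Detection and differential-expression cascades

Expression values and P/M/A flags are pipeline *inputs* (the MAS5
summarization that produces them is an upstream black box; the synthetic
generator emulates its flags by intensity thresholding, below).

**In-vitro.** Detection per condition = flag ∈ {P, M} in **all** replicates.
The DE test between two conditions considers only probesets detected in
both. Fold change is computed on linear-scale replicate means,
direction-agnostically (max of the ratio and its inverse, with an up/down
label), and the threshold is **inclusive**: fold = 1.30 passes at 1.3. The
significance filter is a two-sided pooled-variance Student t-test on log2
intensities with raw p < 0.05. Choices made where the convention was open:

* *log2 scale for the t-test* — with n = 3 arrays per group the pooled
  equal-variance t on log-scale intensities is the era-standard; the scale
  is configurable only by transforming the input.
* *no multiple-testing correction* — the cascade reproduces a raw-p
  screening filter faithfully; this is documented, not endorsed. An FDR
  layer belongs downstream of this package.
* *degenerate contrasts* — groups whose replicates are exactly identical
  (zero variance on the raw values) get fold 1/p 1 when the means agree
  (excluded) and are flagged `degenerate` with p = 0 when they differ,
  so they are reported rather than producing NaNs.

**Clinical.** Detection = flag ∈ {P, M} in strictly more than 50% of all
samples (14/28 fails, 15/28 passes). The DE rule is a linear-scale fold of
each response group's mean against the mean of **all remaining samples**
(one-vs-rest), passing when ≥ 1.5 for at least one of CR/PR/SD/PD. The
reference for the clinical fold is not fixed by convention; one-vs-rest was
chosen because "changed in at least one response group" implies per-group
contrasts against a common background, and it is the only choice that
needs no arbitrary pairing of groups. Empty response groups are skipped
with a warning.

## Pathway over-representation

Probesets are collapsed to unique gene ids (unannotated probesets dropped
and counted), the universe N is the platform's annotated gene set
intersected with the pathway database's gene space, and each pathway with
DE-overlap k **strictly greater** than the per-pathway cutoff (15 or 10 in
the original screening design; scaled down for desk-size experiments) is
scored with the hypergeometric upper tail P(X ≥ k), computed through the
survival function in log space. Raw p-values are reported sorted
ascending, flagged significant below α. The "genes per pathway" cutoff is
interpreted as the DE-overlap count (the alternative — pathway size on the
platform — is a one-line change and noted here deliberately).

## Sense:antisense discovery

Orientation bookkeeping counts probesets per {sense, antisense,
unassigned}; percentage breakdowns use half-up rounding at 2 decimals
(1 decimal for clinical shares). Pairing is gene-level: probesets without a
gene id are dropped (counted), remaining ids deduplicated per orientation,
and the SAS pairs are the intersection of the two gene sets, so
|pairs| ≤ min(#sense genes, #antisense genes) holds by construction.
Unassigned-orientation probesets are not eligible for pairing. When one
probeset per orientation must represent a gene (for per-pair expression),
the highest-mean-intensity probeset is chosen, ties to the smallest id.

**cis-NAT geometry.** Loci are 0-based half-open with strand ∈ {+, −}; the
5′ end of a plus-strand transcript is its start, of a minus-strand
transcript the base at end − 1. For two opposite-strand overlapping
intervals the classifier returns `fully_overlapping` when one interval
contains the other (equality allowed; containment takes precedence because
it satisfies both end conditions), else `head_to_head` when the overlap
interval contains both 5′ ends, `tail_to_tail` when it contains both 3′
ends; disjoint intervals are `non_overlapping`. For opposite-strand
partial overlaps exactly one of head-to-head/tail-to-tail holds, so the
classifier is exhaustive and mutually exclusive (property-tested).

**Concordance.** A pair is `discordant` when |log2(mean_sense) −
log2(mean_antisense)| strictly exceeds τ = 1 (a 2-fold gap is still
concordant at the boundary). The underlying notion of "similar vs
differential intensities" is qualitative; τ is a fixed, documented cutoff
that makes it testable, not a biological constant.

## Array-vs-qPCR concordance

Fold changes are signed ratios (+2 = 2-fold up, −4 = 4-fold down), mapped
by the sign-preserving transform x ↦ sign(x)·log2|x| (the base cancels in
r; the sign convention must be fixed, and signed folds are correlated
rather than absolute ones). Pearson's r is computed from the standard
product-moment sums, r² alongside, and the two-sided p-value from
t = r·√((n−2)/(1−r²)) with n − 2 df. n ≥ 3 and non-constant vectors are
required.

## The synthetic-data generator

The generator emulates the structure of a paired generic/disease-specific
platform study; its defaults are the study conditions the pipeline is
tested under.

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | genes in the toy transcriptome (desk-scale stand-in for ~20k) |
| `nat_fraction` | 0.2 | P(gene has an antisense partner) — the literature's ~20% NAT incidence |
| `overlap_category_weights` | 0.4/0.4/0.2 | head-to-head / tail-to-tail / fully-overlapping mix |
| `transcript_length_range` | 500–2000 nt | uniform transcript lengths |
| `probe_length`, `probes_per_probeset` | 25 nt, 11 | Affymetrix-style probeset anatomy |
| `shared_content_fraction` | 0.6 | genes on both platforms (≈ the published common/total ratios) |
| `redundancy_generic` | 1.8 | mean probesets per gene on the generic platform (1 + Poisson) |
| `unassigned_fraction` | 0.09 | unannotated share of DSA-specific probesets (~8.7% observed) |
| `de_fraction` | 0.06 | transcripts with a planted effect (≈ published DE/total ratios) |
| `effect_log2` | 1.0 | planted |log2 FC|; sign random |
| `noise_sd_log2` | 0.25 | replicate noise SD, log2 scale |
| `baseline_log2_range` | 4–12 | per-transcript basal log2 intensity |
| `detect_threshold_P/M` | 100 / 50 | linear-intensity flag thresholds (P ≥ 100 > M ≥ 50 > A) |
| `flag_flip_rate` | 0.01 | flag corruption probability |
| `n_reps`, `n_clinical` | 3, 28 | triplicate in-vitro conditions; clinical cohort size |

Noise and effect magnitudes have no published values for the emulated
arrays; the defaults above are clearly-labelled stand-ins chosen once as
plausible for MAS5-summarized data, and the recovery/power analyses state
them explicitly. The clinical CR/PR/SD/PD split is likewise unpublished;
the generator assigns 7/7/7/7 round-robin.

Geometry: each gene occupies its own locus on a toy chromosome with enough
margin that only planted partners overlap. Antisense intervals are placed
so the overlap region contains both 5′ ends (head-to-head), both 3′ ends
(tail-to-tail), or one whole transcript (fully overlapping), with overlap
depth drawn strictly between 1 nt and either length so partial overlaps
never degenerate into containment. Strands are mirrored correctly when the
sense gene lies on the minus strand.

Sequences are uniform ACGT, drawn **independently per transcript** — an
antisense sequence is *not* the reverse complement of its partner over the
overlap. Pairing information lives in the annotation (shared gene id),
exactly as in a platform's annotation files; this keeps the common/unique
ground truth structural and exactly recoverable by probe matching, at the
cost of genomic sequence consistency (see limitations). Probes are verbatim
substrings at distinct random offsets.

Expression: log2 intensity = per-transcript baseline + planted effect (in
the treated condition of the sensitive/resistant comparison, or in the
transcript's assigned clinical response group) + N(0, `noise_sd_log2`) per
probeset × sample. Flags threshold the *linear* intensity (≥ P-threshold →
P, ≥ M-threshold → M, else A) and are then corrupted independently at
`flag_flip_rate`, so detection is coupled to expression level as in real
flag calls. One RNG stream per logical stage (transcriptome, platform
design, each expression matrix, qPCR emulation) is derived from the master
seed, so identical config + seed gives byte-identical output bundles and
single stages can be re-run reproducibly.

What the generator does **not** emulate: probe thermodynamics and
cross-hybridization, batch and scanner effects, heavy-tailed or
intensity-dependent noise, correlated genes, trans-NATs, CEL-level data.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under its stated rules — not robustness of those rules to
real-array artefacts.

## Numerical and reporting conventions

* Half-up decimal rounding for all reported percentages (never bankers'
  rounding); 2 decimals for content breakdowns, 1 for clinical shares. One
  published breakdown value (49.02% where 11,320/23,089 = 49.0277% rounds
  half-up to 49.03%) is inconsistent with any standard rounding of its own
  count pair; this package does not chase it.
* Fold thresholds inclusive (≥); majority detection strict (>); pathway
  gene-count cutoffs strict (>); concordance τ strict (>).
* Hypergeometric tails via the scipy survival function; verified in tests
  against exhaustive enumeration for all N ≤ 12 and against closed forms.
* The t-test p is verified against the closed-form t CDF to 1e−10.
* Determinism: manifests carry SHA-256 digests of every emitted file; the
  test suite asserts two same-seed runs are byte-identical.

## Analysis sizes used in tests

Recovery tests run at 500 genes (noiseless probes; zero mapping errors
required). Power analyses use 1000 planted transcripts at effect_log2 = 1,
σ = 0.25, n = 3: the analytic joint power of the pooled t-test (noncentral
t, ncp = 4.899, df = 4) with the fold ≥ 1.3 filter is ≈ 0.947, and the
empirical cascade pass rate is required to agree with that oracle within a
99.9% binomial band; the null-transcript pass rate must stay within
binomial tolerance of ≤ 5%. End-to-end pipeline checks run at 100–200
genes, which exercises every stage in seconds.

## Known limitations

* Antisense transcript sequences are annotation-linked, not
  sequence-complementary; probe matching can therefore never discover SAS
  pairs from sequence alone (by design — pairing is an annotation
  operation here).
* The clinical fold reference (one-vs-rest) and the t-test scale (log2) are
  documented choices among unstated-in-the-field alternatives; both are
  isolated behind `FilterConfig` and the module functions if a different
  convention is needed.
* Raw p-values throughout (screening fidelity); no moderated-variance or
  permutation tests.
* The enrichment universe is the platform's annotated genes, not the
  genome and not the detected subset; both alternatives change N and are
  easy to swap at the call site.
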