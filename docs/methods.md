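# Methods

This note documents the models and numerical choices behind `xenosig`:
what each statistic is, which knobs matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Data model

All analyses consume probe-by-sample matrices of log2, RMA-style
normalized intensities, one per species, with a (possibly partial)
probe→gene-symbol annotation. Missing values are not supported — post-RMA
array data is complete, and requiring completeness simplifies every
downstream contract. A `scale` flag (`log2`, the default, or `linear`)
controls fold-change arithmetic. Probe-level rows are the default unit of
analysis; `collapse_to_genes` reduces to one row per symbol by keeping
the probe with the highest mean intensity (deterministic, standard
practice). Gene symbols are compared case-insensitively because mouse
symbols are conventionally mixed-case and human upper-case; species
mix-ups are additionally guarded by the `HS_`/`MM_` probe prefixes the
generator emits.

## The signature resource

The packaged 64-entry signature stores rank, probe-set id, symbol and an
EMT annotation class per entry, with class counts fixed at 17
(core-overlap with the published 91-gene EMT core signature) + 3 (the
obvious markers SNAI2, FN1, ACTA2) + 4 (reported additions PDGFRB,
SPARC, INHBA, COL6A2) + 40 (other). The full 91-gene core list is not
packaged — only its 17-member overlap and the constant size 91 used in
enrichment arithmetic — because inventing unprinted list contents would
be worse than omitting them. Historic symbols (HNT, C7orf10) are kept
verbatim; no alias translation is attempted.

## Proxy co-expression ranking

COL11A1 serves as a single-gene proxy for the whole signature. The
default association measure is the sample Pearson correlation of each
gene's row with the proxy row; constant rows score 0 and are flagged
degenerate, and ranking ties break lexicographically for determinism.

Mutual information is offered as the alternative measure: a plug-in
estimator on the joint histogram after equal-frequency binning of each
variable (default 3 bins — with ~18 samples more bins mostly estimate
noise; the plug-in bias is roughly (bins−1)²/(2n ln 2)). Ties are broken
by stable rank order, except that a constant vector collapses to a single
bin so that a zero-entropy margin gives MI = 0 exactly. Summation order
is canonicalized so MI(x, y) equals MI(y, x) bit for bit. This estimator
is a documented stand-in: the binning/spline choices of published MI
rankings are rarely specified.

Two summaries describe the top of a ranking: `top_k_consistency`
(precision — the fraction of the top-k, proxy excluded, that is
signature) and `top_k_recall` (the fraction of the signature captured by
the top-k). With a 64-gene signature, consistency at k = 100 caps at
63/100; signature-detection checks at k > 63 therefore use recall.

## Sample partitioning

The default `largest_gap` rule sorts proxy values in descending order
and splits at the largest consecutive difference, considering only
interior splits that leave ≥ 2 samples per group; exact ties resolve by
sample-id order with a warning. The rule is only well defined when the
between-group expression gap dominates the noise — at the default
synthetic noise level it can lock onto a spurious within-group gap — so
the `fixed_n_high` override (top-n samples high) exists for replicating
a known design such as the 7-high/11-low split, and end-to-end runs use
it. Whether the original 7/11 grouping came from a rule or visual
inspection is unrecorded; neither option here claims to be that
procedure.

## SAM

The two-class unpaired statistic for gene *i* is the relative difference

    d_i = (x̄_high − x̄_low) / (s_i + s0),
    s_i = sqrt[(1/n1 + 1/n2) · (SS_high + SS_low) / (n1 + n2 − 2)],

which reduces to the pooled-variance t statistic at s0 = 0 (verified
against scipy's t-test in the suite). The fudge factor s0 is selected
from the percentiles (0, 5, …, 100) of the s distribution by minimizing
the coefficient of variation of the median absolute deviation of d
across quartile bins of s — the candidate that most decouples the spread
of d from the scatter scale; ties take the smallest candidate, and fewer
than 10 genes fall back to s0 = median(s) with a warning.

The null distribution permutes group labels. When the number of distinct
high-group labelings C(n, n_high) is at most `exhaustive_threshold`
(default 50000) all labelings are enumerated in lexicographic order —
C(18, 7) = 31824 qualifies, so the 7-vs-11 analysis is deterministic and
seed-independent. Otherwise `n_permutations` labelings are drawn from
the seeded generator; fewer than 10 available permutations is refused.

Per-gene q-values use the median-false-positive estimator: q_i =
median over permutations of #{null |d| ≥ |d_i|}, divided by the rank of
|d_i| among observed values (1 = most extreme), capped at 1 and
monotonized so a larger |d| never receives a larger q. This is a
standard permutation-FDR construction but is *not* the Storey Δ-threshold
procedure of the samr package; replication of published call counts
(e.g. 398 up / 32 down) can therefore differ by a few percent even on
identical data. No π₀ correction is applied, which makes q conservative.

Significance is the joint rule: q < 0.05 **and** fold change > 2 (up) or
< 1/2 (down); a gene with FC in [1/2, 2] is never called regardless of
q. Fold change on log2 data is 2^(mean difference) — the ratio of
geometric means; on linear-scale data it is the plain ratio. Genes with
zero within-group scatter and s0 = 0 would have |d| = ∞; they are
flagged degenerate and surfaced in the report rather than silently
ranked.

The permutation engine is vectorized over labeling chunks (group sums
and sums of squares via one matrix product against a 0/1 labeling
matrix); chunks are kept near 2·10⁶ elements because larger working sets
thrash memory without helping throughput. A full 5000-gene, 31824-
permutation run takes ~50 s on one CPU.

## Hypergeometric enrichment

`hypergeom_tail(k, n, K, N)` sums the pmf from k upward in log space
(gammaln + logsumexp), keeping relative accuracy for tails far below
1e-30 (scipy's `hypergeom.sf` and an exact rational-arithmetic
enumeration serve as independent cross-checks in the tests; agreement is
better than 1e-9 relative over the exhaustive N ≤ 30 scan). Conventions:
k ≤ 0 returns exactly 1, k > min(n, K) exactly 0.

The universe size N is a required explicit argument (the pipeline
defaults it to the number of genes analyzed). This is deliberate: for
the fixed overlap (k=17, n=64, K=91) the tail spans 8.4e-10 at N=2000 to
7.4e-27 at N=22000, so any published P value that omits N — as the
2×10⁻²² and 10⁻²⁷ figures this analysis descends from do — cannot be
reproduced, only bracketed.

## Cross-species analysis

The attribution logic: the partition is derived from *human* COL11A1 and
then applied unchanged to the mouse matrix, so any mouse differential
expression is linked to the state of the human graft, not to anything
measured in the mouse itself. The mouse analysis reports
significant_down genes (the direction of interest; the symmetric up
analysis is available), sorted by ascending fold change. The human
signature score is the unweighted per-sample mean of the signature-gene
rows — the simplest score consistent with heat-map ordering; weighted
variants were deliberately deferred. Adipocyte association is the
Pearson correlation of the marker-mean (default markers ADIPOQ, CFD,
FABP4) with that score; constant inputs are reported as 0 with a warning
rather than NaN. Heat-map order: samples by descending signature score,
the human gene block by signature rank, the mouse block by ascending
fold change.

## Synthetic generator

A single latent factor drives both species — the modeled claim is
precisely that one biological process in the human cells explains both
the human signature and the mouse adipocyte response. Per sample s the
activity a_s is uniform on (0.7, 1.0) for the 7 high samples and on
(0.0, 0.45) for the 11 low samples; the deliberate (0.45, 0.7) gap makes
the largest-gap partition well defined at low noise while keeping a
continuous range of expression within groups. In log2 space:

    human signature gene:  x = β + λ_g·a + ε      λ_g ~ N(3.0, 0.3) clipped at 0
    human background:      x = β + ε
    mouse adipocyte gene:  y = β − 4.0·a + ε
    mouse background:      y = β + ε
    β ~ U(4, 12),  ε ~ N(0, 0.5)

Transfection labels (7 INHBA, 6 FST, 5 control), drawn independently of
activity, add +3 log2 units to the transfected human row only — INHBA is
itself a signature gene, which reproduces the real-data quirk that its
expression is manipulated and must be excluded from co-expression
claims; FST exists as a dedicated background row.

Defaults are anchored to the printed effect sizes of the xenograft study
this design emulates: a loading of 3.0 gives typical planted fold
changes of ~3.7 (the observed SNAI2 FC of 5.22 corresponds to λ ≈ 3.8),
and the adipocyte slope of 4.0 gives ~5.7× downregulation (the top
observed adipocyte FCs, 12.3 and 11.8, correspond to slopes ≈ 5.8).
Weaker settings (λ ≈ 1.2) would make per-gene correlations ≈ 0.4 at 18
samples, too weak for any top-of-ranking property to hold — a power
calculation, not a post-hoc tuning. Noise is Gaussian in log2 space
(standard for RMA intensities; heavier tails deferred). All randomness
flows from one seeded generator; the same seed reproduces the experiment
bit for bit.

`plant_fold_change` converts a target linear FC into a loading via
log2(FC)/0.625, where 0.625 is the *expected* activity gap
E[U(0.7,1)] − E[U(0,0.45)]. The truth table records both the intended FC
and the *realized* FC (loading × the drawn activity gap): with large
loadings the per-seed gap realization alone moves the materialized FC by
~20%, so recovery tests compare estimates with the realized value —
isolating measurement-noise recovery from activity-sampling variability
that is part of the planted truth.

What the generator does **not** emulate: probe-level cross-species
hybridization (assumed minimal in the real design), multiple probes per
gene, correlated background genes, batch structure, non-Gaussian tails,
or the full mouse stromal response beyond the three-marker adipocyte
cluster. A green synthetic test therefore establishes that the
algorithms recover the stated generative structure — not that they
reproduce any particular real dataset's gene counts.

## Known limitations

- The q-value estimator intentionally differs from samr's; published
  call counts are expected to match only approximately.
- Published enrichment P values without a stated universe size are
  treated as non-reproducible by design.
- MI estimation at n ≈ 18 is noisy; Pearson is the measure of record.
- The largest-gap partition is a heuristic; use `fixed_n_high` when the
  design's group sizes are known.
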