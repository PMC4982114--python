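# Methods

## Problem setting

The package operates downstream of count-level RNA-seq processing.  Its unit
of input is a *contrast*: a per-gene table of log2 fold change, nominal
p-value and optional normalized read intensities for one
treated-vs-untreated (or responsive-vs-unresponsive basal) comparison of a
tumor model.  All inference is at the table level; alignment, normalization
and dispersion estimation are out of scope, as are multi-sample designs
beyond two-condition contrasts.  P-values are used unadjusted with fixed
cutoffs rather than FDR control, reproducing the procedure the package
implements; every threshold comparison is strict (">" means ">").

Genes absent from a table are "not measured", which is distinct from
"measured but not significant": all set algebra intersects with each table's
universe explicitly, and panel cross-tabs report a separate not-measured
bucket.  Gene symbols match case-sensitively after whitespace trimming.

## Upstream-regulator scoring

Each regulator in a signed regulator→target network is scored against a
contrast's significant-gene set (default |FC| > 2, p < 0.001):

* **Overlap p** — upper-tail hypergeometric P(X ≥ k) with universe N = the
  genes measured in that DE table (conditioning on detectability, as in
  standard over-representation practice), K = the regulator's targets within
  the universe, n = significant genes, k = matched targets.  k = 0 returns
  p = 1.
* **Activation Z** — z = Σ w·s_obs·s_exp / √(Σ w²) over *informative*
  matched targets (expected sign ≠ 0, weight > 0).  Targets with unknown
  edge direction count toward k and the overlap p but not toward z.
  Undefined (no informative targets) propagates as state "Undetermined".
* **Bias-corrected Z** — the dataset direction bias d is the mean observed
  direction over all significant genes; the regulator's sign bias is
  Σ w·s_exp / Σ w; their product b recentres and rescales the agreement sum
  x to its exact null moments under i.i.d. biased directions:
  z_bc = (x − b·Σw) / √(Σ w²·(1 − b²)).  When |b| = 1 the observed
  agreement is fully attributable to bias and z_bc is defined as 0; when
  b = 0, z_bc = z identically.

The commercial causal-analytics tool whose outputs these three statistics
emulate does not publish its formulas; the definitions above are this
package's own, chosen to be exactly calibrated (null mean 0, variance 1 —
verified by simulation at 10,000 resamples) and antisymmetric under a
whole-dataset direction flip.  Output metadata flags them as stand-ins.
Activation state is the sign of z alone; magnitude significance is enforced
separately by the stringent filter, so downstream direction comparisons
remain defined for sub-threshold scores.

## Selection and uniqueness

Exclusion rules before any filtering: regulators annotated as exogenous
chemicals are dropped (endogenous mammalian chemicals kept); group
regulators whose constituents are all present individually are dropped;
same-name duplicates (e.g. species variants) keep the entry with the larger
|z| ("activation score" is read as |z|; an undefined z ranks lowest).

Stringent UPRs satisfy jointly: overlap p < 10⁻⁴, matched targets > 10,
|z| > 2 and |z_bc| > 2.  The cross-model uniqueness decision tree is
evaluated in fixed order (branch labels are carried in every verdict):

1. absent from B's full post-exclusion listing (operationalized as: not
   scored, or zero matched targets) → unique;
2. both |z_B| and |z_bc,B| > 2: opposite activation state → unique; same
   state → not unique (shared);
3. exactly one of the two > 2 *in A's direction* → not unique; one > 2 in
   the opposite direction, or neither > 2 → candidate;
4. candidates resolve on B's overlap p: ≥ 10⁻³ → unique;
   10⁻⁴ ≤ p_B < 10⁻³ → unique only if p_B > 100·p_A (the post-dedup p_A is
   used); p_B < 10⁻⁴ → not unique; the in-band ratio failure → not unique.

The same-direction both-exceed case and the candidate fallthrough take the
conservative (not-unique) call, the complements of the stated unique rules.
Uniqueness versus several comparator models is the conjunction of the
pairwise verdicts; zero comparators is vacuously unique and warns.  Common
stringent UPRs between two models require the same activation-state sign by
default; opposite-sign pairs are reported separately, and a flag folds them
in for sensitivity analyses.

## Response-gene set algebra

Model-A-specific response genes in a direction: (1) genes significant in A
and significant in B in the *opposite* direction are specific to both
models, each in its own direction; (2) genes significant in A and not
significant in B are removed when the signed-FC ratio FC_A/FC_B lies in the
inclusive band [1/r, r] (default r = 2; relaxed r = 1.33 for close schedule
comparisons) and kept otherwise.  Opposite-sign FCs and genes unmeasured in
B are kept: both represent maximal between-model divergence, and the ratio
band is undefined across signs.  The ratio uses signed linear FCs, matching
how such tables print "expression ratios".  A relaxed significance variant
(|FC| > 1.5, p < 0.001) is available through the same rule object.

Basal comparisons are ordinary DE tables (responsive vs unresponsive
untreated expression), so one filter implementation serves both treated and
basal contrasts; consistent basal differentials are intersections of
significant-up (or -down) sets across all comparators.  The
responsiveness-enrichment fold for a gene subset is
(|subset ∩ responsive|/|subset|) / (|responsive|/|universe|) with an
upper-tail hypergeometric p; an empty subset yields an undefined fold with a
warning rather than an error.

Because no formula is published for "percent similarity" between two
contrasts' responses, `response_similarity` reports both the Jaccard index
and the overlap coefficient, labeled, without asserting either convention.

## Pathway enrichment

Plain hypergeometric upper-tail p per GMT set, restricted to a stated
background universe (default: the contrast's measured genes; a union-of-GMT
background is available for DAVID-like behavior, since DAVID's default
background is genome-wide and the choice is deliberately exposed rather than
asserted).  `ease=True` reproduces DAVID's EASE score (overlap reduced by
one before the tail), the statistic behind published "modified Fisher exact"
pathway p-values; it is off by default.  Significance is raw p < 0.05,
strict, with no multiple-testing correction, again mirroring the procedure
being reproduced.  Sets disjoint from the universe are skipped with a log
note; ties in p are broken by set id for deterministic output.

## Synthetic data

The generator emulates the *table-level* statistics of a five-contrast
tumor-model comparison at roughly 1/5 scale: 4,000 genes, 200 regulators
with 15–40 unit-weight targets each (75 % activating, 20 % repressing, 5 %
unknown-direction edges), and 20 planted regulators per treated contrast.
Three contrasts have disjoint planted sets (the three single-host tumor
models); the two immunodeficient-host schedule contrasts share 12 of 20
planted regulators with identical activity signs, emulating the high
between-schedule similarity that motivates the common-stringent-UPR
strategy; two basal contrasts reuse half of the responsive model's planted
regulators plus basal-only ones, so basally differential genes are enriched
for treatment-responsive genes (the "priming" effect the basal analysis
looks for).  Activity signs are 3:1 activated:inhibited, echoing
up-dominated responses.

Per contrast, log2FC ~ Normal(μ_g, σ) with σ = 0.25, μ_g the sum of
activity × edge sign × effect size (default 2.0) over planted regulators
targeting the gene, and μ_g = 0.05 (a mild global up-bias) for untargeted
genes; p-values are the two-sided normal tail of log2FC against σ.  With
these defaults the expected fraction of genes passing |FC| > 2 and
p < 0.001 is ≈ 12–13 % per treated contrast, the generator's calibration
target of 12.6 %.  Count-level negative-binomial simulation is deliberately
not modeled: the pipeline consumes only (FC, p, intensity), so fidelity at
the table level suffices.  Intensities are log-normal (log-mean 4.0,
log-sd 1.2) and independent of fold change — they support the > 50
intensity filter without claiming any coupling between expression level and
response.  Gene sets mix truly co-regulated sets (a regulator's exact
target set) with random decoys; the panel is a labeled random gene subset
with a configured 30 % overlap with responsive genes.

What passing tests on this generator do *not* show about real data: no
correlation structure between genes beyond shared regulators, no
pooled-replicate variance, no intensity–significance coupling, symmetric
Gaussian noise, and a network known without error.  Recovery rates here are
upper bounds on what identical thresholds would achieve on real tables.

An effect size of exactly 0 simulates an explicit null; a positive effect
size at or below the noise standard deviation is rejected as an infeasible
scenario (the planted signal would sit inside the noise floor).  All
randomness flows from one integer seed through `numpy.random.default_rng`;
identical seeds give byte-identical written tables.

## Numerical and degenerate-input choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  verified against exhaustive enumeration for every configuration with
  N ≤ 12.
* Significant genes cannot have FC = 0 (|FC| > threshold ≥ 1), so observed
  directions are always ±1; a defensive assertion guards the invariant.
* Regulators with no targets in a table's universe are omitted from scoring
  (not scored at p = 1), because the platform never measured them.
* Empty significant sets are not errors: every regulator scores p = 1 with
  undefined z.
* Intensity filtering on a table without intensity columns raises a
  configuration error rather than silently passing nothing.
* File parsers report named errors with 1-based line numbers for duplicate
  rows, malformed numerics and empty GMT lines; round-trips through the
  writers are exact (floats written with `repr`).

## Problem sizes used in the shipped checks

The acceptance script and test suite run the default 4,000-gene scenario:
recovery statistics average ten seeded scenario replicates, the null
control uses 100 seeds, and the bias-corrected-Z calibration uses 10,000
resamples of a 15-target regulator at dataset bias 0.3 — sizes chosen so
the full battery completes in under a minute on one CPU while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

The Z-score definitions, though calibrated, are not the proprietary
originals, so absolute scores are not comparable with that tool's output
(the decision *rules* consuming them are faithful).  The uniqueness tree's
boundary cases at |z| exactly 2 follow the strict reading (not "> 2" means
candidate-side).  The similarity metric ambiguity is surfaced rather than
resolved.  Ortholog mapping, GO-based panel construction, functional
annotation clustering and mechanistic-network visualization are explicitly
out of scope; panels and gene sets are file inputs.
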