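# Methods

This note documents the statistical procedures implemented in
`fieldtx`, the parameters that matter, the synthetic-data model used to
verify them, and the design choices made where the underlying study
protocol left the details open.

## Normalization and relative expression

Raw single-color array intensities are non-negative; two inter-array
normalizations are provided.

**75-percentile scaling** (`io.percentile_normalize`): each sample is
divided by its own type-7 (linear-interpolation) 75th percentile and
log2-transformed, so the array's upper-quartile probe maps to exactly
0. The percentile estimator is the common default of numerical
software; raw values are floored at ε = 0.1 before division so silent
probes do not produce −∞. The floor affects only non-signal probes
(typical signal is orders of magnitude above it) and preserves
ordering.

**Quantile normalization** (`io.quantile_normalize`): classic
rank-mean normalization — the reference distribution is the
across-sample mean of sorted columns; tied values receive the mean of
the reference values at their tied ranks; log2 with the same floor.
Without ties, every sample's sorted value vector is identical by
construction.

**Relative expression** (`io.relative_expression`): per-gene log2
value minus that gene's median over a reference sample set (default:
all samples of the analysis). The transform is idempotent and makes
profiles comparable across genes of different absolute abundance.

Thresholds follow the "above"/"below" wording of the protocol as
*strict* inequalities throughout (raw > 100, normalized > −5,
entropy < 4.5, relative > 8, FDR < 0.05, FC > 3 or 2), so any count
this package reports is exactly reproducible.

"Expressed" calls are made per condition on the replicate-mean
normalized value (not per replicate); condition-level summaries use
arithmetic means over replicates in design order.

## Organ/tissue specificity

For each gene, condition-level expression weights w_t over the N = 48
conditions give shares p_t = w_t / Σ w_t and Shannon entropy
H = −Σ p_t log2 p_t (bits), ranging from 0 (single condition) to
log2 48 ≈ 5.585 (uniform). A gene is called specific when H < 4.5 and
its maximal relative expression exceeds 8 log2 units in at least one
array.

Two normalization details were genuinely open and are fixed as
follows:

* **Entropy weights are linear-scale** (2^log2 value) after quantile
  normalization. Log2 values can be negative, which breaks the
  probability normalization; exponentiating restores a well-defined
  weight while keeping the quantile-equalized ranks. A shifted-log2
  alternative is available via `condition_weights(mode="shifted-log2")`.
* **The relative-expression filter uses the 75-percentile-normalized
  matrix** (median-centered over all 143 arrays), not the quantile
  matrix. Quantile normalization maps a sample's most extreme values
  onto the pooled reference tail and therefore compresses exactly the
  large effects the +8 cutoff is meant to catch; on the
  percentile-normalized scale an effect of +10 log2 units survives
  intact, which is the reading under which a fixed +8 threshold is
  meaningful.
* Entropy is computed over the 48 condition means (not the 143
  individual arrays), matching the number of biological contexts.

Specific genes are clustered on their relative-expression profiles
with distance 1 − Pearson r and average (UPGMA) linkage, cut into
k = 7 groups; labels are renumbered by decreasing cluster size (ties:
lexicographically smallest member). Constant profiles, whose
correlation is undefined, are assigned distance 1 to everything with a
warning.

## Differential expression

Per-gene two-sided unpaired t-tests on log2 values; Welch's unequal-
variance form is the default (the pooled-variance form is available
via `variant="pooled"` for exact-reproduction attempts). Degenerate
rows with zero variance in both groups use p = 1 for equal means and
p = 0 otherwise. P-values are adjusted by Benjamini–Hochberg step-up;
fold change is the geometric-mean convention FC = 2^|Δmean log2|
(difference of log2 group means, not ratio of linear means). Selection
requires q < FDR *and* FC > cutoff, split by the sign of the log2
fold change.

The lemma × palea comparison is a per-gene balanced fixed-effects
two-way ANOVA with interaction (closed-form type-I sums of squares,
which coincide with type-II/III on balanced data), F-tests per factor,
BH across genes per factor. Unbalanced designs are rejected rather
than approximated.

The fertile/sterile contrast treats the three sterile mutant lines as
three replicates of the sterile condition and uses FC > 2; the
vegetative→reproductive cross-tissue comparison uses daytime samples
only, and the "universal" set is the intersection of the per-tissue
selections with a per-gene direction-concordance flag.

## Time-course phase structure

The sample-by-sample Pearson correlation matrix (after excluding
contamination-flagged genes, below) is clustered on its rows — each
timepoint represented by its correlation profile — with Euclidean
distance and complete linkage, cut at k = 3. When the cut is
time-contiguous it is accepted directly; otherwise every contiguous
placement of k − 1 boundaries is scored by mean within-phase PCC minus
mean between-adjacent-phase PCC and the best is returned. The object
records which path was taken, making the phase call deterministic and
auditable where the original protocol relied on visual inspection of a
clustered heat map.

**Transient-spike detection** flags a gene at interior timepoint t
when its value exceeds both neighbors *and* its median over all other
timepoints by more than log2(min_ratio), with min_ratio = 32 by
default. This targets one-timepoint contamination events — pollen
deposited on leaf samples at peak flowering expresses pollen-specific
genes at enormous levels for exactly one sampling date — while leaving
sustained stage shifts untouched. In the pipeline the flagged genes
are excluded *before* the PCC matrix is computed: at the synthetic
design size (5,000 genes) an 80-gene, 100-fold spike carries several
times the relative weight it has on a 29,000-probe array and would
otherwise dominate the flowering timepoint's correlation profile; the
original analysis likewise removed these genes once identified.

**Gene clustering** supports centered Pearson, uncentered correlation
r_u = Σxy / √(Σx²·Σy²) (scale- but not shift-invariant) and Euclidean
distances with average, centroid and complete linkage. Centroid
linkage on correlation-type distances can produce inversions (a merge
lower than a child merge); these are recorded in the tree rather than
reordered away.

**Cluster-based refinement** of a transition DE set cuts the gene tree
into n_cut (default 10) clusters and keeps clusters whose centroid
step across the transition is at least half the median per-gene
|step|, pooling kept clusters by step sign. The step is measured as
the difference of *medians* over the before/after timepoint windows:
a one-timepoint transient landing on the first post-transition
timepoint inflates a window mean and would masquerade as a sustained
change, whereas the median ignores it. Exact reproduction of any
particular refined count is not promised — the rule is this package's
operationalization of "selected based on similarity in expression
patterns".

## Enrichment

GO-slim annotation is consumed as a generic-term → slim-term mapping
applied to a gene → generic-term table (unmapped terms dropped with a
logged count, per-gene deduplication). Term enrichment of a study set
within a background uses the upper-tail hypergeometric probability
P[X ≥ k] with BH correction across tested terms; terms with zero study
hits are skipped.

Motif scanning matches IUPAC degenerate patterns position-by-position;
a genomic 'N' (unknown base) is matched only by a pattern 'N', never
by a specific code — the conservative convention. Motif enrichment
truncates every upstream sequence to its last `flank` bases (default
1,000, the promoter-proximal side), tabulates gene-level presence
(≥ 1 match) into a 2×2 study/background table and applies the
one-sided Fisher exact test for over-representation. The scan is
forward-strand; for the default pattern GNATATNC, which is its own
reverse complement, strandedness is immaterial. The background set is
a required argument — it is part of the scientific question, not a
default.

Gene-set trajectory profiles (mean ± s.e.m. per sample over a set's
relative values) serve GO categories, KEGG photosynthesis sets and
miRNA-precursor probe sets alike; no dedicated machinery is needed for
the miRNA analysis beyond subsetting to precursor probes.

## Synthetic-data model

The generators (`fieldtx.simulate`) emulate the study design with
planted, fully recorded ground truth. All effects are planted on the
log2 scale; export adds N(0, 0.3²) per-sample log2 scale shifts and
exponentiates to a linear "raw" intensity scale, so the pipeline's own
normalization is genuinely exercised. Replicate noise is N(0, 0.25²)
log2 units, which yields replicate correlations above 0.9 as in
high-quality array data. Per-gene baselines are log-normal
(log2 ~ N(8, 2²)).

Defaults of the organ/tissue panel (5,000 genes, 48 conditions × 3
replicates, one anther condition with 2, i.e. 143 arrays):

| planted class | count | effect (log2) |
|---|---|---|
| organ/tissue-specific | 50 | +10 in one condition (round-robin) |
| diurnal, leaf blade | 7% of genes | ±2 amplitude, half day-/half night-peaking |
| diurnal, leaf sheath | 70 | ±2 |
| stage-universal (3 tissues) | 215 | ±2 from reproductive stage on |
| stage, single-tissue | 50 per tissue | ±2 |
| lemma/palea tissue effect | 23 | ±1.5 |
| lemma/palea stage trend | 150 | ±1.5 per stage step |
| silent | 3,500 | −10 in a random subset of organ×stage contexts |

Silence is drawn per biological context (organ × stage), shared by
day/night sample pairs — silencing conditions independently would
fabricate day/night contrasts that no biology implies. The silent
breadth per gene is capped at 40% of contexts so that background genes
remain broadly expressed: the fixture's purpose is that planted
specific genes, and only they, satisfy the entropy/relative criteria.

The weekly leaf series plants 400 step genes per boundary (|step| ~
U(1, 3), random sign) after timepoints 5 and 12 (i.e. 41→48 DAT and
90→97 DAT at weekly sampling from 13 DAT) and 80 spike genes at
100-fold for the single 90 DAT timepoint. The fertile/sterile series
plants 300 senescence genes with fertile effects ±U(2.5, 5) log2
scaled by a week schedule (0, 0.6, 0.85, 1.0) and attenuated to 25% in
the sterile lines, so the fertile−sterile divergence is absent at
heading and grows week by week; effect sizes are chosen so the
divergence is statistically detectable at n = 3 replicates and
σ = 0.25, which is what the design intends to demonstrate.

What the generator does **not** emulate: probe-level array artifacts
(spatial effects, background, dye chemistry), probe–probe correlation
within loci, heavy-tailed or intensity-dependent noise, partially
overlapping planted classes, and the real array's 29,119/45,151 probe
attrition. Passing tests therefore certify the statistical machinery
and its thresholds — not performance under real-array noise
structure.

## Numerical choices and degenerate inputs

* Percentile estimator: type-7 everywhere (numpy default).
* log2 floor ε = 0.1 on the raw scale, applied before division.
* PCC matrices are symmetrized ((r + rᵀ)/2, unit diagonal) so the
  stored matrix equals its transpose exactly.
* PCA is an SVD of gene-centered data; component signs are fixed by
  making each component's largest-magnitude loading positive, and
  scores·loadingsᵀ + means reconstructs the input to ~1e−10.
* Correlation distances clip tiny negative values from floating error;
  constant (or all-zero, for uncentered) profiles get distance 1 with
  a warning.
* BH adjustment delegates to statsmodels; zero-variance t-test rows
  and empty reference sets raise or use the documented conventions
  above rather than propagating NaN.
* Stage outputs are written atomically (temp file + rename) with a
  manifest (parameters, checksums, version) per stage.

## Problem sizes

Module tests run on proportionally scaled-down designs (hundreds to a
couple thousand genes); the acceptance suite and `scripts/acceptance.py`
run the full 5,000-gene default design, 200 (tests) or 100 (script)
seeded replicates for phase-boundary recovery at 600 genes per run,
and 200/100 simulated 2,000-gene null experiments for FDR calibration.
These sizes make the whole suite complete in about a minute while
keeping every statistical claim tied to the default study conditions.

## Known limitations

* The probe set "extracted after normalization" on the real array
  (35,760 of 45,151) reflects vendor flag filters and is consumed as
  an input list, never recomputed.
* Exact reproduction of the original study's refined DE counts is out
  of reach by design: the refinement and phase calls formalize steps
  that were originally manual/visual.
* The two-way ANOVA requires a complete balanced design with ≥ 2
  replicates per cell; missing-cell designs are out of scope.
* Input matrices must be complete; imputation is upstream of this
  package.
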