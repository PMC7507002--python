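# Methods

## The signature model

`hifsig` treats HIFα transactivity as an unobserved per-sample quantity that
(i) loads linearly on a block of HIF-inducible transcripts and (ii) scales
the hazard of death. The discovery procedure never observes the latent
activity; it reconstructs a proxy for it in four steps — correlation
expansion from canonical seed targets, an exact binomial over-representation
test, Bonferroni-masked pairwise correlation, and stepwise Cox compaction —
and the validation step asks whether the resulting score stratifies
survival. The package's claim is therefore about the *procedure*: on data
whose generating mechanism matches these assumptions, the chain recovers the
planted structure and calibrates correctly under the null.

### Seed expansion and the enrichment null

For each seed gene the remaining genes are ranked by tie-corrected
(mid-rank) Spearman ρ against the seed's expression vector; ties in ρ break
by ascending gene symbol so rankings are reproducible across platforms and
row orderings. Per-ρ p-values use the t approximation with n − 2 degrees of
freedom, adequate at the cohort sizes (hundreds of samples) this pipeline
targets; an exact permutation option exists for n ≤ 8.

The enrichment test asks whether validated HIF targets are over-represented
among the rankings: P(X ≥ hits) for X ~ Binomial(n, π), with π the assumed
genome fraction of validated targets (default 0.02) and α = 0.049. The tail
is summed directly in log space (log binomial coefficients + `logsumexp`);
no normal approximation is used at any size, and k = 0 returns exactly 1.

Two pooling semantics are provided. `per_seed_each` tests each seed's own
top-k list with n = k. The default `per_seed_union` counts distinct
catalogue genes across all per-seed lists and sets n to the number of
distinct genes pooled across those lists. The second choice is what keeps
the null calibrated: if each of s seeds contributed an independent top-k
budget while n stayed at k, the expected null hit count would be ≈ s·k·π
and essentially every null cohort would be declared enriched. With n equal
to the pooled list size, each distinct pooled gene is a catalogue member
with probability ≈ π under the null, and the measured type-I error at
α = 0.049 is ≤ 0.01 over 1,000 null cohorts (slightly conservative because
catalogue draws are without replacement). When the seeds are one tightly
co-regulated block — the intended use — their lists coincide, the pooled
size approaches k, and the two conventions agree. Seeds are excluded from
hit counting: a seed trivially correlates with itself and would inflate
enrichment. Note that with n = 200 and π = 0.02 the exact tail at 7 hits is
0.109, not below 0.049; the implementation therefore treats both π and α as
parameters rather than asserting any particular printed pairing of them.

### Bonferroni-masked correlation matrix

Over a core set of g genes, all pairwise Spearman correlations are computed
and a pair is significant when p < α_family / (g(g−1)/2) with α_family =
0.01 (g = 38 gives 703 pairs and a per-pair α of 1.42 × 10⁻⁵). The diagonal
is excluded from counting; the fraction of significant pairs is reported as
a cohesion summary of the core.

### Cox fitting and stepwise compaction

The Cox partial likelihood uses the Efron correction for tied event times —
more accurate than Breslow under the heavy ties of month-resolution
follow-up — and is maximized by Newton–Raphson with step-halving.
Convergence requires the largest score (gradient) component to fall below
1e-8 within 50 iterations; standard errors are Wald, from the inverse
observed information. Covariates are z-standardized internally by default
(coefficients on the per-SD scale); the dichotomized hazard ratio fits the
raw 0/1 group indicator so exp(β) is the high-vs-low group HR. The fitter
is verified in the tests against brute-force grid maximization of the
written-out partial likelihood on small fixtures and against an independent
library implementation on larger ones.

Stepwise selection operates directly on this partial likelihood, starting
from the empty model, with forward additions interleaved with drop scans
(`direction="both"`). The default criterion enters the candidate with the
smallest Wald p below 0.05 and removes members whose p rises above 0.10.
An information-criterion mode (`criterion="aic"`) is provided, but it is
not the default for a reason worth stating: AIC admits a null covariate
whenever its chi-square exceeds 2, i.e. with probability ≈ 0.157, so with m
pure-noise candidates the expected number of false inclusions grows as
0.157·m — at 20 candidates roughly three noise genes per run, defeating
the purpose of a compact signature. The p-threshold rule keeps false
entries at the conventional level and is the standard stepwise-Cox
convention in clinical survival modelling. Criterion ties break by
ascending gene symbol; the full add/drop trace is recorded and replays to
the final gene set. If no candidate qualifies at step one, an empty
signature with a warning record is returned rather than an exception.

The final signature size depends on the collinearity of the core: genes
loading on one latent factor carry largely redundant hazard information, so
on strongly single-factor synthetic cohorts the selected set is small (2–5
genes); real cohorts with more heterogeneous co-regulation retain more.

### Scoring and dichotomization

The default score is the unweighted mean of per-gene z-scores ("zmean"):
weight-free, hence transferable to external cohorts and platforms where
refit Cox weights would not apply. The Cox linear predictor over z-scored
genes is available as `linear_predictor`. Scores are z-standardized
(reported values are z-scores) and split at the median; samples exactly at
the median go to the low group — deterministic, and conservative for the
claim that high scores carry risk. Validation reports Kaplan–Meier curves
per group (median survival = first time S(t) ≤ 0.5, undefined if never
reached), the unweighted log-rank test, the dichotomized HR with 95% CI,
Welch's unequal-variance t (Welch–Satterthwaite df, two-sided) against a
binary clinical covariate, and per-gene fold changes between score halves
computed on back-transformed medians (expression is log2; "1.5-fold" is a
linear ratio) with a closed boundary: up iff ratio ≥ 1.5, down iff
ratio ≤ 1/1.5.

## The synthetic cohort generator

Each sample i draws latent activity h_i ~ N(0, 1). Regulon gene g measures
x_gi = λ_g·h_i + ε, ε ~ N(0, σ); background genes are independent N(0, 1).
Event times are exponential with rate h₀·exp(β·h_i), censored at an
independent U(0, C) time. The binary covariate is
Bernoulli(logistic(s·h_i)). Defaults, chosen once as a plausible bulk
tumour cohort: 2,000 background genes plus a 45-gene regulon (5 seeds + 40
targets, ≈2% of the transcriptome), n = 300 (600 for end-to-end runs),
λ ~ U(0.6, 0.9), σ = 0.5, β = 0.8 per latent SD, h₀ = 0.05 events/time
unit, C = 30 time units (≈45% event rate), s = 2. All randomness flows from
one integer seed per generator call.

What the generator does *not* emulate: count noise or platform effects,
batch structure, multiple or correlated latent programs, non-proportional
hazards, informative censoring. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated model —
not robustness to real-data violations of it.

The histology generator renders non-overlapping circular nodules on a pale
hematoxylin-like background and fills each with randomly placed small
disks of DAB-like brown (spatially clustered, as stained cell clusters
are), topping up or trimming single pixels so the positive count equals
round(f·area) exactly. Ground truth per nodule (area, equivalent diameter,
positive fraction) is returned alongside the image and label mask.

## qIHC measurements

Morphometry uses 8-connected components of the label mask; area is pixel
count × (μm/px)², the equivalent circular diameter is 2·√(A/π) (the
"cross-sectional diameter" convention used throughout), and the max-Feret
diameter is reported alongside so either reading of nodule size is
available. Border-touching components are flagged as truncated.

Positive fractions threshold either the DAB channel of the standard
Ruifrok–Johnston color deconvolution (robust to hematoxylin counterstain;
default cutoff 0.05 OD, calibrated on the synthetic slides — real assays
must calibrate per marker) or a raw channel. Fractions are monotone
non-increasing in the cutoff for polarity "above".

Size dichotomization labels nodules small/large against a reference median
diameter (large = ≥ reference, closed on the large side) and applies a
two-sided Pearson chi-square without continuity correction; expected cell
counts below 1 attach a reliability warning instead of suppressing the
test. Log-normality of diameters is assessed by Shapiro–Wilk on
log-diameters with log-normal MLE parameters returned (n ≥ 8 required).

Section alignment maximizes the FFT-based normalized cross-correlation of
mean-subtracted grayscale images over integer translations (optionally
downsampled); the returned offset is B's displacement relative to A, and a
peak NCC below the configurable floor (default 0.3) raises an alignment
failure rather than returning a spurious offset. Colocalization regresses
log-transformed matched per-nodule fractions (Pearson r, slope, slope
F-test); zeros are floored at half the smallest positive fraction and the
floor is recorded. Perfusion fractions reuse the positive-fraction contract
on a fluorescence channel. Multi-group comparisons are a thin wrapper:
Welch one-way ANOVA on log fractions with pairwise Welch t post hocs under
two-stage Benjamini–Krieger–Yekutieli FDR correction, routing two groups to
a single Welch t with a notice.

## Numerical conventions and degenerate inputs

Zero-variance vectors raise an undefined-correlation error (never a silent
ρ = 0). Constant score vectors and single-group median splits raise
degenerate-score errors. Cox fits with no events are unfittable; zero-
variance covariates are rejected as unidentifiable. Exact-median samples go
to the low group. Pixel coordinates are 0-based row-major; masks are label
images with 0 = background. Problem sizes in the test suite and acceptance
script (n = 300–600 cohorts, 1,000-cohort null calibration at 2,000 genes ×
100 samples, 20-nodule slides) were chosen as the smallest sizes at which
the planted effects are comfortably identifiable.

## Known limitations

- Gene symbols must match exactly; no identifier mapping or aliasing.
- No penalized selection, time-dependent covariates, competing risks, or
  proportional-hazards diagnostics.
- The enrichment null treats catalogue membership as independent across
  pooled genes; strong co-expression among non-regulon genes would make it
  conservative.
- qIHC thresholds are configuration, not biology: defaults are only
  meaningful for the synthetic slides.
- Whether the original clinical signatures arose from one stepwise pass or
  iterated passes, and whether seeds were forced into the model, is not
  inferable; both variants are reachable via configuration.
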