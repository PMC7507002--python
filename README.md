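# hifsig

Discovery and survival validation of compact HIFα-inducible gene signatures,
plus automated quantitative immunohistochemistry (qIHC) of stained tissue
sections.

Hypoxia-inducible factor α subunits (HIF-1α/HIF-2α) drive a transcriptional
program whose activity in tumours carries prognostic information. `hifsig`
implements the full analysis chain for deriving a compact HIFα activity score
from a tumour expression cohort and testing it against patient survival:

1. **Seed expansion.** Starting from five canonical HIF targets (BNIP3,
   DDIT4, P4HA1, P4HA2, PLAUR), every gene in the matrix is ranked by
   Spearman ρ against each seed and the top *k* (default 200) retained.
2. **Over-representation test.** Hits from a catalogue of experimentally
   validated HIF targets among the pooled rankings are tested against an
   exact binomial null, P(X ≥ h), X ~ Bin(n, π), with π the catalogue's
   assumed genome fraction (default 2%) and n the number of distinct pooled
   genes — computed by log-space summation, never a normal approximation.
3. **Correlation context.** The candidate core is summarized as a
   Bonferroni-masked Spearman matrix: family α (0.01) split over all
   g(g−1)/2 unordered pairs.
4. **Signature compaction.** Stepwise selection on the Cox
   proportional-hazards partial likelihood (Efron tie handling,
   Newton–Raphson, Wald-p entry/removal by default, AIC optional) reduces
   the core to a compact weighted signature.
5. **Scoring and validation.** Per-sample scores (unweighted mean of gene
   z-scores by default, Cox linear predictor optional) are z-standardized,
   dichotomized at the median, and validated by Kaplan–Meier curves, the
   log-rank test, the dichotomized hazard ratio with 95% CI, Welch's t
   against binary clinical covariates, and a ±1.5-fold median-split
   expression table.

A synthetic-data module generates cohorts with known ground truth — a
single latent HIF transactivity per sample, a loaded regulon block,
exponential survival with log-hazard proportional to the latent activity,
and a logistic binary covariate — so every stage of the pipeline is tested
against planted structure. The `qihc` module quantifies synthetic or real
stained sections: per-nodule morphometry (equivalent circular diameter
2·√(A/π), max Feret), fixed-threshold DAB positive-area fractions after
color deconvolution, size dichotomization with a two-sided chi-square,
log-normality checks of nodule diameters, translation alignment of
consecutive sections by normalized cross-correlation, log-scale
colocalization, and fluorescence perfusion fractions.

## Worked example

```python
from hifsig import (HifSignatureModel, SynthOmicsConfig, TargetCatalogue,
                    gen_clinical, gen_expression, gen_survival)

cfg = SynthOmicsConfig(rng_seed=11)          # 2,045 genes, 300 samples
mat, truth = gen_expression(cfg)
surv = gen_survival(truth, cfg)
clin = gen_clinical(truth, cfg)

model = HifSignatureModel(mat, surv, TargetCatalogue(tuple(truth.regulon_members)))
results = model.fit()
print(results.summary())
```

```
HIF-inducible signature fit
===========================
Samples: 300   Genes: 2045   Events: 142
Seeds: BNIP3, DDIT4, P4HA1, P4HA2, PLAUR
Expansion: 40 catalogue hits among 455 pooled genes; binomial P = 1.39e-14; enriched = True
Core correlation: 780 pairs, per-pair alpha = 1.28e-05, significant fraction = 1.00
Signature (3 genes, criterion=pval, direction=both):
           coef     se     HR  HR 95% lo  HR 95% hi      p
HIFT020  0.3823 0.1233 1.4657     1.1511     1.8662 0.0019
HIFT021  0.3758 0.1302 1.4562     1.1281     1.8797 0.0039
HIFT035 -0.2957 0.1318 0.7440     0.5746     0.9634 0.0249
```

All 40 planted regulon targets are recovered among the seed rankings
(binomial P ≈ 1e-14 against the 2% null), every core gene pair survives the
Bonferroni mask, and stepwise Cox compacts the collinear 40-gene block to
three genes carrying independent hazard information.

```python
v = results.validate(clinical=clin)
print(v.summary())
```

```
Score validation
================
KM median survival: high = 9.18, low = 16.8
Log-rank: chi2 = 11.353 (df=1), P = 0.000753
HR (high vs low) = 1.767 [1.263, 2.471]
Welch t = 11.949 (df = 283.2), P = 6.39e-27
Fold change (|1.5x|): 40 up, 0 down of 40 core genes
```

High-score patients reach median survival at 9.2 versus 16.8 time units
(log-rank P = 7.5e-4; HR 1.77, CI excluding 1), the score separates the
simulated clinical covariate (Welch t = 11.9), and all 40 core transcripts
are >1.5-fold up in the high-score half — the qualitative pattern the score
is designed to detect. `results.validate(expression=..., survival=...)`
transfers the gene list to an external cohort by re-scoring with unweighted
z-means. `results.plot_km()` draws the Kaplan–Meier curves.

The same stages are available from the shell:

```sh
hifsig simulate --out run/ --seed 3
hifsig discover --expression run/expression.tsv --survival run/survival.tsv \
                --catalogue run/catalogue.txt --out run/disc
hifsig validate --scores run/disc/scores.tsv --survival run/survival.tsv \
                --clinical run/clinical.tsv --out run/val
hifsig qihc --image slide.png --mask mask.png --um-per-px 1.0 --out run/qihc
```

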