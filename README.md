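# histoqtl

Genome-wide association testing of **high-dimensional image-derived tissue
embeddings** against genetic variants — the statistical engine for mapping
*tissueQTLs*: loci whose genotype shifts tissue morphology as captured by
patch-embedding representations of histology slides.

## Who this is for

Groups that already have (i) genotypes for a cohort, (ii) per-individual
embedding vectors summarizing tissue images (e.g. mean patch embeddings of
a morphological cluster signature, reduced to L ≈ 64 dimensions), and
(iii) standard covariates, and who want calibrated multivariate GWAS of
those embeddings plus the downstream toolkit: permutation-based multi-trait
FWER thresholds, colocalization with molecular/complex-trait summary
statistics, embedding-space interpretation of hits, and expression
prediction for encoder benchmarking.

## The model

For a variant with dosage vector **g** across N individuals, embeddings
**X** (N × L) and covariates **F** (N × K), the package tests the
generalized variance component model

```
g = F α + u,   u ~ N(0, σx² K(X)),   K(X) = X̃ X̃ᵀ
```

where X̃ has unit-norm rows, so K is the cosine-similarity kernel between
individuals' tissue phenotypes. Association is a score test of σx² > 0 with
statistic Q = ‖X̃ᵀ r‖² = rᵀ K r (r the covariate residual of g), whose null
distribution is a weighted sum of 1-df chi-squares with weights
σ² · eig(X̃ᵀ M X̃) — everything is computed in the L-dimensional space, never
forming the N × N kernel.

Two tail evaluations are provided:

* the **exact finite-sample null** of the standardized statistic Q/σ̂²,
  obtained by writing {Q/σ̂² > t} as a signed chi-square mixture and
  inverting its characteristic function (the default; immune to the error
  of plugging σ̂² into the asymptotic mixture);
* the classical **Davies / Liu** machinery for arbitrary nonnegative
  mixtures (characteristic-function inversion with a moment-matched
  chi-square fallback), which also backs the extreme tails.

Downstream components: pooled min-P permutation thresholds (empirical
α-quantile divided by the trait count), BIC-approximated log Bayes factors
`(χ² − ln N)/2` feeding standard single-causal-variant colocalization
posteriors (PP-H0…H4), genetic-effect-axis estimation and embedding
interpolation, BLUP expression prediction from the embedding kernel, and a
synthetic-cohort simulator for calibration and power analysis.

## Worked example

```python
import numpy as np
from histoqtl import (SimConfig, simulate_cohort, cosine_normalize,
                      test_variant, estimate_axis)

# a 1,000-individual cohort in which one variant explains 1% of the
# trace variance of a 64-dimensional embedding
cfg = SimConfig(n=1000, L=64, v=0.01, seed=3)
g, F, E = simulate_cohort(cfg)

res = test_variant(g, F, cosine_normalize(E))
print(f"Q = {res.Q:.1f}, p = {res.p_value:.3g} ({res.method})")

ax = estimate_axis(g, F, E.values)
print(f"axis recovery |cos| = {abs(ax.beta @ E.planted_direction):.3f}")
```

prints

```
Q = 3662.5, p = 2.39e-113 (liu)
axis recovery |cos| = 0.965
```

i.e. the variant is detected far beyond genome-wide significance
(P < 5 × 10⁻⁸; the tail is so extreme that the Liu moment-matched fallback
reports it) and the estimated direction of its effect in embedding space
matches the planted one almost exactly. With `v=0.0` the same pipeline
returns uniform p-values (see the calibration harness below).

The same analyses run from the shell on delimited files:

```bash
histoqtl scan --vcf geno.vcf --embeddings emb.tsv --covariates cov.tsv \
    --maf-min 0.05 --out scan.tsv
histoqtl permute-threshold --vcf geno.vcf --embeddings emb.tsv \
    --covariates cov.tsv --n-perm 100 --alpha 0.2 --n-traits 68 --out minp.tsv
histoqtl coloc --trait1 scan_lbf.tsv --trait2 eqtl_lbf.tsv \
    --center 9:1234567 --window 1000000 --out coloc.tsv
histoqtl simulate-power --grid-n 650,2000,10000 --grid-v 0.001,0.01 \
    --seeds 100 --out power.tsv
```

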