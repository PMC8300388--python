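# panelgp

**SNP-panel pruning strategies, marker-density metrics and GBLUP
cross-validation for genomic prediction.**

`panelgp` is for quantitative geneticists who thin dense SNP data into
prediction panels and want to know which notion of "marker density" actually
matters for accuracy. A panel's SNP count hides how its markers are spread:
two 10 k panels can differ wildly in the variance of the physical distance
between adjacent SNPs (σd²) and in the adjacent-pair LD (r²̄, σr²²). The
package implements:

* three panel constructors at exact target sizes — minimum-physical-distance
  thinning (**PhyD**), sliding-window LD pruning (**GenD**, 50 kb windows /
  5 kb steps, pairwise r² ceiling) and random sampling (**RanD**);
* the four density statistics d̄, σd², r²̄, σr²² per panel;
* GBLUP with VanRaden's G = WW′/2Σp(1−p), AI-REML variance components and
  the joint mixed-model equations (validation individuals predicted through
  their relationships), under repeated k-fold cross-validation where the
  accuracy is the Pearson correlation of pooled held-out GEBVs with the
  phenotype;
* the pooled correlation analysis relating density measures to accuracy:
  within every SNP-count level both are standardized to mean 0 / SD 1 over
  the three methods (z = (x−mean)/sd), then all (measure, accuracy) pairs are
  pooled across levels and traits and tested with the t statistic of the
  Pearson r;
* a synthetic-cohort generator (clustered marker maps, LD decaying as
  exp(−gap/λ), optional half-sib family structure, tiered QTL architectures
  with calibrated heritability) so the whole pipeline runs without any
  external download;
* a packaged 33-row reference table (11 SNP levels × 3 methods from a
  2,000-bull Holstein cohort: density measures plus 10×10-CV accuracies for
  milk fat percentage FP, milk yield MY and somatic cell score SCS) from
  which the headline correlations are reproduced exactly.

## Worked example

Reproduce the pooled density-accuracy correlations from the packaged table:

```
$ panelgp reproduce-reference
sigma_d2_1e10_all_levels   r=-0.834  t=-14.87  p=9.090e-27  n=99
sigma_d2_1e10_scs_15_50k   r=-0.553  t=-2.10   p=6.208e-02  n=12
r2_mean_all_levels         r=0.094   t=0.93    p=3.533e-01  n=99
r2_mean_scs_15_50k         r=-0.809  t=-4.35   p=1.451e-03  n=12
r2_var_all_levels          r=-0.034  t=-0.34   p=7.369e-01  n=99
r2_var_scs_15_50k          r=-0.772  t=-3.84   p=3.283e-03  n=12
```

Reading the first line: across all 99 (level-standardized) pairs, the
variance of the physical gap between adjacent SNPs is strongly negatively
correlated with GEBV accuracy (r = −0.83, p < 0.001) — at a fixed SNP count,
evenly spread panels predict better — while the LD-based measures show no
relationship overall (r = 0.09 and −0.03). Only for the purely polygenic
trait (SCS) at moderate densities (15–50 k) do the adjacent-r² measures
correlate negatively with accuracy (r ≈ −0.8).

The same contrast appears on simulated data. Build two 200-SNP panels from
one synthetic cohort and compare their density measures:

```
$ panelgp simulate --out-prefix demo --n-individuals 200 --n-markers 2000 --seed 7
wrote 200 x 2000 to demo.bed/.bim/.fam
$ panelgp prune --bed-prefix demo --method PhyD --target-count 200 --out phyd.txt
PhyD: kept 200 of 2000 markers
$ panelgp metrics --bed-prefix demo --panel-file phyd.txt
n_markers      200
d_mean         1273854.7
sigma_d2_1e10  1.21854
r2_mean        0.0086
$ panelgp prune --bed-prefix demo --method RanD --target-count 200 --out rand.txt --seed 7
$ panelgp metrics --bed-prefix demo --panel-file rand.txt
n_markers      200
d_mean         1239287.7
sigma_d2_1e10  160.399
r2_mean        0.1389
```

Same SNP count, nearly the same mean gap — but the random panel's gap
variance is two orders of magnitude larger, the pattern that drives the
accuracy differences above. `panelgp gblup-cv` then cross-validates any
panel against a phenotype table, `panelgp scenario` runs the controlled
gap-variance experiment (equal-mean-gap panels with index-gap variance 0,
20, 40, 80; accuracy declines as variance grows), and `panelgp pipeline`
chains simulate → prune → metrics → CV → correlate into one reproducible run
directory.

The library mirrors the CLI: `panelgp.prune_phyd`, `panelgp.prune_to_count`,
`panelgp.density_measures`, `panelgp.build_grm`, `panelgp.ai_reml`,
`panelgp.solve_mme`, `panelgp.cv_accuracy`, `panelgp.pooled_correlation`.
See `docs/methods.md` for the model, algorithms and simulation design.

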