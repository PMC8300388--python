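# Methods

## The question the package addresses

"Marker density" in genomic prediction is usually read as the SNP count of a
panel, but panels with the same count can differ sharply in how their markers
are spread along the genome. This package implements the machinery to ask a
sharper question: at a fixed SNP count, which density statistics — the
variance of the physical distance between adjacent markers (σd²), or the mean
and variance of the adjacent-pair LD (r²̄, σr²²) — track GBLUP prediction
accuracy?

Three panel-construction strategies are compared:

* **PhyD** — greedy thinning enforcing a minimum physical gap (bp) between
  adjacent kept markers. Produces near-equidistant panels (small σd²).
* **GenD** — PLINK-style sliding-window LD pruning (50 kb windows, 5 kb step):
  one member of any surviving pair with dosage r² above a ceiling is removed
  (the smaller-MAF member; ties drop the later marker). Produces panels with
  low mutual LD but large physical gaps.
* **RanD** — uniform random sampling without replacement.

`prune_to_count` bisects the PhyD/GenD threshold until the panel brackets a
target SNP count and removes any surplus by seeded uniform thinning, so all
three strategies can be compared at identical panel sizes. LD pruning has a
survivor ceiling (with the r² ceiling just below 1 only exact duplicates are
removed); unreachable targets raise a dedicated error carrying the achievable
maximum.

## GBLUP model

The prediction model is `y = 1μ + Zg + e` with `g ~ N(0, G σg²)`,
`e ~ N(0, I σe²)`, where `y` are EBV-like pseudo-phenotypes and
`G = WW′ / 2Σ p_k(1−p_k)` is VanRaden's genomic relationship matrix built
from the panel's markers (`W` the 0/1/2 dosage matrix centered by `2p_k`;
missing dosages mean-imputed; monomorphic markers contribute nothing).

Variance components are estimated by average-information REML. All
per-iteration quantities are evaluated in the eigenbasis of the (training) G,
where `V = σg²G + σe²I` is diagonal, making each iteration O(n) after one
O(n³) eigendecomposition. Newton steps use the AI matrix; a step that exits
the parameter space is truncated at the boundary, step-halved until the
restricted likelihood does not decrease, and replaced by an EM-REML step if
no improvement is found. Components are floored at `1e-8 × Var(y)`;
convergence requires relative parameter change and log-likelihood change
below 1e-8, or the KKT condition (near-zero gradient, or a floored component
with an outward-pointing gradient). Starting values split `Var(y)` equally.
With `G = I` the split is unidentifiable; the estimated total converges to
the sample variance (n−1) and only the total is meaningful.

GEBVs for all individuals — validation individuals have no record but stay
in G — come from the joint mixed-model equations. The implementation solves
the G-premultiplied form of the MME (the random-effect block multiplied
through by `σg²G`), which has the same unique solution but requires no
`G⁻¹`: a VanRaden G built with observed frequencies is exactly singular (its
centered columns put the 1-vector in the null space), so the textbook
`(G σg²)⁻¹` form would need an arbitrary ridge on every real dataset. The
premultiplied system is exact for any PSD G; equivalence with the direct
`V⁻¹`-based BLUP/GLS solution is enforced to 1e-8 in the test suite. A 1e-8
diagonal ridge remains as a logged fallback if the assembled system is
singular.

Accuracy is measured by repeated k-fold cross-validation: per repeat,
individuals are partitioned into k near-equal folds; variance components are
re-estimated on every training set; the held-out GEBVs of all folds are
pooled and correlated (Pearson) with the phenotype — one accuracy per
repeat. Folds whose REML is flagged non-converged are excluded from pooling
with a warning (none occur in the shipped tests).

## Density statistics

For a panel: mean and variance of physical gaps between adjacent markers,
and mean and variance of dosage r² between adjacent markers, computed only
within chromosomes. Variances are sample variances (n−1; the distinction is
negligible at thousands of gaps but is fixed for test determinism). Pairs
with a monomorphic member have undefined correlation and are skipped and
counted. Gap variances are also reported in units of 10¹⁰ bp², the
convention of the packaged summary table.

## Pooled correlation analysis

Panels at the same SNP-count level are standardized within the level:
`z_i = (x_i − mean(x)) / sd(x)` over the level's three methods (sample SD,
n−1 over 3 values; the pooled correlation is invariant to any per-level
affine rescaling, so the denominator convention cannot change it). Each
row's standardized measure is paired with the standardized accuracies of the
selected traits, pairs are pooled across levels and traits, and the Pearson
correlation is tested with `t = r√((n−2)/(1−r²))`, two-sided p from the t
distribution with n−2 df. Pairs sharing a row are treated as independent —
the plain test the headline n = 99 implies; no repeated-measures correction
is applied.

The packaged reference table (33 rows: 11 levels from 1 k to 50 k × PhyD/
GenD/RanD, with σd², r²̄, σr²² and 10×10-CV accuracies for a fat-percentage,
milk-yield and somatic-cell-score trait in a 2,000-bull Holstein cohort) is
checksum-verified on load. From it the package reproduces:

* r(σd², accuracy) = −0.834 over all 99 pairs (p < 0.001);
* restricted to 15–50 k and the polygenic trait (SCS): r(σd², acc) = −0.553
  (from the rounded table cells; the three-decimal rounding shifts the
  second decimal), and r(r²̄, acc) = −0.809, r(σr²², acc) = −0.772, both
  p < 0.01.

## Synthetic cohorts

The generator produces the structural features the analysis needs, not a
population-genetic history:

* **Maps** — markers allocated to chromosomes proportionally to length;
  uniform spacing, or clustered spacing with log-normal gaps (σ = 0.8 log
  units) rescaled to the chromosome length — the heavy-tailed gap
  distributions dense real chips show. Default genome: 5 chromosomes × 50 Mb.
* **LD** — haplotypes follow a first-order Markov chain: the allele at
  marker j copies marker j−1 with a probability calibrated so the
  adjacent-allele correlation is `exp(−gap/λ)` (λ = 500 kb by default,
  long-range LD of a small-Ne livestock population), restarting at
  chromosome boundaries. Allele frequencies are uniform on [0.05, 0.5].
  Dosage = sum of two independent haplotypes, so dosage r² decays with
  physical distance — the property that separates PhyD/GenD/RanD panels.
* **Relatedness** — optionally a paternal half-sib design: each individual
  receives one gamete from one of `n_families` sires (recombination 1e-8
  per bp, ~0.5 crossovers per 50 Mb chromosome) and one fresh population
  haplotype. Progeny-tested bull cohorts are strongly family-structured, and
  without relatedness GBLUP accuracy at sparse-panel densities collapses to
  ~0.1, far below the 0.5–0.7 regime the reference table reflects.
* **Traits** — `y = μ + Σ w_k a_k + e` with QTL sampled from the markers and
  tiered N(0, sd²) effects: FP-like (2 major, sd 10 + 300 small, sd 1),
  MY-like (20 moderate, sd 3 + 300 small), SCS-like (300 small). The
  residual SD is calibrated against the realized genetic variance, so the
  realized heritability matches the target. Phenotypes are single EBV-like
  records with no fixed effects beyond the mean.

What the generator does **not** emulate: mutation/drift equilibrium LD
structure, allele-frequency–dependent LD, selection, multi-generation
pedigrees, genotyping error, or imputation artifacts. Passing tests on these
cohorts show the pipeline's statistical machinery behaves as designed, not
that real-data accuracies are reproduced; the real-cohort results enter
through the packaged summary table.

## The gap-variance scenario experiment

To isolate σd² from SNP count, panels are built by walking the ranked marker
list with index gaps of constant mean 67: variance 0 steps exactly 67;
variances 20/40/80 draw normal gaps (rounded to integers, truncated at 1).
All panels share the mean gap (hence panel size and d̄) and differ in gap
variance. The shipped experiment (`panelgp.cli.scenario_gap_experiment`)
runs 10 cohorts (seeds 0–9: 500 individuals in 25 half-sib families, 50,000
clustered markers, SCS-like trait at heritability 0.8 — the reliability
scale of proven-bull EBVs) and 5-fold CV per panel. At these conditions mean
accuracy declines monotonically with gap variance (≈0.412 → 0.391 from
variance 0 to 80; Spearman −1.0 over the four scenario means).

The effect is small relative to between-cohort noise: a single cohort's
scenario ordering is frequently scrambled, and 10-seed means at other seed
bases gave Spearman between −0.8 and −0.2 (occasionally positive). The test
asserts the sign of the rank correlation at the frozen seeds, which is the
honest strength of the desk-scale claim.

## Numerical and policy choices

* Positions are 1-based bp; all gap arithmetic is raw integer differences.
* HWE filtering uses the plain 1-df chi-square test (not an exact test), the
  era-default behavior; flagged in `genotype_io` docs for users.
* r² is the squared Pearson correlation of unphased dosages over pairwise
  non-missing calls (PLINK's default on unphased data), not haplotype D′².
* Windows in GenD are physical spans that never cross chromosomes; pairs
  farther apart than window − step (45 kb) may never share a window position
  and are exempt from the verification rescan by construction.
* `prune_to_count` enforces exact panel sizes by seeded uniform removal of
  the surplus from the tightest bracketing threshold.
* The scenario walk rounds normal draws to the nearest integer and truncates
  at 1; realized mean gaps stay within ±2 of the target.
* CV repeat r derives its fold seed as `seed + r`; every stochastic stage
  takes an explicit seed and is bit-reproducible.

## Problem sizes in the shipped tests

Unit tests use cohorts of 20–400 individuals and 2–3,000 markers. The REML
calibration check uses 20 cohorts of 800 × 2,000 (mean ĥ² 0.496 for target
0.5); the MME-vs-oracle equivalence uses 200 random instances of n ≤ 20; the
scenario experiment uses 10 cohorts of 500 × 50,000. The full suite runs in
about a minute on one CPU.
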