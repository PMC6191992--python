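# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## The synthetic study generator

The generator emulates a two-species iPSC differentiation time course:
`n_human` and `n_chimp` cell lines sampled at days 0..D−1, with a
configurable subset of lines carrying a second technical replicate (the
default replication scheme — every chimpanzee line and two human lines
duplicated — reproduces the canonical 64-sample layout for 6 + 4 lines over
4 days). Library sizes are log-normal around 2×10⁷ reads (σ = 0.25 on log2);
a `deep_sample` knob inflates one library to exercise the depth-subsampling
rule (`subsample_depth` binomially thins a library exceeding the
second-largest by ≥ 1.8×).

Counts are negative-binomial with mean
`lib_k · 2^η_gk / Σ_g 2^η_gk` and constant dispersion φ (default 0.1;
`var = μ + φμ²`; φ = 0 is the deterministic noise-free limit). The log2
signal η stacks:

* a baseline per gene, N(6, 1.5²);
* a species shift N(0, 0.75²) on a `species_de_fraction` (default 0.4) of
  genes;
* cumulative day effects driven by a motif assignment: each motif specifies
  which consecutive-day transitions move in each species, and flagged
  transitions share one N(0, 1.5²) effect draw across species (so conserved
  motifs produce genuinely conserved trajectories). The default motif mix is
  40% flat genes, a conserved early/all/mid/late spectrum, and two 5%
  species-specific late classes;
* a per-gene × individual × day intercept, redrawn each day with a
  day-specific SD. The default SD is 1.5; on genes flagged for variance
  reduction the SD at `var_shrink_day` (default day 1) is multiplied by
  `var_shrink` (default 0.5). Redrawing each day keeps the per-day sample
  variances independent, which is what gives the two-day F tests their
  nominal null distribution; an optional `ind_persist_sd` adds a persistent
  line component for experiments with cross-day correlation (off by
  default, because any shared component makes the F-test null conservative);
* technical-replicate noise N(0, 0.1²).

The default day-0 individual SD (1.5, vs NB noise contributing ≈ 0.2 to the
log2-scale variance) was fixed by a power analysis of the F tests at
n = 6 individuals: with the prescribed shrink 0.5 the expected day-0/day-1
variance ratio is ≈ 3.2, large enough that the π̂₁ estimators recover the
flagged fractions to within ±0.1 despite (5, 5)-df tests.

**Variance-reduction flags and sharing.** Fractions `f_human` and `f_chimp`
of genes are flagged per species. Their overlap is
`max(s·min(f_H, f_C), f_H + f_C − 1)·G` genes, where `s` is the sharing
parameter: `s = 1` nests the rarer set inside the larger one, `s = 0` gives
the smallest overlap the marginals allow (zero when `f_H + f_C ≤ 1`). The
overlap is monotone in `s`, which is the property the recovery tests use.
Note that "independence-level" overlap corresponds to `s = f_H`, so small
`s` encodes *anti*-sharing; the conditional-sharing estimator sees this as
an observed value below its permutation null.

**Flow cytometry.** One flow sample per (individual, day): cells are drawn
from per-day 6-dimensional Gaussian components (default means separated by
≥ 6 unit SDs, patterned after pluripotency/endoderm marker panels:
OCT3/4⁺SOX2⁺ at day 0, EOMES⁺ at day 1, SOX17⁺CKIT⁺ at day 2,
CKIT⁺CXCR4⁺ at day 3). Each sample's true purity is its per-day baseline
(0.90/0.85/0.75/0.70) plus N(0, 0.03²) jitter; contaminating cells come
from the other days weighted toward adjacent stages. A non-positive-definite
component covariance is rejected.

**What the generator does not emulate:** read-level sequencing artifacts,
mapping or ortholog-assignment bias, gene–gene correlation beyond the shared
library size, GC/length effects on counts (gene lengths exist only for RPKM
arithmetic), day-specific purity gradients in the *expression* data, and
doublets or spectral spillover in the flow data. Passing recovery tests
therefore certifies the statistics under the model's assumptions, not
robustness to those artifacts.

## Normalization

* **Filtering**: keep genes with log2 CPM strictly above 1.5 in at least
  `min_per_species[sp]` samples of *every* species (both-species reading;
  the per-species minimum is configurable, e.g. 15/16 after dropping an
  outlier sample). Outlier exclusion is an explicit `exclude_samples` list,
  never automated.
* **log2 CPM**: the prior count (default 0.5) is applied on the CPM scale —
  sample k's prior is `0.5·L_k/10⁶` with the denominator enlarged by twice
  that — making log-CPM exactly invariant to rescaling a sample's counts and
  depth together.
* **TMM**: reference = sample whose upper-quartile count fraction is closest
  to the mean upper quartile (ties to the lowest column index); per sample,
  gene-wise M and A versus the reference over genes positive in both; double
  trim (30% on M, 5% on A, rank-based); factor = weighted mean of trimmed M
  with inverse delta-method variance weights; factors centered to zero mean
  log. This matches the reference R implementation to ~10⁻⁸ on fixtures.
  Exact scale invariance holds only for global rescaling: scaling one sample
  perturbs the variance weights (a ~1% effect on factors), which the tests
  document rather than hide.
* **Cyclic loess**: for each sample pair, lowess of M on A (span 0.5, with a
  1%-range delta for speed), each sample moved half the fitted trend; 3
  cycles by default. Pair A-values are conserved exactly.
* **Precision weights**: per-gene OLS on the design, lowess (span 0.5) of
  √(residual SD) on average log2 count, per-observation prediction at the
  fitted log2 count via monotone linear interpolation with constant
  extrapolation, weight = prediction⁻⁴ (floored at 10⁻⁴ before inversion).
* **Technical replicates**: `post_average` (mean of normalized values per
  individual × day) or `pre_sum` (sum raw counts, renormalize). The two
  agree at r > 0.99 on simulated data; `post_average` is the default used
  by the variance analysis.

## Differential expression

Design: treatment coding with reference (human, day 0) — intercept, species,
D−1 day indicators, D−1 interactions. Day is categorical here (the tests are
pairwise), numeric only in the QC regressions. The "interaction at day d"
contrast is the species difference-of-differences relative to day 0.

The within-block correlation is estimated from OLS residuals by a
bias-corrected moment equation: with M the residual projector and C the
within-block adjacency, E[Σ_pairs e_i e_j] = σ²(a + ρb) and
E[RSS] = σ²(n − p + ρc) with a, b, c computable from M and C, so ρ solves a
linear equation per gene; estimates are pooled by a 15%-trimmed mean on the
atanh scale and clipped to the admissible range (−1/(m_max−1), 1). The
correction matters: the naive estimator is biased low and inflates the
realized FDR. Blocks are caller-specified — the cell line for real designs
with cross-day line effects, the (individual, day) differentiation for data
from this generator (whose intercepts are redrawn per day).

GLS uses the equicorrelation whitener R^(−1/2) with per-observation weights
as diag(1/w); with weights absent the fit vectorizes across genes, with
weights it is a per-gene QR solve. Moderation matches the first two moments
of log s² to a scaled F: solving trigamma(d₀/2) = var(log s²) −
trigamma(d/2) by Newton (50 iterations, relative tolerance 10⁻¹⁰); a
non-positive excess variance gives d₀ = ∞ (complete pooling). BH adjustment
comes from statsmodels and is cross-checked against a brute-force step-up.

Two-cutoff sharing: shared = strict (q < 0.01) in one species and loose
(q < 0.05) in the other; the conditional percentage divides strict-B ∩
loose-A calls by loose-A calls.

## Correlation motifs

Study statistics: per species and day transition (consecutive scheme, or
all-vs-day-0; `max_day` drops late transitions), a two-day moderated fit
blocked on individual gives t and its total df (capped at 200 to keep the
t density well-defined in the complete-pooling limit). The alternative
density is a central t scaled by √(1 + v₀); v₀ is estimated per study by a
small two-group EM whose update moment-matches the responsibility-weighted
second moment of t (floor 0.05, start π₁ = 0.2, v₀ = 4).

The mixture EM works with the bounded density ratio A = f₁/f₀:
log P(t_g|k) − Σ log f₀ = Σ_d log(1 + q_kd(A_gd − 1)). E-step
responsibilities and per-study DE responsibilities are exact; M-step updates
are closed-form. Convergence at Δℓ < 10⁻⁶ or 500 iterations; q clipped to
[10⁻⁶, 1 − 10⁻⁶]; the log-likelihood is asserted non-decreasing every
iteration. Restarts draw q ~ U(0.05, 0.95) and π ~ Dirichlet(1); the best
restart by log-likelihood wins; 100 restarts by default (tests use fewer on
small instances). BIC = −2ℓ + (K−1 + K·D)·ln G, AIC analogous.

Assignment is conservative: a gene joins its maximum-posterior motif only if
its own per-study posterior DE calls (≥ 0.5 counts as DE, the boundary
included) reproduce that motif's rounded pattern; otherwise it is
unassigned. Trajectory sharing requires |posterior DE(human) − posterior
DE(chimp)| ≤ 0.20 at every paired transition; the shared fraction is over
assigned genes.

## Variance dynamics

Variances are computed on combined-replicate values, per gene/species/day,
with n ≥ 2 individuals; zero variances become missing (not floored) on the
log2 scale — their genes drop out of the global tests but keep their
gene-level F tests (F = ∞ → p = 0 under the reduction alternative, flagged
degenerate).

* Global shift: one-sided Welch t on the log2-variance distributions
  (day_a > day_b alternative); a paired per-gene variant is available since
  the pairing convention is a genuine free choice.
* Divergence shift: one-sided Mann–Whitney U on |log2 FC| of DE genes
  (FDR 5%) from the two days' species contrasts.
* π̂₀: Storey's grid λ = 0.05..0.95 (step 0.05), natural cubic spline with
  3 df (interior knots at the grid's tertiles) evaluated at λ = 0.95,
  clipped to [0, 1]. A bootstrap alternative (λ minimizing the bootstrap
  MSE around the minimal grid value, 100 resamples) is provided as a
  robustness check.
* Conditional sharing: π̂₁ of species 2 restricted to species-1 genes with
  p < cutoff (default 0.05; cutoff 1 recovers the unconditional value;
  subsets under 50 genes warn). A top-N variant sweeps the N smallest
  species-1 p-values.
* Permutation null: permuting species-1 p-values across genes is equivalent
  to conditioning on a uniformly random subset of the observed size, which
  is how the implementation draws it (vectorized over permutations, the
  spline smoother applied as a single linear projection). The null value is
  the mean draw; the one-sided empirical p uses the add-one rule
  (1 + #{draws ≥ observed})/(B + 1). Default 10⁴ draws (10⁵ reproduces
  archival-scale precision at ~10× the cost).
* Purity adjustment: samples with purity contribute residuals of a per-gene
  within-species regression of expression on purity (constant purity falls
  back to centering, with a warning); each track's log2 variances are
  shifted so its species' day-0 median equals 1; tracks are averaged per
  gene/species/day.

## Flow-cytometry purity

Cells are subsampled uniformly without replacement (default 1,000 per
sample; smaller samples are kept whole with a warning). k-means (k-means++,
10 restarts, seeded) runs on the rows of the cell–cell Pearson correlation
matrix; zero-variance marker vectors are dropped (correlation undefined)
and reported as unassigned. Above 20,000 cells the correlation rows are
computed blockwise with identical results, but note the matrix itself is
O(n²) memory (~8 GB at the 31,000-cell archival scale) — the examples and
tests run at a few hundred cells per sample, which leaves the estimator
unchanged. Cluster-to-day matching is by majority day (ties to the lower
day), replacing visual PCA matching so the pipeline is automatic; the first
three PCs of the correlation rows are returned for audit. Per-sample purity
is the fraction of cells in the sample's own-day cluster(s).

## QC screen

PCA centers genes and decomposes the sample space by SVD; PC scores are
regressed on day (numeric trend) and a species indicator. Stage 1 fits one
model per (PC 1–5, factor) — regression for numeric factors, one-way ANOVA
across levels otherwise — and applies BH across the full matrix at FDR 10%.
Stage 2 associates survivors with day and species: ANOVA for numeric
factors; for categorical factors a chi-square independence test with a
Monte-Carlo p (tables resampled at fixed margins, default B = 10⁴, add-one
p). On small tables the Monte-Carlo p is exactly discrete and can sit at
1 when the observed statistic is the distribution's floor; it converges to
the asymptotic p on large balanced tables. The partition test compares
`factor ~ species + day` against `+ species:day`: nested-ANOVA F for
numeric factors, binomial-GLM deviance vs chi-square for two-level factors,
multinomial-logit likelihood ratio (BFGS — Newton is fragile on sparse
cells) for more levels; empty species × day cells are an error naming the
cells.

## Known limitations

* The consensus-correlation GLS is a single-ρ approximation; genes whose
  true block correlation deviates strongly are mis-weighted (per-gene REML
  would address this at ~100× the cost).
* π̂₁ estimates are attenuated by incomplete power (visibly so at n = 6
  individuals and (5, 5)-df F tests); recovery tests budget ±0.1 for this.
* The motif alternative density assumes a single scale inflation per study;
  heavy-tailed effect-size mixtures would call for a nonparametric f₁.
* The permutation null preserves only the marginal p-value distribution;
  gene-level couplings (e.g. expression-dependent power affecting both
  species) shift observed conditional π̂₁ away from the null even without
  flag-level sharing, which is a real property of the estimator, not of the
  implementation.
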