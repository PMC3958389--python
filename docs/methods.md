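# Methods

## The genetic model

A biallelic QTL segregates in a cross between inbred lines P1 (allele A)
and P2 (allele B).  Ordered genotypes record parental origin (maternal
allele first): AmAf, AmBf, BmAf, BmBf.  The genotypic mean is

    mu + c*m + a*x_a + d*x_d + i*x_i + ica*(m*x_a) + icd*(m*x_d) + ici*(m*x_i)

* `m` — cytoplasm indicator, −1 for a P1 maternal line, +1 for P2.  P1 is
  the reference line; the P2 cytoplasm carries the effect `c`.
* `x_a, x_d, x_i` — additive/dominance/imprinting indicators per ordered
  genotype: (+1,0,0), (0,1,+1), (0,1,−1), (−1,0,0) in the order above.
  The imprinting effect `i` is therefore half the difference between the
  two reciprocal heterozygote means; `ica, icd, ici` are the cytoplasm ×
  nuclear interactions.

Stacking the rows for all classes of a design (reciprocal F2: 2 cytoplasm
states × 4 genotypes; reciprocal backcross BC1–BC4: 4 crosses × 2
segregating genotypes) yields an invertible 8×8 matrix; `effects_from_means`
solves the inverse problem exactly.  Both design matrices have condition
number ≈ 2.62 (benign).

## Genotype posteriors with sex-specific recombination

The QTL genotype is missing data.  Given the two flanking markers, the
package enumerates the ordered alleles carried by the maternal and the
paternal gamete at the flanks (16 configurations), weights each by its
two-locus gamete probability, multiplies in the three-point conditional
probability of the QTL allele per gamete, and marginalizes onto the
observed unordered marker codes.  Missing marker codes are summed over
exactly (no imputation).

Sex matters: the maternal gamete recombines at female map distances and
the paternal gamete at male distances.  A sex-averaged map plus the
constant expansion ratio λ (`d_f = 2λd/(1+λ)`, `d_m = 2d/(1+λ)`; λ = 1.25
for mouse genome-wide) defines both.  The Haldane map function
`r = (1 − exp(−2d/100))/2` is used throughout; its no-interference Markov
property is what justifies the three-point factorization
`P(q | l, r) = t1·t2/t12`.

A structural fact worth knowing: when *both* flanking markers are
heterozygous, swapping the A/B labels of both gametes is an exact symmetry
that exchanges the reciprocal heterozygotes, so P(AmBf) = P(BmAf) for any
λ.  Sex-specific rates separate the reciprocal heterozygotes only through
asymmetric flank configurations (e.g. AA on one side, AB on the other).
This is why imprinting is testable but weakly identified in F2 data.

For backcrosses the paternal gamete is fixed by the recurrent parent, so
the posterior reduces to the maternal (female-rate) gamete term over two
components.

## Mixture likelihood and EM

Phenotypes are a K-component Gaussian mixture (K = 4 for F2, 2 for BC)
with component means `row_ij · beta` and a common variance sigma^2.  Null
models zero subsets of {c, a, d, i, ica, icd, ici}; `mu` and sigma^2 are
always free.  EM:

* E-step: responsibilities ∝ prior × normal density (computed with a
  per-row max shift; no underflow for any realistic data).
* M-step: responsibility-weighted least squares over the free columns;
  sigma^2 = weighted mean squared residual (MLE, divisor n).
* Initialization: one weighted least-squares pass using the prior mixture
  proportions as weights — deterministic, no seed dependence.
* Convergence: log-likelihood increment < 1e-8 (absolute), max 500
  iterations; non-convergence is flagged, not raised.  The log-likelihood
  is nondecreasing by construction and asserted in tests.
* Singular weighted normal equations (e.g. a single cross direction makes
  `c` and `mu` collinear) raise an error naming the free effects.

The genome scan warm-starts each grid position's EM from the previous
position's estimates — adjacent positions share flanking markers, so the
optimum moves smoothly; this is a pure speed device (same likelihood, same
tolerance) and the profile is unchanged relative to cold starts.

### F2 identifiability and the reporting convention

Under the F2 design the sign of the heterozygote split (`i`, `ici`) is
essentially unidentified; the full model still fits them freely because
the imprinting and interaction LR tests need that alternative.  Reported
*estimates* for F2 data, however, follow the estimable reporting model
with i = ici = 0: leaving the split free lets the fit absorb noise into
the two heterozygote means, visibly deflating sigma^2-hat.  The Monte
Carlo estimation study therefore refits at the scan peak under the
reporting constraint; `FitResult.sign_unidentified` marks the affected
effects in test output.  Backcross data identify all eight effects.

## Scan, thresholds, tests

* The no-QTL null `y = mu + c*m` is fitted once in closed form.  Keeping
  `c` in the null means a pure maternal effect cannot masquerade as a QTL
  peak; the scan LR therefore tests the six QTL effects (df 6).
* Grid: each chromosome from first to last marker inclusive, default 2 cM;
  at a marker the interval degenerates and that marker drives the
  posterior.  Peak ties break to the left-most position.
* Permutation thresholds shuffle phenotypes within cross-direction strata
  by default (preserving the cytoplasm structure under the null), rescan,
  and take the empirical (1−α) quantile of the genome-wide maximum LR
  (`method="higher"`); unstratified shuffling is a flag.
* Battery at a position: LR tests of c=0 (df 1), i=0 (df 1; optionally
  {i, ici}, df 2, via `imprinting_joint`), ica=icd=ici=0 (df 3), a=d=0
  (df 2) against the full model; chi-square p-values by default,
  position-fixed permutation p-values `(1+#{LR* ≥ LR})/(1+B)` on request.

## Simulator

Gametes are Markov chains over the ordered loci (markers plus QTL): first
allele uniform, each interval switches phase with probability
`haldane_r(d_sex)`.  One maternal (female distances) and one paternal
(male distances) gamete per individual give ordered genotypes; marker
codes are unordered; phenotypes add N(0, sigma^2) noise to the class mean.
Populations are bitwise-reproducible from the scenario seed.

Preset conditions mirror the published study design: one 100 cM linkage
group, 6 equidistant markers, QTL at 48 cM, λ = 1.25, half the family per
reciprocal direction.

* **Estimation preset** (`table2_scenario`): effects (mu, c, a, d, ica,
  icd) = (10, 1, 1, 0.8, 0.6, 0.5), i = ici = 0, residual variance taken
  directly as printed per heritability level (3.81 / 2.04 / 1.26 for H² =
  0.1 / 0.25 / 0.4).  The printed variances are used verbatim because no
  variance bookkeeping we could construct reproduces them from the effect
  sizes (the equal-frequency eight-class genetic variance would give
  sigma^2 ≈ 3.70 at H² = 0.4); printed inputs trump ambiguous formulas.
* **Power preset** (`table3_scenario`): all listed effects 0.8 except the
  varied one — cytoplasmic c ∈ {0, 0.461, 0.679} or imprinting i ∈
  {0, 0.680, 1.020} by variance proportion (0 / 5% / 10%) — with sigma^2
  calibrated from H² via the package's own bookkeeping: sigma^2_g is the
  variance of the eight class means under equal class probabilities
  (balanced directions × Mendelian 1/4), sigma^2 = sigma^2_g (1−H²)/H².

What the simulator does *not* emulate: genotyping error, missing marker
data patterns, segregation distortion, multiple or linked QTL, polygenic
background, non-Gaussian residuals.  Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
real-data pathologies.

## Monte Carlo experiments (`cytoqtl.mc` and `scripts/acceptance.py`)

The estimation experiment runs 200 replicates at n = 800, H² = 0.4
(sigma^2 = 1.26): simulate, scan at 2 cM, take the profile argmax, refit
there under the F2 reporting model, and average the estimates; the RMSE of
mu-hat is reported as dispersion.  The size/power experiment runs 200
replicates per family at the same n and H²: scan, then the chi-square
battery at the per-replicate peak; rejection rates at the nominal 5% level
estimate test size (varied effect at 0) or power.  200 replicates keep the
full suite in the minutes range on one CPU; replicate seeds spawn from one
master seed.  Note RMSE of a mean-like estimator is a heavy-tailed
statistic at 200 replicates (its Monte Carlo error is roughly 10–15%
relative), which bounds how sharply the dispersion numbers can be pinned.

## Phenotype transformation

`boxcox_transform` applies the Box-Cox power family ((y^λ − 1)/λ, log at
λ = 0) before model fitting when phenotypes are skewed; λ is chosen by
profile likelihood on a fixed grid over [−2, 2] (step 0.05) unless given.
Nonpositive phenotypes require an explicit, logged shift.

## Numerical and design choices

* Positions are cM coordinates on each linkage group; simulated maps start
  at 0, and reported QTL locations are distances from the first marker.
* sigma^2 is floored at 1e-300 to keep degenerate perfect-fit cases finite.
* Genotype codes: AA = P1/P1 homozygote, AB, BB, NA (token configurable);
  unknown tokens become missing with a logged count.
* LR values are clipped at 0 (convergence tolerance can leave a −1e-9).
* The empirical threshold quantile uses the "higher" order statistic, so
  α = 1 returns the minimum of the null maxima and thresholds are
  monotone in α.

## Known limitations

* Single-QTL model only; clustered peaks on one chromosome cannot be
  deconvolved (composite interval mapping is out of scope).
* F2 imprinting effects are testable but not estimable (sign-unidentified);
  use backcross designs for imprinting effect sizes.
* The constant-λ sex map is genome-wide; per-interval sex ratios exist in
  real data and are supported only by supplying sex-specific maps through
  λ at construction.
* Chi-square reference p-values for the battery are asymptotic; at small n
  or near-boundary alternatives use the permutation mode.
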