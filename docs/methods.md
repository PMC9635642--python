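# Methods

## Model family

All models are intercept-plus-random-effects Gaussian mixed models of
pre-corrected phenotypes on `n` individuals,

    y* = 1 mu + sum_c u_c + e,   u_c ~ N(0, K_c sigma_c^2),   e ~ N(0, I sigma_e^2),

where each relationship kernel `K_c` is the cross-product of a standardized
feature matrix: the genomic kernel `G = ZZ'/m` (VanRaden's second method),
the transcriptomic kernel `T = WW'/k`, their Hadamard product `G#T` for
genome-by-transcriptome interaction effects (positive semidefinite by the
Schur product theorem), and the conditioned kernel `Tc = Wc Wc'/k`.
Phenotypes are assumed pre-corrected for systematic effects, so only an
intercept is fitted; the model set {g}, {t}, {g,t}, {g,t,gt}, {g,tc} is
named GBLUP, TBLUP, GTBLUP, GTIBLUP, GTCBLUP.

## Preprocessing

Genotype QC removes, in order: markers with minor-allele frequency below
0.05, markers with call rate below 0.90, and — scanning left to right —
any marker whose absolute Pearson correlation with the most recently
retained marker exceeds 0.80 (the earlier marker of a violating pair is
kept; correlations use pairwise-complete observations). Remaining missing
dosages are mean-imputed per marker before standardization, which places
imputed entries at zero after centering. Standardization uses the sample
standard deviation (n−1 denominator); zero-variance features are dropped
and reported.

Transcripts are rank-Z transformed per gene: a value with (average, for
ties) rank `r` among `n` samples maps to the normal quantile
`Phi^-1(r/(n+1))`. The transform is idempotent and gives every gene the
same marginal quantiles; a gene with all-tied values is an error. The
rank-to-quantile offset (the `r/(n+1)` rule rather than a Blom-type
correction) is a convention choice; any monotone variant gives identical
ranks and near-identical quantiles.

## Conditioning transcripts on genotypes (GTCBLUP)

`Wc = (I − Z (Z'Z + lambda I_m)^{-1} Z') W` with
`lambda = m * sigma_e^2 / sigma_g^2`, both variances being the posterior
means of a GBLUP fit of the same trait (the posterior mean is used for
consistency with every other posterior summary reported). Because the
marker count `m` typically far exceeds `n`, the smoother is evaluated in
the algebraically identical n-dimensional form
`Wc = (I − ZZ'(ZZ' + lambda I_n)^{-1}) W`; both forms are implemented and
agree to machine precision (the m-form remains available for
cross-checking). At `lambda = 0` the smoother becomes the orthogonal
projection onto the genotype column space (evaluated by a least-squares
solve, since `ZZ'` is singular for centered `Z`); as `lambda -> inf` it
vanishes and `Tc -> T`. The total sum of squares of `Wc` is nondecreasing
in `lambda`.

`Wc` is deliberately **not** re-standardized: the conditioned kernel
divides by the gene count only, so variance removed by conditioning stays
removed and the diagonal of `Tc` shrinks below one. If the GBLUP genomic
variance is essentially zero (below 1e-6 of the phenotypic variance),
lambda diverges and conditioning is refused with an explicit error — a
trait without genomic variance has nothing to condition on.

## Priors and Gibbs sampler

Every variance component has a scaled-inverse-chi-squared prior with
df = 5. Scales derive from the phenotypic variance `sigma_p^2` and a prior
proportion of explained variance `R2` (default 0.5), split equally across
the kernels in the model:

    S_e = sigma_p^2 (1 − R2)(df + 2)
    S_c = sigma_p^2 (R2 / n_components)(df + 2) / meandiag(K_c)

The `(df + 2)` factor places the prior mode of each variance at its target
share; the division by `meandiag(K_c)` expresses the scale in kernel units.
The same `(df + 2)` convention is used for the residual and the component
scales. (Renderings of this prior family sometimes show `df − 2` for the
residual scale — that factor corresponds to the prior mean rather than the
mode; the mode convention is the one used by the BGLR family of samplers
and is adopted here for both.)

Sampling is performed in the eigenbasis of each kernel: with
`K_c = V_c D_c V_c'` (eigenvalues below 1e-8 of the largest truncated),
`u_c = V_c a_c` has independent Gaussian coordinates, so each sweep reduces
to scalar conjugate updates of `a_c`, inverse-chi-squared updates of the
variances, a Gaussian update of the flat-prior intercept, and — for
individuals with missing phenotypes — a data-augmentation draw of their
residual. Augmented validation individuals thereby receive posterior draws
of every component effect; their posterior means are the forward
predictions, and the `g` means are the GEBV. The chain is fully
deterministic given its seed.

Chain defaults mirror a production analysis: 60,000 sweeps, 20,000
burn-in, thinning 10, hence exactly 4,000 retained draws. For the
desk-scale kernels of the synthetic studies a 6,000/2,000/5 chain
(`ChainSettings.reduced`) is ample: effective sample sizes of the variance
chains are in the hundreds, and the package logs them (they never gate
results). The closed-form solver `blup_solve` (GLS intercept plus
mixed-model equations at fixed variances) provides the independent oracle
used by the tests; with variances fixed, the sampler's posterior-mean
effects agree with it to correlation > 0.999.

## Variance partition

Proportions of phenotypic variance are computed per retained draw and then
summarized (posterior mean and SD). Each component enters on the phenotypic
scale, `sigma_c^2 * meandiag(K_c)`, because the variance a component
contributes to individual i is `K_ii sigma_c^2`. For kernels built from
standardized features the mean diagonal is 1 by construction and this is
the plain ratio of variance components; it differs only for `Tc`, whose
diagonal the smoother deliberately shrinks. Reporting `sigma_tc^2` at its
kernel scale would inflate the transcript share (and deflate every other
share) by exactly the variance that conditioning removed, which would
contradict the construction's purpose of leaving the genomic share intact.

## Evaluation

Forward validation uses the youngest generation as the validation set and
everything older as reference. Accuracy is the Pearson correlation between
`y*` and predictions in the validation set; its SE is the SD over paired
bootstrap resamples (degenerate resamples with undefined correlations are
redrawn and counted); RRMSE divides the root-mean-squared error by the
validation-set phenotypic SD (n−1 denominator); the bias slope is the OLS
coefficient of `y*` on predictions (above 1 deflated, below 1 inflated);
model R2 is the squared correlation within the reference set. Accuracies
of two models sharing the phenotype are compared with Williams' t for
dependent correlations (`|R| = 1 − r12² − r13² − r23² + 2 r12 r13 r23`,
`df = n − 3`), two-sided; no multiple-testing correction is applied across
per-trait model comparisons, mirroring common practice in this literature —
users comparing many models should correct externally.

## Synthetic-data generator

The generator emulates the statistical structure of a moderately sized
outbred mouse population with liver transcriptomes:

* **Genotypes.** Founder haplotypes follow a first-order allele-copying
  rule (`ld_autocorr = 0.9` by default, appropriate for a dense, evenly
  spaced marker grid), and the observed generations are bred from a finite
  founder pool (24 founders) by random mating with recombination
  (crossover probability 0.01 per marker interval), giving four
  non-overlapping generations of sizes 47/47/192/192 (n = 478). The finite
  parent pool creates the sib/cousin family structure such populations are
  maintained at; this relatedness is what concentrates genetic signal on
  the leading eigenvectors of `G`, and without it neither the redundancy
  nor the conditioning phenomenon emerges.
* **Transcripts.** Each of `k = 2000` genes (a desk-scale stand-in chosen
  to preserve the genes >> individuals regime of real transcriptome
  panels; the full 11,770-gene scale runs fine and gives the same
  patterns) is a cis-block signal — five adjacent markers with random
  effects — scaled to a genetic variance share `prop_cis`, plus Gaussian
  noise, then rank-Z transformed. Real co-expression structure
  (shared latent factors, tissue composition) is not emulated.
* **Phenotype.** `y = g_direct + coupling * t_effect + gt_effect + e`, with
  `g_direct` loading on all markers (share `h2_direct`), `t_effect`
  loading on all transcripts (share `t2_mediated`), an optional
  interaction formed from the elementwise product of standardized latent
  genomic and transcriptomic scores (share `gt2`), and residual variance
  `1 − h2_direct − coupling² t2_mediated − gt2`. Components are rescaled
  to hit their target shares exactly; cross-terms are sampling noise.
  `coupling` in [0, 1] attenuates the transcript pathway and emulates a
  growing time gap between phenotyping and transcript sampling: the
  variance transcripts can explain falls with the square of the coupling.

Defaults (`prop_cis = 0.7`, `h2_direct = 0.15`, `t2_mediated = 0.45`,
`coupling = 1`, `gt2 = 0`) define the canonical redundancy study: most of
the genetic signal reaches the phenotype through transcripts. On such
studies GTBLUP's genomic share drops far below GBLUP's heritability while
GTCBLUP's matches it, and the validation-set correlation between the `g`
and `tc` predictions collapses from strongly positive (unconditioned
`rho(g,t)` around 0.8–0.9 — note this synthetic entanglement is several
times stronger than in typical real traits) to near zero, typically
slightly negative (about −0.3 to −0.1 across seeds).

What passing tests on these studies do **not** show: performance under
real LD decay and founder-haplotype mosaics, co-expression structure,
non-Gaussian phenotypes, or pre-correction of raw phenotypes for fixed
effects (phenotypes are generated pre-corrected).

## Numerical choices and limitations

* Kernel eigenvalues below 1e-8 of the largest are truncated; kernels with
  eigenvalues below −1e-8 of the largest are rejected as non-PSD.
* All cross-product kernels are symmetrized (`(K + K')/2`) against
  round-off; matrices round-trip through TSV at 12 significant digits.
* The sequential-correlation pruning keeps the earlier marker of a
  violating pair; applying the three QC rules in a different order changes
  the retained set, and the implemented order is MAF, call rate,
  correlation.
* Single-chain inference; convergence diagnostics (effective sample size)
  are reported, not enforced. For multi-kernel models with heavily
  overlapping kernels the component variances are weakly identified and
  mix slowly — their sums and the component predictions are stable much
  earlier than the individual shares.
* `blup_solve` inverts an n×n system directly and is intended for oracle
  use and modest n, not for biobank-scale data.
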