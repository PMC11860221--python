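# Methods

`statusgen` implements the family-based decomposition toolkit for polygenic
scores (PGS) of occupational status: a forward pedigree simulator that serves
as ground truth, the population / within-sibship / adoption /
parental-control design fits with bootstrap attenuation ratios, an
equilibrium model of the attenuation expected from assortative mating alone,
multi-mediator path models, heritability-rescaled genetic confounding of
intergenerational transmission and of status–health associations, and
occupational status coding (ISEI / SIOPS / CAMSIS).

## Generative model

Each person carries a latent additive score `A` (the infinitesimal model:
scores, not SNPs — every estimator in the package consumes scores, so
SNP-level simulation would add nothing testable). Transmission is

    A_child = (A_f + A_m)/2 + e_seg,   e_seg ~ N(0, sigma2_A0/2),

with the segregation variance fixed at half the *founder* additive variance,
the standard infinitesimal convention; it gives the equilibrium-variance
recursion `V(t+1) = V(t)(1 + r_A(t))/2 + sigma2_A0/2` a closed fixed point
used for validation. The phenotype (occupational status on a latent
continuous scale) is

    Y = beta_d * A + beta_n * (A_rf + A_rm) + gamma * (Y_rf + Y_rm)/2 + eps,

where `rf/rm` are the *rearing* parents: `beta_n` is genetic nurture
(passive gene–environment correlation), and `gamma`
(`beta_parent_phenotype`, off by default) is phenotype-mediated social
transmission, used by the intergenerational-transmission scenario so that a
known part of the parent–offspring correlation is genuinely non-genetic.
Founders receive pseudo-parental draws so their phenotype variance is
comparable; the transient washes out over the simulated generations.

Spouse pairing is primary phenotypic assortment by Gaussian-copula rank
matching: male phenotype ranks are matched against a noised copy of the
female phenotypes with the noise solved from the target spousal correlation
`r_mate`. Twelve generations reach the equilibrium additive variance to
well under 1% for any `r_mate < 0.9`; non-convergence is recorded as a
warning (threshold widened to three sampling SEs for small samples), never
an error. Sexes alternate within sibships so every generation can mate; sex
has no phenotypic effect in the generator and enters only as a covariate
downstream. A fraction of final-generation children are adoptees reassigned
to random unrelated rearing couples, whose scores (and phenotypes, when
`gamma > 0`) replace the biological parents' in the nurture terms.

The observed PGS is `S = A + nu` with a single noise variance for everyone,
solved in closed form from the realized final-generation moments so that the
incremental R² of `S` for `Y` hits a chosen target (a target above
`corr(A,Y)²` raises an error). All stochastic stages draw from named streams
derived from one seed, so attaching mediators never perturbs the pedigree
draws; everything is bit-for-bit reproducible from `(config, seed)`.

### Default calibration

The `SimulationConfig` defaults (equivalently `paper_scenario()`) are the
package's combined study conditions: `beta_d = 0.76`, `beta_n = 0.24`
(nurture share 0.24 of the raw slope), `var_env = 4.5`, `r_mate = 0.6`,
`pgs_target_r2 = 0.097`, 5% adoptees, two siblings per family, 12
generations. They were calibrated once so that the headline family-design
quantities fall where large UK cohort studies place them: within-sibship
attenuation of the noisy PGS ≈ 54–58%, adoption-design attenuation ≈ 23–28%,
spousal phenotype correlation 0.6, PGS incremental R² 0.097 against a
latent-score R² near 0.2. Two known consequences of this parameterisation
are documented rather than hidden: the parental-control design under-absorbs
(≈10–17% attenuation) because the midparent *phenotype* is a noisy proxy of
the parental genotype when `var_env` is large, and for the same reason the
status–health attenuations land near 13–17% rather than ~20%. Because
synthetic health is `lambda*Y + noise`, the health attenuation is
mathematically identical for any `lambda` (it cancels in the ratio), so
"general" and "mental" health differ only by sampling noise.

Recovery and calibration scenarios (`null_scenario`, `nurture_scenario`, the
coverage experiment) deliberately use amplified signal (heritabilities around
1/2–2/3) and, where the check does not pin a sample size, enlarged samples.
These are estimator-validation experiments designed for statistical power —
they test that the estimators recover known truths, not that real data look
like this.

## Design estimators

All fits standardize outcome and PGS to mean 0, SD 1 **once on the analysis
sample** (not per family), then:

- **population**: OLS of the residualized outcome on the residualized PGS
  (covariates projected out first — Frisch–Waugh); incremental R² is the gain
  of the full model over the covariate-only baseline.
- **within-sibship**: family-demeaned OLS on families with ≥2 complete
  siblings (singletons dropped and logged), standard errors clustered by
  family (the SE estimator is a package choice). Demeaning is unit-tested
  against family-indicator OLS to 1e-8.
- **adoption**: the population fit restricted to adoptees; fewer than 30
  adoptees warns, zero is an error.
- **parental control**: PGS plus parental occupational status (plus
  covariates); near-collinearity (|r| > 0.999) is an error.

The attenuation ratio `beta_reduced / beta_PGS` gets a 95% *percentile*
bootstrap CI (ratio distributions are skewed) from resampling **families**
with replacement — sibling pairs stay intact, and a family drawn twice
counts as two clusters. Replicate refits run on plain numpy arrays;
categorical covariates are not supported inside the bootstrap. A population
coefficient within 2 SE of zero attaches an instability warning. Empirical
coverage of the 95% CI is 93–96% over 200 replicate simulations at the
package's test settings.

Two practical points about the adoption design, visible in the simulator and
relevant to real studies: (i) its natural population reference is the
non-adopted population — in real cohorts adoptees are ~1% so this is moot,
but in a simulation with many adoptees a full-sample reference is diluted
toward the direct effect; (ii) adoptees' phenotypic variance is lower
(they lack the positive covariance between own score and nurture), which
inflates their standardized slope by ≈ sqrt(Var_pop/Var_ado); the effect is
second-order when the PGS explains little variance.

## Expected attenuation from assortative mating alone

The additive score splits into the part `S` captured by the PGS (variance
share `h2_pgs_share`) and the uncaptured residual `U`. Phenotypic matching
induces, at equilibrium, a positive `Cov(S, U)`: the population slope of
`Y` on `S` picks it up, the within-sibship slope does not (sibling
differences in `S` are pure segregation noise, independent of `U`'s), so

    ratio = V_S / (V_S + Cov(S, U)).

The equilibrium moments come from iterating the exact Gaussian-copula
covariance recursions (e.g. `Cov(S_f, U_m) = r * Cov(S,Y) Cov(U,Y) / V_Y`)
to a fixed point; `r_mate = 0` returns exactly 1, as does full capture
(`h2_pgs_share = 1`). An independent forward-simulation oracle (explicit
`S`/`U` transmission through 16–18 generations of copula matching, then the
actual design estimators on a final sibling generation) agrees with the
recursion to within 0.01 across the parameter grid; the oracle is treated as
authoritative.

Magnitudes: with matching on the measured phenotype at SNP-heritability
scale (h² ≈ 0.15) the expected attenuation is only a few percent. An
attenuation in the low-to-mid twenties of percent — the range quoted for
occupational status — requires strong matching (r ≈ 0.5–0.7) on a highly
heritable latent status factor (h² ≈ 0.6, the twin-study scale); the package
exposes `h2_total` so either regime can be computed.

A related exactness result: under *primary phenotypic* assortment the
spousal PGS correlation equals the benchmark
`r_pheno * corr(PGS, Y)_f * corr(PGS, Y)_m` at every mating round, including
at equilibrium — the accumulated genetic spousal correlation is exactly what
phenotypic matching transmits. An observed spousal PGS correlation *above*
that benchmark (as reported in real data) therefore indicates assortment on
something more heritable than the measured phenotype; such social-homogamy
matching is outside the generator's scope, and the package's
`spousal_pgs_correlation` reports both quantities with bootstrap CIs so the
comparison itself is data-driven.

## Mediation

Per-equation least squares on the complete-case sample, all variables
standardized: `M_k = a_k*PGS + controls`, `Y = c'*PGS + sum b_k M_k +
controls`, total effect from the reduced regression. The omitted-variable
algebra makes `total = c' + sum a_k b_k` an exact identity (checked to
1e-10 on every fit). For a saturated linear path model these point
estimates coincide with a covariance-structure (SEM) fit, which is why no
SEM engine is needed. Inference is a family-clustered bootstrap: percentile
CIs and two-sided p-values (add-half counting; approximately uniform under
the null by a KS check), with the conventional star coding (* 0.01–0.05,
** 0.001–0.01, *** <0.001). Proportions mediated use the signed total
effect as denominator; suppression (sign-conflicting indirect effects) is
reported as-is with a note, and a total effect within 2 SE of zero flags
the proportions unstable. Life-course analysis fits one model per career
wave on that wave's complete cases, skipping waves below a configurable
floor.

## Transmission and health confounding

The parent–offspring status correlation is mediated through the offspring
PGS: `a` = slope of PGS on parental status, `b` = partial slope of offspring
status on PGS given parental status, share = `a*b / r`. Because the
observed PGS is the latent common-variant score attenuated by independent
noise with reliability `R2_PGS / h2_SNP`, both paths shrink by the square
root of that reliability and the share by the reliability itself; the
rescaled share is therefore `share * h2_SNP / R2_PGS`, capped at 100% with
a flag, with the non-genetic complement reported alongside. The correction
is validated against the generator: degrading a noise-free score to
reliabilities of 0.3–1.0 and rescaling recovers the latent-score share
within ±4 points at 10,000 trios. The residual deficit (≈1–2 points) is the
partial-coefficient factor `(1 − r_pA²)/(1 − rel·r_pA²)` that the linear
rescaling does not correct; it is second-order for realistic correlations.
Paternal status is the default parental measure; the estimator takes a
column name, so a midparent or maternal measure plugs in unchanged.

Status–health confounding re-fits the standardized health ~ PGS regression
per wave and outcome with and without parental status; the attenuation is
`100·(1 − beta_with/beta_without)`, cells with a baseline coefficient
within 2 SE of zero are flagged and excluded from the across-wave averages.
Health ratings are treated as metric after standardization; no ordinal link
functions.

Career trajectories convert panel status to percentile ranks **within each
time point** — `(rank − 1/2)/n · 100`, whose mean is exactly 50 for a
complete wave without ties, so cohort-wide drift cannot distort the
profiles — then average by PGS quantile (default quintiles), parental
education band (Low / Medium / High tertiles of midparent status) and sex.

## Occupational status coding

Crosswalk tables map occupation codes to ISEI / SIOPS / CAMSIS scores from
delimited text with optional `#`-metadata (provenance, declared score
ranges, validated on load); duplicate codes and empty tables are format
errors, an absent scale column degrades to "unavailable". Real crosswalks
are licensable artifacts; the package ships only a clearly synthetic
12-code toy table and the file schema they plug into. Per-person scoring
uses the most recent record, ties broken by the last-listed record (a
package convention, counted in the scoring log); unmapped codes yield
missing scores and increment a counter. Phenotype preprocessing uses the
rank-based inverse-normal transform with the Blom offset 3/8 (the offset is
a package choice), average ranks for ties, missing values preserved; the
transform is idempotent and invariant under monotone re-expressions.

## Numerical and degenerate-input conventions

Zero-variance outcome or score, no multi-sibling family, zero adoptees,
collinear parental control, all-missing transforms and fewer than 30
couples raise typed errors; small-sample but estimable cases warn instead.
Bootstrap replicates that degenerate (e.g. a resample without sibling
pairs) are dropped from the percentile computation. The pipeline writes a
JSON summary carrying package version, config hash (output directory
excluded), seed and all warnings; re-running an identical configuration is
byte-identical, and per-stage RNG streams keep stage toggling from
perturbing other stages' draws.

## Limitations

The generator omits SNP-level structure and linkage disequilibrium, the X
chromosome, sex effects, participation/selection bias and social-homogamy
mating; mediators are single indicators (no measurement models); health has
no causal pathway of its own (so health confounding mirrors status
confounding by construction). Passing tests show that the estimators
recover the generative quantities under these idealized conditions — they
do not certify behavior under real-data pathologies (informative
missingness, cohort effects, ancestry structure) that the generator does
not emulate.
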