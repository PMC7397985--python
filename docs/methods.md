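# Methods

## The scientific problem

Extra-pair offspring (EPO) counts measure the extra-pair mating behaviour of
socially monogamous birds.  Whether selection can shape that behaviour
depends on its narrow-sense heritability h² = σ²_A / σ²_P: the
per-generation response to selection is Δz̄ = h²·Cov(ω, z) = σ²_A·b.  This
package estimates σ²_A and h² for an EPO count measured in a single breeding
season of a wild pied-flycatcher-like nest-box population, using the
pedigree accumulated by years of individual monitoring, and then asks how
strong selection would have to be to move the trait mean.

The field data themselves are replaced by a synthetic-data generator with
the same statistical structure, so every stage of the analysis is testable
end to end.

## Pedigree machinery

A pedigree is a validated parentage table (unique ids, acyclic, no id used
as both dam and sire, unlisted parents auto-promoted to founders —
immigrants enter this way).  For variance-component estimation the pedigree
is pruned to the *informative* subset: phenotyped individuals plus all their
ancestors.  Descendants and collateral relatives of phenotyped individuals
carry no additional information for the animal model and are dropped;
pruning is idempotent.

The numerator relationship matrix A is built by the tabular method in
parent-before-offspring order (Kahn's algorithm, ties in input order):
A_ij = ½(A_{j,dam(i)} + A_{j,sire(i)}), A_ii = 1 + ½A_{dam(i),sire(i)},
missing parents contributing zero.  A is symmetric positive semi-definite
with diagonal 1 + F.  The independent oracle for A is gene dropping: two
uniquely labelled alleles per founder transmitted down the pedigree, with
realized IBD sharing averaged over drops.  Inbreeding coefficients alone are
computed by a memoized coancestry recursion so that large shallow pedigrees
never require the dense matrix.

Kinship summaries follow the usual counting rules: a maternal (paternal) sib
pair shares a known dam (sire), full sibs share both, so maternal sibs =
full sibs + maternal half sibs by construction; mean sibship is offspring
per parent among parents with ≥ 1 offspring; the relatedness histogram
tallies off-diagonal A values at a configurable resolution (default 0.025 —
the discrete levels ¼, ⅛, … of outbred wild pedigrees are exact multiples,
and the resolution is configurable because inbred loops can produce
intermediate values).

## The animal model

The trait model is the standard latent Gaussian GLMM of quantitative
genetics:

    η = Xβ + Z_a a + Z_s s + e
    a ~ N(0, σ²_A A),  s_j ~ N(0, σ²_site,sex(j)),  e ~ N(0, σ²_R I)
    y_i ~ Poisson(exp(η_i))        (or η observed directly: gaussian-identity)

The per-record residual makes the counts lognormal-Poisson ("additive
overdispersion"), so a residual variance is always present under the
Poisson family.  Fixed effects use treatment contrasts with yearling/female
reference; when an age×sex interaction is requested without a main effect
the interaction absorbs the missing factor's levels (the usual full-rank
completion).  The breeding-site-quality random effect has a
sex-heterogeneous (idh-style) structure: by default each observed integer
recruit-count level, per sex, is one effect, female and male effects having
separate variances and no cross-sex covariance.  Because the covariate is
numeric, a random-regression reading (sex-specific slope on the recruit
count) is available behind the `site_reading` switch; the factor reading is
the default.

### Priors

Variance components get scaled-inverse-χ²(ν, V) priors (the univariate
inverse-Wishart).  The genetic and site components are parameter-expanded by
default: the effect block is multiplied by a working scalar with a
N(α_μ, α_V) prior, so the effective variance is α²σ²_w and the implied prior
on the standard deviation is heavy-tailed (V = 1, ν = 1, α_μ = 0,
α_V = 1000 by default).  This both mirrors common practice for
variance components near zero and dramatically improves mixing there.  The
residual prior is either free (V = 1, ν = 1; `PriorSpec.study_R1()`) or held
fixed at V = 1 (`PriorSpec.study_R2()`), the usual device for
poorly-informed residual variances in count models; with `fix` set, every
stored σ²_R draw equals V exactly.  Fixed effects have diffuse
N(0, 10⁸) priors.

### Sampling

Gibbs updates throughout, with one Metropolis ingredient:

- **Location effects** (β, a, s) have exact conjugate Gaussian conditionals.
  The animal block is sampled in the basis of the SVD C = USVᵀ of
  C = Z_a L (L = chol(A)): writing a = αLQu with u ~ N(0, σ²_w I) makes the
  conditional precision diagonal, so the update is an exact joint draw at
  O(n²) cost per sweep instead of a dense Cholesky per iteration.  The m − n
  null-space coordinates of u never touch the data; their sum of squares
  (needed by the σ²_w update) is drawn analytically as σ²_w·χ²(m − n).  Site
  effects have diagonal conditionals because each record loads on exactly
  one level.
- **Variances** are scaled-inverse-χ² conditionals; the expansion scalars α
  are conjugate scalar regressions.
- **Latent liabilities** (Poisson family only) get per-record random-walk
  Metropolis updates against y_i·η − exp(η) plus the Gaussian prior around
  the fitted location.  Proposal scales are adapted per record during
  burn-in toward 44% acceptance (Robbins–Monro, frozen afterwards).
  Liabilities are clipped at |η| ≤ 30 with a logged count as an overflow
  guard.

A single seeded generator drives the whole chain: identical seed and
configuration give bit-identical draws.  The Gaussian-family sampler was
validated against a direct REML maximizer; the Poisson machinery is
calibrated by the null-trait control (below).

Scheduling: the package default is 10⁵ iterations, thin 50, burn-in 10⁴
(1,800 kept draws).  The full study-scale schedule (1.005×10⁷ / 10⁴ /
5×10⁴ → 1,000 draws) is `MCMCConfig.study_scale()`.  Tests and the
calibration runs use 1.5–6×10⁴ iterations on problems of ~500–600 phenotyped
individuals, sizes chosen so a complete calibration (tens of chains) runs on
a single core in minutes.

### DIC and diagnostics

DIC is the conditional form: D̄ + p_D with p_D = D̄ − D(θ̄), the deviance
evaluated at the posterior mean liabilities (Poisson) or posterior mean
location and residual variance (Gaussian).  Effective sample sizes use
Geyer's initial-positive-sequence estimator on the thinned draws; parameters
with |lag-1 autocorrelation| ≥ 0.12 are flagged, as are degenerate chains
(except a residual variance fixed by its prior, which is constant by
contract).  The posterior predictive zero check simulates full replicate
data sets (new animal, site and residual effects) from sampled posterior
draws and compares predicted with observed zero counts.

## Scale conversion

A log-link GLMM estimates variances on the latent scale.  With
η ~ N(μ, σ²), σ² = σ²_A + σ²_rest, the data-scale quantities have closed
forms: mean m = exp(μ + σ²/2), var = m + m²(exp(σ²) − 1),
σ²_A,obs = m²σ²_A (the Ψ = E[d exp(η)/dη] linearization), h²_obs =
σ²_A,obs/var.  With fixed effects, the closed forms are averaged over the
empirical distribution of fitted linear predictors, one term per record,
which also folds the fixed-effect variance into var_obs.  The overdispersion
variance is always part of σ²: it belongs to the latent distribution of the
additive-overdispersion model.  A 64-node Gauss–Hermite quadrature path is
kept for validating the closed forms; the Monte-Carlo oracle estimates
σ²_A,obs independently as cov(y, a)²/σ²_A.

h²_obs is always below h²_latent when non-additive latent variance is
present, and is increasing in σ²_A throughout the study-relevant range
(σ² ≲ 2); for very large latent variance the exp(σ²) term in var_obs
dominates and the curve provably turns over, which is why the monotonicity
property is only asserted on the bounded range.

## Posterior summaries

Heritability posteriors from weakly informed animal models pile against
zero and are strongly right-skewed, so the point estimate is a Gaussian-KDE
mode with Silverman bandwidth shrunk by a factor 0.1 (to resolve the sharp
near-zero peak; the factor is an argument), evaluated on a 512-point grid
with ties broken toward the smaller value.  The 95% credible region is the
highest-posterior-density region — by default the shortest interval
containing ⌈0.95n⌉ sorted draws, with an opt-in KDE level-set variant that
can return disjoint intervals for multimodal posteriors.  Observed-trait and
null-trait h² posteriors are compared with the Wilcoxon rank-sum test
(normal approximation, tie-corrected).

## The null-trait control

MCMC variance components cannot be exactly zero, so the floor of the
h² estimate is calibrated empirically: iid Poisson counts with the observed
mean — heritability zero by construction — are fitted with the identical
model battery.  On the synthetic study-like data the null latent-h² modes
come out ≈ 0.003, an order of magnitude below the 0.10 screening threshold,
and the Wilcoxon comparison separates observed from null posteriors whenever
genuine additive variance is present.

## The synthetic-data generator

`simulate_population_pedigree` emulates a serially monogamous nest-box
population: each year 220–320 pairs (the study population's range) form
from surviving breeders (annual adult return rate 0.35, typical of small
migratory passerines), locally recruited yearlings, and immigrant founders
filling the shortfall; clutches are Poisson(6.5) truncated at 1; each chick
independently recruits with probability 0.111 (the study's recruitment
rate).  Phenotyped individuals are the final season's breeders (~480–620),
with age class from first breeding year and a small-integer recruit-count
quality mark per nest box.  `simulate_breeding_values` gene-drops latent
breeding values (founders N(0, σ²_A); offspring midparent average plus
Mendelian deviation with variance σ²_A(½ − ¼(F_dam + F_sire)); a missing
parent is replaced by a fresh founder draw for its half so every marginal
variance stays σ²_A).  `simulate_trait` overlays fixed, site, and residual
effects on the latent scale and observes Poisson(exp(η)); the default
intercept and residual variance (μ = −1.83, σ² = 1.56) are calibrated so the
counts reproduce the emulated study's observed moments (mean 0.35,
variance 0.81).

What the generator reproduces well: the zero-inflated overdispersed count
distribution; many small families (mean sibship ~1.4–1.7); a founder-heavy
pedigree with shallow genetic depth.  What it does not: the exact sparsity
of the field pedigree (the simulated population keeps ~50% of breeders
locally born versus ~28% in the emulated study, and accumulates somewhat
deeper ancestries), natal dispersal out of the study area, non-random mate
choice, and any environment–pedigree correlation.  Passing calibration tests
therefore demonstrates correctness of the estimation machinery under
realistic structure, not field-data power.

A caveat the synthetic experiments make explicit: with ~600
single-observation Poisson records at mean 0.35, the *latent-scale* h²
posterior is intrinsically diffuse — it can span most of [0, 1] even when
the truth is known.  Parameter-recovery calibration is therefore run on the
design where the check is informative (balanced full-sib families, Gaussian
trait, ~600 phenotyped: modes concentrate within ±0.15 of the truth and HPD
coverage is nominal), while the Poisson machinery is calibrated through the
null-trait control and the posterior predictive check.

## Selection arithmetic

Pure algebra, exposed as small functions: the breeder's equation R = h²s;
the equivalent forms Δz̄ = h²Cov(ω, z) = σ²_A·b; the female decomposition
Δ_I = h²σ_NEPO·s_EW (indirect) and Δ_D = ½h²σ_NEPO·β_fEPC (direct); the
required selection intensity i = Δz̄/(h²√σ²_z) and gradient β = Δz̄/σ²_A.
Full precision is returned everywhere; rounding (1–2 dp) happens only at the
presentation layer.  The relative-change percentage sometimes quoted
alongside Δz̄ = 0.1 is not reproduced: its arithmetic basis is unclear
(0.1 of a mean of 0.35 is 28.6%, not a few percent), so the package reports
only the absolute shift.

## Pipeline and reproducibility

`pipeline_run` chains the stages (data or generator → prune → A → battery of
fits → latent/data-scale h² → mode + HPD → null comparison → selection
arithmetic), writing chains as CSV, summaries as CSV/JSON, and a manifest
with configuration hash, per-stage seeds split from one master seed, and
input digests.  Re-running a configuration reproduces every output
byte-for-byte.  Numbered drivers under `analysis/` present the stages as a
narrative; `results/` holds their tables.

## Known limitations

- Univariate models only: no multi-trait or genotype-by-sex covariance
  structures (sex-specific analyses are run as separate fits), no
  zero-inflated or hurdle observation families, no maternal-effect
  components.
- The liability Metropolis step limits mixing for weakly informed Poisson
  fits; the expanded priors and long thinning mitigate but do not remove
  this — effective sample sizes are always computed rather than assumed.
- DIC is reported, not used for model selection: the battery exists to show
  how h² moves with model structure.
- The site-effect "factor" reading treats recruit-count levels as unordered
  groups; the regression reading is available but shares the same
  single-covariate limitation.
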