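# Methods

## Scope and conventions

Time is measured backwards from the present in units of 2·Nref
generations, population sizes as ratios ν to the ancestral reference
size Nref, and the scaled mutation rate is θ = 4·Nref·μ (per site or per
locus as stated). Under this convention two lineages in a population of
ratio ν coalesce at rate 1/ν and a branch of length t carries
Poisson(θ·t/2) mutations, so the expected pairwise difference count in a
constant population is exactly θ. Conversion to individuals and years
happens in one place only (`demography.to_demographic_units`):
Nref = θ̂/(4 μ L) with L the assayed sequence length in bp, and
years = T_scaled × 2·Nref × g for generation time g. The package
defaults μ = 7.7e−10 per site per generation and g = 2 years, the
standard values for small iguanian lizards.

## Expected SFS under a size history

For a sample of n allele copies the vector of expected SFS entries
F = (F₁ … F₍ₙ₋₁₎) under the neutral Wright–Fisher diffusion obeys the
closed linear system dF/dt = D F/ν(t) + s with the tridiagonal drift
operator

    (D F)_i = ½[(i−1)(n−i+1) F_{i−1} − 2 i(n−i) F_i + (i+1)(n−i−1) F_{i+1}]

(absorbing boundaries F₀ = Fₙ = 0) and mutational influx s = (n/2)·θ·e₁
into the singleton class. The neutral system needs no moment closure;
its constant-size equilibrium is Fᵢ = ν·θ/i, which the solver reproduces
to machine precision (the equilibrium is its exact fixed point).

Numerics: D is similar to a symmetric tridiagonal matrix through a
positive diagonal scaling, so its eigendecomposition is computed once
per sample size with `eigh_tridiagonal` and cached. Constant-size epochs
are then propagated *exactly* (two dense matrix–vector products per
epoch); epochs with exponentially changing size are integrated with
LSODA at rtol 1e−10 / atol 1e−12 with the analytic Jacobian D/ν(t).
Epochs shorter than 1e−12 time units are skipped — drift has no time to
act, and the exponential-rate parameterisation degenerates numerically.
Integration is initialised at the equilibrium of the most ancient epoch,
which is constant by construction.

Correctness is established by a dual route: an independent time-rescaled
coalescent simulator (exact closed-form inversion of the cumulative
coalescent rate through the epochs — no discretisation) reproduces the
solver's spectra within Monte-Carlo error for instantaneous-change,
exponential-growth and three-epoch histories, and msprime provides a
third, external check at constant size.

## Models, likelihood, optimisation, selection

The four size-history models and their parameters:

| model        | parameters           | meaning |
|--------------|----------------------|---------|
| two_epoch    | ν, T                 | instantaneous change to ν at time T |
| growth       | ν, T                 | exponential change reaching ν at present, started at T |
| bottlegrowth | νB, ν, T             | instantaneous change to νB at T, then exponential to ν at present |
| three_epoch  | νB, ν, TB, TF        | size νB for duration TB, then ν for the final TF |

The composite likelihood treats SFS classes as independent Poisson
counts with mean θ·ξᵢ(params); θ is profiled analytically
(θ̂ = Σobs/Σξ) and therefore **not counted in k** — AIC = 2k − 2·logL
with k = 2, 2, 3, 4. With folded observations the model spectrum is
folded before the likelihood. Box bounds default to ν ∈ [1e−3, 1e3] and
T ∈ [1e−4, 5], generous for any postglacial history.

Optimisation mirrors common SFS-fitting practice: four rounds of 50
replicates with 25 L-BFGS-B iterations each, searching in log-parameter
space (positivity for free, and multiplicative perturbations become
additive). Round 1 draws starts log-uniformly inside the bounds; each
later round r perturbs the incumbent best by a log-uniform factor of at
most 2^(1/r), so the search contracts around the best replicate. The
whole procedure is deterministic given its seed.

Model selection reports logL, AIC, ΔAIC, relative likelihood
exp(−ΔAIC/2), Akaike weights and their cumulative sum in AIC order;
values are exact, with a separate 2-decimal round-half-up formatter for
table presentation.

Uncertainty: the goodness-of-fit bootstrap draws Poisson spectra from
the fitted θ̂·ξ and refits, placing the empirical log-likelihood within
the simulated distribution; the non-parametric bootstrap resamples RAD
loci with replacement, rebuilds the spectrum through the same
thin → project → fold pipeline and refits (started from the point
estimate with reduced rounds — the surface near the optimum is smooth),
reporting 2.5/97.5 percentile intervals.

## SFS construction

`thin_one_snp_per_locus` keeps one uniformly chosen SNP per locus,
restoring the between-site independence the composite likelihood
assumes. `sfs_from_genotypes(project_to=m)` handles missing calls by
projecting every site from its observed allele-copy count down to a
common m with hypergeometric weights C(k,j)C(n−k,m−j)/C(n,m) — linear,
expectation-preserving, and the standard way to keep incomplete sites;
sites observed in fewer than m copies are dropped and mass landing on
the monomorphic classes is discarded. The default analysis folds the
spectrum: short-read RAD data without an outgroup cannot be polarised,
and all four models are ancestral-state-agnostic; both folded and
unfolded paths are implemented. The projection target (default m = 70
allele copies) is an explicit configuration knob.

Caveat worth knowing: when loci carry many SNPs each, per-locus thinning
*distorts* the spectrum shape (long genealogies are down-weighted), and
near-equivalent expansion models can swap ranks. At realistic RAD
densities (≲1 SNP per locus) the distortion is negligible.

## Structure statistics

FST uses the Weir & Cockerham (1984) variance components a, b, c per
site and the weighted multi-locus estimator Σa/Σ(a+b+c) (ratio of sums,
matching the semantics of the common VCF toolchain option); per-site
components are exposed for audit and negative estimates are reported as
computed. π sums the unbiased per-site heterozygosity
(n/(n−1))·2p(1−p) and divides by the assayed length L, so monomorphic
assayed sites dilute the average exactly as in sequence-based π.
Kinship is the KING-robust estimator
φ = (N_het,het − 2·N_opp-hom)/(N_het(i)+N_het(j)), allele-frequency-free
and hence robust to the structure it is screening within; degree classes
use the powers-of-two midpoint thresholds (0.354/0.177/0.0884/0.0442).
With only a few hundred shared sites the sampling noise of φ is a few
hundredths, so 3rd-degree calls at desk scale are indicative, not
conclusive. Genotype PCA mean-imputes missing dosages per site and
centres without variance scaling by default (scaling amplifies noise at
near-monomorphic sites; a frequency-scaling option exists); component
signs are fixed by making the largest-magnitude loading positive. DAPC
is linear discriminant analysis on the retained PC scores with
row-stochastic posterior membership.

## Morphometrics

All morphometric traits are ln-transformed and regressed on **ln** SVL
(not raw SVL — the residuals of a log-log fit are dimensionless
allometric deviations; the choice is configurable) over all specimens
pooled; residuals feed the downstream analyses. Meristic counts are
z-scored but not size-corrected. The Mann–Whitney sex screen is applied
per trait and to PC1, since which variable such a screen targets is a
analyst choice — both are reported, neither privileged. LDA accuracy
defaults to leave-one-out (resubstitution is optimistic and also
reported on request); groups with one specimen are excluded with a
record. Missing traits: listwise deletion with a logged count, the
smallest-surprise default at n ≈ 80.

## Synthetic-data generator

The generator emulates the study design the package targets: 78
diploids in five demes (16/16/16/15/15), 1000 unlinked 51-bp loci
(within the realistic 700–3500 range for this data type; the count is a
knob), per-site θ = 1e−3 (μ = 7.7e−10 with Nref ≈ 3.25e5 — the very low
diversity of a recently founded population), nested splits at
0.05–0.14 time units with no post-split migration, and 25% missing
calls injected uniformly at random (assembly pipelines that *allow* 50%
missing per site realise a lower mean). The split times were chosen
once, by pilot simulation, to put pairwise FST in the moderate band
(≈0.04–0.15) characteristic of such systems. Mutations follow the
infinite-sites model within each locus (capped at the locus length);
there is no recombination, no selection and no migration — deme
differentiation is pure drift since splits.

What passing tests on these data do **not** show: robustness to linked
selection, allele dropout, paralog collapse, non-uniform missingness,
or gene flow — none of which the generator produces. The generator's
role is to verify the *statistical machinery* under a known truth, not
to certify behaviour on any particular empirical dataset.

## Problem sizes used in the checks

The automated checks run at deliberately modest sizes chosen as the
package's own test design: Monte-Carlo solver validation at 2×10⁵
genealogies (n = 20); parameter recovery at θ = 500, n = 70 with the
estimate averaged (geometric mean) over three replicate datasets —
a single Poisson draw at that θ has ~20% MLE sampling noise, so the
averaged check tests unbiasedness rather than one draw's luck;
bootstrap-CI coverage with 25 bootstrap replicates over 25
meta-replicates at reduced optimiser settings; and model-selection
recovery over ten paper-scale datasets (3491 loci at the generator's
default diversity, ≈0.3 SNPs per locus so thinning is near-identity)
with three optimisation rounds of twelve replicates. The full published-style settings (4 × 50 × 25,
100 bootstrap replicates, m = 70) remain the `RunConfig` defaults.

## Known limitations

- Single-population demographic models only; no migration, no joint
  multi-population SFS, no linkage-aware likelihood.
- The Poisson random field treats thinned SNPs as independent; residual
  linkage inflates confidence nominally.
- The composite-likelihood AIC compares models, not absolute fit; use
  the parametric bootstrap for absolute goodness of fit.
- KING degree classes below 2nd degree are noisy at < 10³ shared sites.
- The coalescent generator's exponential epochs assume the rate
  integral stays finite within each epoch, which any biologically
  sensible parameterisation satisfies.
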