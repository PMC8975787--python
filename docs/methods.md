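# Methods

`chickadmix` implements the statistical chain used to ask whether birds of
two hybridizing chickadee species are in worse body condition where the
species co-occur (sympatry) than where they do not (allopatry), and
whether cryptic hybrid ancestry is part of the story. This note documents
the models, the defaults and why they are what they are, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Hybrid index

The hybrid index h ∈ [0, 1] of an individual is the proportion of its
alleles deriving from parental population B. At an unlinked biallelic
locus l with reference-allele frequencies p_Al and p_Bl in the two
parental populations, each of the two allele copies is independently the
reference allele with probability

    φ_l(h) = (1 − h)·p_Al + h·p_Bl,

so the reference-allele count g_l is Binomial(2, φ_l(h)) and the
log-likelihood is the sum over loci of log C(2, g_l) + g_l log φ_l +
(2 − g_l) log(1 − φ_l). This is the classic admixture/hybrid-zone
likelihood of Buerkle (2005). Loci are restricted to *diagnostic* sites —
per-SNP Weir–Cockerham F_ST strictly above 0.65 between the two parental
reference panels — because weakly differentiated sites contribute almost
no information about h. Locus-level effects (genomic clines, local
ancestry) are deliberately not modeled: the per-locus binomial mixture is
the whole contract.

Parental frequencies are plug-in sample frequencies from user-designated
reference panels with a Jeffreys-style pseudocount of 0.5 added to each
allele count. The pseudocount keeps φ strictly inside (0, 1), so the
likelihood is finite at loci fixed in a panel; it is configurable.

The posterior under a uniform(0, 1) prior is sampled by random-walk
Metropolis with Gaussian proposals (default sd 0.05) reflected at the
boundaries, 6000 iterations with a 3000-iteration burn-in; reflection
keeps the kernel symmetric so the acceptance ratio is the likelihood
ratio. A deterministic grid maximum-likelihood estimate (step 0.001, ties
toward smaller h) is always computed alongside as a cross-check; on
simulated 300–500-locus individuals the posterior mean and the grid ML
agree to well under 0.02. An acceptance rate outside [0.05, 0.95] raises
a warning suggesting a proposal retune (a flat likelihood, for example,
accepts every proposal and mixes poorly at sd 0.05).

**Credible intervals.** The reported 95% interval is the
highest-posterior-density (shortest-window) interval over the post-burn-in
draws, with two corrections chosen for boundary behavior: (i) when the
grid-ML estimate sits exactly on 0 or 1, the posterior mode is on that
bound and the true HPD set includes it, so the matching endpoint is set to
the bound (sample draws alone can never reach a boundary, which would make
intervals for pure parental individuals miss the truth by construction);
(ii) endpoints are rounded outward at the 0.001 grid resolution — a
conservative reporting convention matched to the estimator's resolution.
Equal-tailed percentile intervals are available via
`interval="equal_tailed"`. In calibration runs (50 individuals per
ancestry class, 500 diagnostic loci, panels of 40) the posterior mean has
mean absolute error ≈ 0.009 and the intervals cover the true h for ≈ 98%
of individuals.

The raw index is folded to g(x) = 0.5 − |x − 0.5|, mapping both pure
parentals to 0 and an F1 to 0.5; an individual with folded index ≥ 0.20
(inclusive) is called a hybrid. The 0.20 cutoff captures F1s and
first-generation backcrosses while excluding most later-generation
backcrosses. Hybrid prevalence is reported only among sympatric birds:
allopatric individuals have no opportunity to hybridize and would dilute
the denominator.

## Per-SNP differentiation

`weir_cockerham_fst` is the two-population Weir & Cockerham (1984) θ̂
from genotype counts, using observed heterozygosity and supporting unequal
sample sizes — the same estimator convention VCFtools prints per site.
Negative estimates are retained unclamped (they never pass the diagnostic
threshold anyway); sites where both panels are monomorphic for the same
allele have a zero denominator and return NaN, which is never selected as
diagnostic. A fixed difference returns exactly 1.0 regardless of sample
sizes: the analytic components give b = c = 0, and this identity is
special-cased because floating-point cancellation would otherwise return
values one ulp short of 1. Diagnostic selection uses a strict inequality
(F_ST > threshold), so raising the threshold always selects a nested
subset.

## Scaled mass index

Body condition is the scaled mass index (Peig & Green 2009):

    SMI_i = M_i · (L0 / L_i)^b_SMA

with M_i mass (g), L_i tarsus (mm), L0 a fixed standardization length
(default: the species mean tarsus; overridable to a published reference
value), and b_SMA the scaling exponent from standardized major axis
regression of ln M on ln L: b_SMA = sign(r)·s_lnM/s_lnL, equivalently
b_OLS/r. The exponent is fitted once per species on the pooled
(sympatric + allopatric) sample, because SMI values computed under
different exponents are not comparable — `compare_groups` refuses inputs
tagged with different parameters for exactly this reason.

A property of SMA worth knowing when interpreting synthetic-data fits:
because b_SMA = s_y/s_x, residual noise in ln-mass inflates the fitted
exponent above the generative OLS slope by the factor 1/r. With the
generator's defaults (OLS slope 1.09, tarsus sd 0.5 mm, ln-mass residual
sd 0.04) the fitted exponent converges to ≈ 1.85, not 1.09. This is the
estimator working as defined, not a bug; the tests assert the
Monte-Carlo-derived interval.

Sympatry/allopatry comparisons use Welch's unpooled-variance two-sample t
with Welch–Satterthwaite degrees of freedom (pooled-variance available by
flag). The headline "percent lower" is 100·(mean_allo − mean_symp)/
mean_symp — the sympatric mean as denominator, the only convention
consistent with the published group means. Under a null simulation (zero
deficit) the test's two-sided rejection rate at α = 0.05 is calibrated
(3.5% over 200 replicates).

## All-subsets AICc model averaging

Candidate models for SMI are every subset of the candidate terms (default
sex, age, sympatry, elevation, latitude, elevation:latitude, optionally
hybrid index) that respects marginality — the interaction only ever enters
with both main effects — including the intercept-only model. Numeric
predictors are Z-scaled (sample sd) before fitting so coefficients are
comparable within a model. Models are Gaussian, fitted by maximum
likelihood; at most one random intercept (default grouping: year) is
supported, estimated by ML through statsmodels' MixedLM. The parameter
count k for AICc includes every estimated parameter: fixed effects, the
residual variance, and the random-intercept variance when present.

The top model set is ΔAICc ≤ 4 from the best model; Akaike weights are
renormalized over that set. Averaging is *full* (zero method): a term
absent from a model contributes coefficient 0 at that model's weight,
shrinking weakly supported effects toward zero, with Buckland-style
unconditional standard errors

    SE(β̄) = Σ_i w_i sqrt(se_i² + (β_i − β̄)²),

se_i = β_i = 0 where the term is absent. Confidence intervals use the
1.96 normal quantile (configurable); the reported p-value is the
two-sided normal tail of β̄/SE — one defensible convention among several,
stated rather than inferred. A term is "strongly supported" when its CI
excludes zero. In recovery simulations (n = 500, a 5% sympatric mass
deficit ≈ 0.6 g against a ≈ 0.5 g residual sd), the sympatry term is
strongly supported in 20/20 replicates while a pure-noise covariate is
never flagged.

Crossed random effects (bander, band number) are out of scope: a single
random intercept is the supported structure, and the boundary MLE
(intercept variance → 0) that frequently occurs in all-subsets scans is
treated as a valid fit, not an error.

## Site filters

Loci are retained when site QUAL ≥ 30 (Phred; "below 30" removed, exactly
30 kept), minor allele frequency ≥ `min_maf` computed from non-missing
calls, missingness ≤ 0.5, and — when depth is recorded — mean depth
within the configured bounds (default use: 1–10×). The default
`min_maf = 0.0001` reads "0.01%" literally as a proportion; because that
threshold is unusually small and may be intended as 1%, it is a plain
config knob rather than a hard-coded interpretation. MISSING is a
distinct sentinel (−1), never conflated with homozygous reference;
half-calls count as missing.

## Synthetic-data generator

The generator emulates the *statistical structure* the pipeline assumes,
not the biology of real genomes:

- **Frequencies.** Background loci follow a Balding–Nichols scheme:
  ancestral frequency uniform on [0.05, 0.95], each parental frequency
  Beta-drifted with parameter f (default 0.15). A configurable fraction
  (default 3%) of loci are near-fixed for opposite alleles
  (p_A ∈ [0.95, 1], p_B ∈ [0, 0.05]) — the highly differentiated tail the
  diagnostic filter is meant to find. With 10⁴ loci and 40+40 parental
  genotypes, ≈ 354 loci exceed estimated F_ST 0.65: the 300 near-fixed
  ones plus a ≈ 54-locus background tail.
- **Genotypes.** Drawn under the same independence model the likelihood
  assumes (no linkage, no inbreeding, no genotyping error beyond a flat
  missingness knob), so parameter-recovery tests are a clean test of the
  estimator, not of robustness to model violation. Ancestry classes fix
  h_true at 0, 0.25, 0.5, 0.75, 1.
- **Morphometrics.** Tarsus ~ Normal per species (means 17.83/18.62 mm,
  sd 0.5 mm); ln-mass = ln a + b·ln tarsus + Σ log(1 − deficit) + ε with
  OLS slopes 1.09/1.12, intercepts set so mean masses land near
  11.37/11.59 g, and ε ~ Normal(0, 0.04). Condition deficits are
  multiplicative on mass (not tarsus) — condition is mass-for-length —
  with defaults of 5% for sympatry (inside the 4–8% band of interest) and
  5% for hybrid classes. Mass is rounded to 0.5 g and tarsus to 0.01 mm,
  as recorded on a banding sheet.
- **Cohort.** The default design yields 220 birds of which 170 are
  sympatric including 20 hybrids (11.8%), mirroring the structure of the
  genotyped subset the pipeline is built for; hybrid classes carry
  species-A plumage labels (cryptic hybrids). Sex is unknown for 30% of
  birds; ages collapse to HY vs AHY/ASY.

What passing tests on this generator demonstrate: the estimators recover
the parameters of their own generative model at realistic sample sizes,
the filters and selections implement their stated rules, and the
end-to-end pipeline is deterministic given seeds. What they do not
demonstrate: robustness to linkage, genotyping error, reference bias,
population structure within panels, or non-lognormal mass variation —
none of which the generator produces.

## Problem sizes and determinism

Tests and calibration runs use deliberately modest sizes chosen to make
Monte-Carlo bands tight enough to be meaningful: 300–500 diagnostic loci
per individual, parental panels of 40, 50 individuals per ancestry class
for recovery, 20 replicates for effect-recovery rates, 200 replicates for
null calibration. Every stochastic routine takes an explicit integer
seed (numpy `default_rng`); identical seeds give bit-identical outputs,
and the pipeline writes all seeds to its run manifest. Grid ML breaks
ties toward smaller h; NaN F_ST is propagated but never selected;
degenerate inputs (zero-variance tarsus, constant model columns, empty
panels, all-missing genotypes) raise informative errors rather than
producing silent numbers.
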