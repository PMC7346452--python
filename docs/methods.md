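# Methods

`purgekit` quantifies inbreeding depression (ID) and its purging for a
binomial fitness trait — kit survival at birth — in a closed, pedigreed
population. This note documents the models, the estimators, the numerical
choices and the limits of what the synthetic validation shows.

## Inbreeding coefficients by gene dropping

For every individual the package estimates four identity-by-descent
probabilities at a random autosomal locus:

* **F** — classical inbreeding: both alleles are copies of one founder
  allele (autozygosity);
* **F_A-B** (Ballou) — a random allele of the individual has been part of
  an autozygous genotype in at least one ancestor;
* **F_A-K** (Kalinowski) — the individual is autozygous *and* the shared
  allele has been autozygous before in an ancestor;
* **F_NEW** (Kalinowski) — autozygosity occurring for the first time, so
  that F = F_NEW + F_A-K.

Estimation is by gene dropping: each founder receives two uniquely
labelled alleles; every non-founder inherits one uniformly random copy
from each parent; one unlinked locus is simulated per replicate and the
probabilities are replicate frequencies. Each transmitted copy carries an
*ancestrally autozygous* flag, set when the transmitting parent is itself
autozygous at the locus or when the parental copy was already flagged —
so the flag is monotone down the pedigree and excludes the individual's
own first-time autozygosity ("previous generations" never includes the
individual itself). The estimators are

* F̂_A-B = mean over replicates of (number of flagged copies)/2;
* F̂_A-K = mean of (number of flagged copies)/2 restricted to replicates
  in which the individual is autozygous. When the two copies of an
  autozygous genotype disagree in their flags (possible, because flags
  attach to copies with distinct transmission histories) the replicate
  counts with weight equal to the fraction of flagged copies — this
  convention makes F̂ = F̂_NEW + F̂_A-K an *identity* on every run, not an
  approximation;
* F̂_NEW = F̂ − F̂_A-K, computed from the same integer replicate counts so
  the identity holds exactly in floating point.

Monte-Carlo standard errors are binomial, sqrt(p̂(1−p̂)/R). The default
R = 10⁶ replicates puts every SE below 5·10⁻⁴; tests and the simulation
harness use 10³–10⁵ for speed. A single master seed (default 20200708)
makes coefficient tables bit-reproducible.

For pedigrees with at most 10 non-founders an exact oracle enumerates all
4^m transmission outcomes with equal weight and applies the same flag
semantics; classical F from this enumeration equals the deterministic
tabular value exactly (both are dyadic rationals).

Unknown parents are treated throughout as unique, unrelated, non-inbred
founders (the standard tabular-method convention); in gene dropping an
unknown-parent slot contributes a fresh unflagged allele.

## Deterministic pedigree statistics

* **Exact F** uses the Meuwissen–Luo recursion (O(n · ancestors)).
* **A and A⁻¹**: the additive relationship matrix is built by the tabular
  method over the ancestor closure of any subset; its sparse inverse
  comes directly from pedigree rules (Henderson, with inbreeding), which
  is what the mixed model consumes.
* **Complete generation equivalents**: CGE(i) = Σ over known parents of
  ½(1 + CGE(parent)), i.e. each known ancestor contributes (1/2)^n once
  per distinct path, so a fully known depth-g pedigree scores exactly g.
  The phrase "sum over all known ancestors" is ambiguous between per-path
  and per-ancestor counting; per-path counting is the convention of the
  standard pedigree software this measure comes from.
* **Founder contributions**: c_f(founder) = 1, c_f(i) = ½(c_f(sire) +
  c_f(dam)), averaged over a cohort; contributions sum to 1 for
  fully-pedigreed cohorts, and "contributing founders" are those with
  positive contribution.
* **Ne**: the default estimator regresses −ln(1 − F_i) on the equivalent
  generation number t_i = CGE_i + 1 and converts the slope b into
  ΔF = 1 − e^(−b) (from the idealized relation F_t = 1 − (1 − ΔF)^t); the
  alternative averages individual rates ΔF_i = 1 − (1 − F_i)^{1/(t_i−1)}.
  Both are exposed because the upstream literature does not pin one down;
  either way Ne = round(1/(2ΔF)), reported as an integer. Litter dummies
  are excluded from Ne, CGE summaries and founder-contribution cohorts —
  they exist solely to carry litter-level coefficients.

**Litter dummies.** Kits are not individually pedigreed, so one synthetic
progeny per unique (dam, sire) mating pair carries the litter-level
coefficients (F_L, F_NEWL, F_A-KL, F_A-BL); repeated kindlings of a pair
share the dummy. Dummies are validated never to appear as parents.

## The survival model

Each kindling record contributes a binomial response (kits born alive out
of kits born) with logit link:

    logit P(survival) = parity + season + z.covariates + a_dam
    a ~ N(0, σ²_a · A)

* **Parity** is categorised 1 (reference), 2, 3–10, 11+; a class absent
  from a fitting period is dropped from the design rather than left as an
  all-zero column.
* **Season** is an indicator for summer, defined as 15 June–15 September
  inclusive on both ends.
* **Inbreeding covariates** are z-standardised within each fitting
  period (models are fitted per period). The default scale is the sample
  SD (ddof = 1); a 2-SD variant (which puts continuous covariates on a
  binary-predictor scale) is available as `gelman_2sd`. A year-of-kindling
  effect is deliberately absent: in a closed population calendar time is
  nearly collinear with the inbreeding trend.
* **The "animal" effect attaches to the dam** of each record. Dams are
  the repeated, pedigreed unit; litter dummies occur once each, so a
  litter-level genetic effect would be unidentifiable from the residual.
  The choice of dam (rather than litter or both) is this package's
  design decision, not a claim about the original analysis.

The response is binomial counts per kindling; a Bernoulli per-kit
expansion is available (`response="bernoulli_expanded"`) and yields the
same estimates, the likelihoods differing by a data-constant.

### Laplace estimation

The marginal likelihood is approximated by Laplace:

    ℓ(β, σ) = log f(y | â) − ½ â'A⁻¹â/σ² − ½ log det(σ²A) − ½ log det(Z'WZ + A⁻¹/σ²)

with â the conditional mode and W the binomial IRLS weights at the mode.
All linear algebra runs through Henderson's sparse A⁻¹ (at most nine
non-zeros per pedigree member) and sparse LU factorisations, so the cost
per iteration is a sparse solve rather than a dense q³ operation in the
number of dams.

Fitting is two-stage:

1. **profile stage** — penalized IRLS over (β, a) jointly at fixed σ,
   wrapped in a bounded 1-D search over log σ (σ ∈ [10⁻⁴, 10], start 0.3);
   the objective is the Laplace expression evaluated at the joint mode.
2. **refinement** (default, `method="laplace"`) — bounded quasi-Newton
   (L-BFGS-B, gradient tolerance 10⁻⁸) over (β, log σ) against the exact
   Laplace objective, with the conditional mode recomputed per
   evaluation, plus a Nelder–Mead polish on small datasets.

`method="profile"` stops after stage 1. It is the appropriate mode for
large batch fits (candidate enumeration, simulation studies): on a
5,000-record fit it is ~12× faster and agrees with the refined estimates
to better than 0.01 on every slope coefficient (the intercept differs by
~0.06); the study pipeline and the recovery harness use it, single fits
default to the refined mode. Degenerate cases: σ fixed at 0 (or no
grouping) collapses exactly to plain logistic regression; results are
invariant to record ordering.

Wald covariances of β come from the Schur complement of the mixed-model
equations at the optimum. AIC = −2ℓ + 2k and
AICc = AIC + 2k(k+1)/(n−k−1), where n is the number of kindling records
and k counts the fixed coefficients plus one variance component — the
convention is constant across candidates, which is all that AICc
comparisons require.

## Multi-model inference

Two candidate families are fitted per period, each the 2³ = 8 subsets of
its three inbreeding covariates around the fixed core parity + season +
animal:

* Ballou–Boakes: {z.F_D, z.F_L, z.F_A-BL} — purging appears as a positive
  ancestral-inbreeding effect alongside negative inbreeding effects;
* Kalinowski: {z.F_NEWD, z.F_NEWL, z.F_A-KL} — purging appears as
  β(z.F_NEWL) < 0 with β(z.F_A-KL) > 0.

Candidates within ΔAICc ≤ 2 of the best model are retained and their
Akaike weights w_i ∝ exp(−Δ_i/2) renormalised. Coefficients are combined
by the **natural average**: only over models containing the term, with
weights renormalised among those; the unconditional SE is
Σ w̃_i sqrt(SE_i² + (β_i − β̄)²) and the 95% CI is β̄ ± 1.96 SE.
**Relative importance** is the summed selected-set weight of the models
containing the term, so RI = 1 for terms in every selected model and
RI = w for a term confined to a single model of weight w. CIs are
unconditional (averaged); conditional inference on the single best model
is available from its stored fit. Non-convergent candidates are excluded
before selection, not penalised. "Significant" in reports means the 95%
CI excludes zero.

## The synthetic population

The generator breeds a closed herd with no immigration: founders in year
0, yearly recruitment of replacement does and bucks drawn from the year's
litters (optionally by truncation on a neutral heritable index, which
accelerates the decline of founder contributions), overlapping
generations through a multi-year breeding life, Poisson litter counts per
doe-year and shifted-Poisson litter sizes (mean 9 — litter size is a
nuisance input here, not a modelled trait). Mating is random, circular or
within-line; the latter two push inbreeding up faster. Survival outcomes
are drawn from the binomial-logit truth above, with the polygenic dam
effect sampled *exactly* from N(0, σ²_a A) by Mendelian sampling down the
pedigree, and covariates standardised within periods by the same code
path the analysis uses, so true coefficients are on the reported scale.

Default scenario sizes are the study system's order of magnitude scaled
down ten-fold (≈140 bucks, ≈530 does, ≈2,200 kindlings over 25 years);
`first_period_scenario` is a single-period variant sized to ≈5,000
kindlings for the recovery experiments. At one-tenth scale genetic drift
is necessarily ~10× faster than in the full-size population, so absolute
levels of F and Ne are not comparable to a full-scale herd — trends and
estimator behaviour are what the synthetic data validate. The default
truth encodes a first-period-like purging pattern (intercept 3.2, season
−0.25, parity 0.20/0.31/0.37, z.F_NEWL −0.4, z.F_A-KL +0.3, σ²_a = 0.3).

The generator shares one set of gene-dropped coefficient estimates
between data generation and analysis (the truth is defined on the
estimated-covariate scale), so recovery experiments isolate model and
averaging error from covariate measurement error. What passing tests
show: the estimator recovers signs and magnitudes of effects of this size
at this scale, with near-nominal CI coverage. What they do not show:
behaviour under real-data features absent here — maternal environment,
heterogeneous management, litter-size/survival trade-offs, genotyped
inbreeding, or selection on the trait itself.

## Numerical and degenerate-input choices

* Dates parse as ISO-8601; month-precision dates resolve to day 15, since
  period boundaries are month-level and inclusive.
* Topological order is canonical (Kahn's algorithm, ties by id), so row
  order of input files never affects results.
* Standardisation refuses zero-variance covariates; within the pipeline
  such a covariate (e.g. ancestral inbreeding before any autozygosity
  exists) is reported as undefined and its candidates are excluded for
  that period.
* Zero-variance coefficient columns yield undefined correlation cells
  (self-correlation kept at 1).
* IRLS weights are floored at 10⁻¹² to keep the penalized system
  factorable; step halving guards every Newton update.
* Oracle comparisons use the binomial SE under the exact probability,
  sqrt(p(1−p)/R), which stays well-defined when an estimate hits 0 or 1.

## Known limitations

* The Laplace approximation is least accurate for small litters and
  extreme survival probabilities; the quadrature cross-check bounds the
  error at 0.05 log-units on a one-effect toy, not in general.
* No dominance or maternal-environment variance components, no
  inbreeding × ancestral-inbreeding interaction, no genomic inbreeding —
  all deliberately out of scope.
* Ne from realised inbreeding assumes the idealized exponential F
  trajectory; in short windows with little pedigree depth the regression
  can be unstable (it raises rather than reporting a rate outside (0,1)).
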