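# Methods

This note records the model implemented by `pedrisk`, the conventions and
numerical choices behind it, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Model structure

Cancer incidence for individual *i* at integer age *t* (years 0–79, hazards
piecewise-constant on [t, t+1)) is

λ_i(t) = λ₀(t) · RR_G(t) · exp(σ_P(t)·v) · RR_RF,

the product of a constrained baseline, a major-genotype relative risk, a
polygenic log-hazard modifier, and risk-factor multipliers. The polygene and
risk factors multiply the model's primary cancer only (female breast cancer
in the breast model, tubo-ovarian cancer in the ovarian model); secondary
endpoints in relatives (ovarian, male breast, prostate, pancreatic in the
breast model) enter through their major-gene relative risks alone. All
components combine multiplicatively — the model family's standing assumption,
adopted here unchanged.

### Major genes

Each gene carries a population allele frequency q, a screening sensitivity
SS, age-piecewise relative risks per endpoint (constant or exp(u+v·age)
segments on inclusive integer age intervals; uncovered ages default to
RR=1; at interval joins the lower interval applies through its upper bound),
and a dominance rank. The genotype space is collapsed: {non-carrier} ∪
{carrier of gene g}, with founder priors from HWE carrier probabilities
c = 2q(1−q)+q² and dominance collapse (a carrier of several genes counts as
carrying the highest-ranked one; double-carrier mass is O(10⁻⁶) at these
frequencies). For Mendelian transmission the collapsed state is expanded to
allele counts — a carrier is heterozygous or homozygous with the HWE
conditional odds, transmitting its allele with probability
(q(1−q)+q²)/c — and a child receiving alleles from both parents is
re-collapsed by dominance. Test likelihoods are SS for a positive test in a
carrier, 1−SS for a negative one; specificity is fixed at 1 (a detected
variant is real), and each gene's test is evaluated against that gene's
allele state independently of other genes.

### Polygene

The residual polygenic component is discretised as the standardised sum of
2N biallelic loci: n = 2N+1 levels with Binomial(2N, ½) founder masses and
grid values (k−N)/√(N/2) (exact mean 0, variance 1). Transmission is the
exact hypergeometric model — each parent passes a Hypergeometric(2N, R, N)
draw of its R risk alleles — which keeps the founder distribution stationary
and gives midparent means with segregation variance N/(2N−1) (→ ½ as N
grows). Hazard multipliers exp(σ_P(t)·v_k) are renormalised to population
mean 1 at every age. The default n=7 balances accuracy against the cubic
growth of the transmission tensor; tests use n=3 where brute-force
enumeration is the oracle.

σ_P(t) is a required configuration input; the shipped default (constant 1.2
for the breast model, 1.1 for the ovarian model) is a synthetic placeholder,
not an estimate — consequences below under *Fixtures*.

**Adding genes.** When a gene moves from the polygene into the explicit
model, its log-scale variance v_g(t) = p(1−p)·ln²RR_g(t) (p the carrier
probability), averaged over ages with incidence weights, is subtracted:
σ_new² = σ_old² − Σ v_g. Whether the published model removes variance on the
log-RR scale or a liability scale is not derivable from the main text; the
log-RR convention is used and isolated in `gene_log_rr_variance`.

**PRS.** A measured PRS z explaining α² of the polygenic variance implies a
residual polygene ~ Normal(α·z, 1−α²) on the standardised scale.
`condition_on_prs` realises this as a shift/scale of the grid (masses
unchanged). Inside pedigree peeling, where the polygene level is a shared
latent variable, the PRS instead enters as the exact observation factor
N(z; α·v_k, 1−α²) on the individual's level — the two agree in their first
two moments and coincide as n grows; the factor form composes correctly with
family history.

### Incidence and baseline constraining

Birth-cohort incidence is assembled from calendar-period tables by averaging
the rates along each cohort year's Lexis diagonal (age t, period y+t);
periods beyond the observed range borrow the nearest observed period (this
carry-forward/backward rule is the one place the cohort construction is
underdetermined — registry smoothing details vary — so it is isolated behind
`build_cohort_incidence`). Five-year input groups are expanded by constant
interpolation. The model layer groups individuals into birth decades and
borrows the latest available cohort for people born beyond the table.

Given the joint profile distribution (genotype × polygene level × risk-factor
bin, masses mᵢ, multiplier curves RRᵢ(t)), the baseline solves, forward from
age 0,

λ₀(t) = λ_pop(t) · Σᵢ mᵢ Sᵢ(t) / Σᵢ mᵢ Sᵢ(t) RRᵢ(t),
Sᵢ(t+1) = Sᵢ(t) · exp(−λ₀(t) RRᵢ(t)),

so the hazard averaged over the still-disease-free equals λ_pop(t) at every
age (verified to 10⁻¹⁰ relative in tests). Exponential within-year survival
is used rather than (1−λ) products: stable for small rates and consistent
with per-year rate semantics.

A consequence worth stating: the constraint matches *hazards*, not survival.
By Jensen's inequality the model's population survival slightly exceeds
exp(−Σλ_pop), so the model-average lifetime risk sits below
1−exp(−Σλ_pop) by a second-order term ≈ ½·Σ λ²·Var(RR) that grows with the
multiplier variance (about 1×10⁻³ relative at σ_P = 1.0 with the synthetic
incidences, about 4×10⁻⁴ at σ_P = 0.7). The exact internal identity —
prior-weighted carrier-specific risks equal the marginal risk — holds to
machine precision and is tested separately.

### Continuous risk factors

Bin masses follow B(n−1, ½); for a continuous density the fixed masses
uniquely determine the boundaries as quantiles (computed from the survival
side where tail masses underflow the CDF side). Per-bin RRs are
density-weighted averages by adaptive quadrature (relative tolerance 10⁻¹⁰,
validated against a closed form for the normal/log-linear case and against
dense Riemann sums). All RRs are rescaled so the population mean is exactly
1 — the constraining step would otherwise re-absorb the constant, so
absolute risks are invariant to this; it just makes per-bin RRs
interpretable. The individual's zero-mass bin at the measured value has RR
RR(x)/Z on the same scale; because it carries no mass it provably leaves
λ₀ untouched (tested at 10⁻¹⁴).

The individual's position in the distribution is treated as fixed over age;
age-varying parameters are accepted in configuration but constant for
height (mean 162.81 cm, SD 6.452 cm, log-RR per SD 0.10130 for both
cancers).

**Bin-count selection.** For n = 2, 3, … the lifetime risk is computed at
100 percentiles (0.5%–99.5%, 1% apart); each percentile's asymptote is
estimated by Aitken Δ² extrapolation over the computed sequence (isolated in
`asymptotic_value`; the published mechanism says "asymptotic extrapolation"
without fixing the formula), and the chosen n is the smallest with RMS
relative error below 10⁻⁴. On the synthetic model this selects n = 5 for
height, with a monotone error sequence.

### Pedigree likelihood and risks

Observation likelihoods per person multiply: survival/hazard terms per
endpoint (follow-up stops at the first cancer diagnosis or censoring; a
diagnosis at age d contributes S(d)·λ(d)), the five-category ER/TN pathology
probability at the diagnosis age (gene-specific table if available, else
population; ER-unknown contributes 1; pathology on non-breast cancers is
ignored), genetic-test factors, and the PRS factor. Unmeasured risk factors
are marginalised per person as a mixture over their population bins (they
are individual-specific and non-transmitted, so this is exact).

The total likelihood is computed by variable elimination on the factor graph
(founder priors, parent–child transmission tensors, observation factors)
with greedy min-degree ordering and per-step rescaling against underflow.
This handles arbitrary loop-free pedigrees and marriage loops; consanguinity
is rejected with a clear error. Peeling is verified against exhaustive
enumeration (200 random pedigrees ≤ 6 members, within 10⁻⁹ relative).
Carrier probabilities are the target's posterior over collapsed states;
risks are posterior-weighted cumulative incidences, with the target's
risk-factor bin posterior carried jointly so future hazards use the same
latent assignment as the likelihood. Lifetime risk is the age 20→80
cumulative risk conditional on being disease-free at 20. Unknown censoring
ages default to (2020 − birth year) capped at 80.

Reclassification distributions integrate lifetime risk over the population
distribution of the chosen unobserved factors: categorical factors are
enumerated exactly, the PRS on a ≥64-node Gauss–Hermite grid; a seeded
Monte-Carlo sampler cross-checks the category proportions in tests (3 SE).
The "mother affected at 50" family-history scenario censors the mother at a
configurable age (default 55 — the scenario leaves it open, so it is an
explicit knob).

## Fixtures: what the synthetic data does and does not emulate

`pedrisk.fixtures` generates everything the published parameter tables do
not provide: calendar incidence (constant or log-linear in age with a cap,
zero before age 20; magnitudes giving realistic lifetime risks of ~10%
female breast, ~1.5% tubo-ovarian), pathology tables (logistic age trends
with the qualitative gene directions: BARD1/RAD51C/RAD51D predominantly
ER-negative and decreasing with age, CHEK2/ATM predominantly ER-positive,
TN-majority within ER-negative except CHEK2), risk-factor distributions, and
random pedigrees with phenotypes simulated forward from the model itself
(genotype → hazard → event age), which is what makes parameter-recovery
testing possible.

Passing tests therefore demonstrate the *mathematics*: constraint
satisfaction, exactness of peeling, variance conservation, orderings and
convergence. They do not demonstrate calibration to any real population:
published absolute lifetime risks (24%/22%/21% breast for BARD1/RAD51C/
RAD51D carriers; 5.0% ovarian for PALB2) require national registry incidence
for the 1980s UK birth cohort, and published reclassification percentages
additionally require the published questionnaire-factor and density
distribution tables; with synthetic inputs the corresponding checks are the
risk orderings, carrier-dominance directions, and quadrature-vs-Monte-Carlo
consistency. Fixture tables never imitate real national rates numerically.

## Numerical choices and degenerate inputs

- Quadrature support truncated at μ±8σ (tail mass < 10⁻¹⁵); outermost bin
  edges closed 4σ beyond the adjacent quantile.
- Baseline constraining raises a degenerate-model error if the disease-free
  average multiplier hits zero; profile masses must sum to 1 within 10⁻¹².
- α² = 1 PRS conditioning clamps to the nearest grid level (the observation
  factor becomes an indicator).
- Zero total pedigree likelihood (e.g. a positive test configuration made
  impossible by the collapsed representation) raises an inconsistency error
  rather than returning NaN posteriors.
- State-space caps guard peeling (advising fewer polygene levels) and
  enumeration.

## Limitations

- No competing mortality: risks are pure cumulative cancer incidence and
  overstate absolute risk at old ages.
- The collapsed genotype space cannot represent double carriers, so two
  positive tests in different genes are inconsistent by construction.
- One polygenic component per model; no cross-cancer polygenic correlation,
  and the polygene does not modify secondary endpoints.
- Contralateral/second-cancer risks and male-proband breast-cancer
  prediction are out of scope (male phenotypes enter relatives'
  likelihoods only).
- The package consumes published relative risks and frequencies; it does not
  estimate them, and ships no real population parameters beyond the gene
  tables.
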