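# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices that matter for reproducing results.

## Dose–response models and likelihoods

Continuous responses (log2 expression; organ weights) are modeled as
Gaussian with a mean function μ(d) and a single residual SD σ shared across
dose groups.  Constant variance is assumed throughout because the benchmark
response is defined in σ units — an SD-multiple BMR is only meaningful with
one σ.  Under this likelihood the ML mean-parameter estimates coincide with
least squares, so linear/polynomial families are solved exactly by OLS and
the nonlinear families (power, Hill, exponential 4/5) by bounded nonlinear
least squares (trust-region reflective), with a moment-based start plus four
lognormally jittered restarts and a 250-evaluation cap per start.  Hill fits
are multimodal in (k, n); the multi-start is what makes their recovery
reliable.  σ̂² = RSS/N (the ML estimate) and the AIC counts σ as an
estimated parameter: AIC = 2(p_mean + 1) − 2ℓ.

Dichotomous (quantal) incidence uses the binomial likelihood with the eight
standard quantal mean functions (gamma, dichotomous-Hill, logistic,
log-logistic, probit, log-probit, Weibull with shape ≥ 1, two-stage
multistage with non-negative coefficients), fit by L-BFGS-B with jittered
restarts.  Power-type shape parameters are restricted to ≥ 1 by default
(configurable) to exclude infinite low-dose slopes.

Group-summary continuous endpoints (mean/SD/n per dose) are expanded into a
two-point pseudo-sample per group that reproduces the group mean and sum of
squares exactly; under the constant-variance Gaussian likelihood this is
sufficient — the fit depends on the data only through those statistics.

## Benchmark dose and its lower bound

Continuous BMD: smallest d > 0 with |μ(d) − μ(0)| = BMR·σ̂, closed form for
linear/power/Hill, bracketed root-finding on a 400-point log grid up to 10×
the top dose otherwise (relative tolerance 1e-8).  Dichotomous BMD: dose at
extra risk [P(d) − P(0)]/[1 − P(0)] = BMR, default BMR 0.10 extra risk.  The
transcriptomic BMR default is 1.349 σ (≈ the shift placing 10% of a control
population beyond its 99th percentile); the apical continuous BMR defaults
to 1 σ.  Both are plain config fields.

BMDL: one-sided 95% profile-likelihood bound.  The profile fixes BMD(θ) = b
via an SLSQP equality constraint over the full parameter vector (mean
parameters plus log σ for continuous fits), steps b downward geometrically
(factor 0.75) until the deviance 2(ℓ̂ − ℓ_b) crosses χ²₁(0.90) = 2.7055, and
bisects to relative tolerance 1e-4.  A profile that cannot be bracketed is
reported as not computable, never as a number.  Interpreting the "0.95
confidence interval" as one-sided follows benchmark-dose software
convention; a two-sided reading would use χ²₁(0.95) and give slightly lower
bounds.  Coverage of the true BMD measured on simulated linear genes
(6 × 6 design, σ = 0.2) runs at 94–99%, consistent with the nominal
one-sided 95%.

## Gene screening

The conservative screen uses a shrinkage-variance ANOVA: per-gene residual
variances are shrunk on the log scale by a positive-part James–Stein rule,
z̃_g = z̄ + (1 − c)(z_g − z̄) with c = min(1, (G−3)·ψ′(df/2)/Σ(z_g − z̄)²),
where ψ′(df/2) is the known sampling variance of log s² for a chi-square
variance estimate.  When all gene variances coincide the rule is a no-op and
the statistic reduces to the ordinary F.  Significance comes from
permutation: residuals (value minus group mean) are restandardized by
√((n−1)/(n−k)), pooled across the entire matrix, globally shuffled, the
group structure reimposed, and the statistic recomputed (default B = 1000;
p = (1 + #{F*ₛ ≥ Fₛ})/(1 + B), so the attainable floor is 1/(1+B)).  Global
pooling is deliberate: with a shrunken (near-common) denominator the
statistic is no longer self-normalized, and within-gene shuffling cannot
reproduce the chi-square spread of the between-group mean square — it
rejects at roughly twice the nominal rate.  The pooled scheme is calibrated
(measured 3.7–5.4% at nominal 5% across seeds) at the cost of ignoring
gene–gene correlation, which the generator does not produce anyway (see
below).

FDR adjustment is Benjamini–Hochberg (via statsmodels), fold changes are
least-squares means (group means of log2 values in the one-factor design),
and the two retention rules are: conservative — FDR p ≤ 0.05 and max linear
|FC| ≥ 1.5; liberal — ANOVA p ≤ 0.05.  Threshold comparisons are inclusive
(≤, ≥) and configurable.

## Gene-level workflow details

Selection cascade order: nested chi-square among linear/poly2/poly3 first,
then AIC against Hill and Power (ties to fewer parameters), then the GOF
gate.  Flag handling precedes the GOF filter: a flagged-and-substituted
model only needs GOF p > 0.05 (its own gate), while never-flagged selections
face the stricter p > 0.1; the post-filter therefore applies the 0.1 removal
to never-flagged records only.  The halving fallback assigns 0.5× the lowest
unflagged-Hill BMD in the study and scales the BMDL by the same factor.
Probe-to-gene collapse averages BMD and BMDL over a gene's surviving probes
(a `lowest` alternative is available); synthetic studies are generated at
gene level, so the collapse is an identity there.

## Pathways, approaches, bootstrap

Pathway BMD = mean of member-gene BMDs, assigned only with ≥ 4 scored
members.  Enrichment is the right-tailed Fisher exact (hypergeometric tail)
test.  Two universes are used: DEG enrichment tests the conservative DEG set
against all platform genes; BMD-restricted enrichment keeps the platform
universe but selects the genes that survived BMD modeling — the same test as
conventional enrichment with a different selected set.  Upstream-regulator
significance is the identical Fisher overlap applied to regulator target
sets from a user GMT; curated activation scores of commercial tools are out
of scope.

The eleven approaches follow the rules listed in the README.  Aggregation is
the unweighted mean across selected pathways (each pathway already a mean
over genes) for pathway-set rules, the mean over selected genes otherwise;
Approach 11 takes the median of pathway BMDs (a gene-level median variant is
exposed).  Approach 5 uses linear-interpolation quartiles with an inclusive
Q1 ≤ BMD ≤ Q3 band.  Approach 3 applies no enrichment gate by default (its
rationale is "regardless of enrichment"); a flag adds one.  All top-20
selections break ties by the ranking key then lexicographic identifier, so
reruns are bit-identical.  Selections shorter than 20 are flagged `partial`;
empty selections make the approach `unavailable` rather than erroring.

Bootstrap (default B = 2000): gene BMDs are resampled with replacement
within each selected pathway (pathway rules) or within the selected gene set
(gene rules); the entity selection itself is held fixed across replicates,
and per-approach seeds are derived counter-style from the run seed.  The
bootstrap mean is the reported POD for all approaches (including the
median-statistic Approach 11, whose bootstrap mean is reported the same
way); the CV = SD/mean summarizes dispersion.

## Apical recommendation ladder

A fit is viable when it converged, has a testable GOF with p ≥ 0.1 (a model
with no residual degrees of freedom cannot be assessed and is not viable),
a computable BMDL, BMD ≤ the current top dose, and BMD/BMDL < 20.  Among
viable fits: lowest AIC when the BMDL spread is within 3-fold, otherwise
lowest BMDL.  With no viable fit the highest dose group is removed and the
suite re-run; once three groups (including control) remain the endpoint is
reported as failed.  These rules mirror published benchmark-dose modeling
guidance; the exact internal tables of proprietary wizards are not public,
so the rules here are documented and configurable.

## Concordance

PODs in ppm convert to mg/kg-day via subchronic food-intake factors
(female F344 0.113, male F344 0.1).  Criterion 1 uses the mean of
per-chemical BMD_t/POD ratios (strictly < 3); descriptive fold-band counts
are two-sided (1/3 ≤ ratio ≤ 3, inclusive).  Criterion 2 is the two-sided
Pearson p on log10 pairs (< 0.05), exactly calibrated under normality.
Criterion 3 is the likelihood-ratio test of ŷ = a + b·x against y = x with
the variance profiled out, LR = n·ln(RSS₀/RSS₁), referred to χ²(2).  That
reference is asymptotic: at n = 6 chemicals the exact null law
((RSS₀−RSS₁)/RSS₁·(n−2)/2 ~ F(2, n−2)) gives a 13.6% rejection rate at the
nominal 5% cutoff, and the measured rate matches (13.3–13.5% over 10⁴
simulations).  The test is reported as defined because that is the
field-standard formulation; users comparing few chemicals should expect
criterion 3 to be conservative toward declaring 1:1 departures.  Log base
cancels in both r and LR.

## Synthetic-data generator

The generator emulates a subchronic rodent study: six dose groups (control
plus five treated, default 0/2.5/5/10/25/75 mg/kg-day), six replicates per
group, log2 expression with i.i.d. Gaussian noise (default σ = 0.2, typical
of RMA-normalized arrays), a minority of dose-responsive genes
(default 15%) with true BMDs sampled log-uniformly over a configured range,
random response direction, and generating curves drawn from
linear/power/Hill.  Mean shifts saturate at ±4 log2 units — transcripts do
not rise without bound — which leaves the BMR crossing, and hence the true
BMD, untouched.  Half the pathways are constructed "enriched" (default 60%
of members drawn from responsive genes); regulators likewise.  Matched
apical endpoints are generated as Hill-shaped continuous summaries (true
BMD = the σ-multiple crossing) and logistic-in-log-dose dichotomous
incidence anchored so the stated extra risk occurs exactly at the requested
dose.

What it does not emulate: probe-level artifacts, batch effects,
heteroscedasticity, gene–gene correlation, or within-animal correlation
between transcriptomic and apical endpoints (the two are independent given
dose).  Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to correlated or
heavy-tailed real-array noise.

The six-chemical concordance suite spreads apical BMDs geometrically over
2–300 mg/kg-day, scales each chemical's dose grid around its apical BMD
(0, 0.2×, 0.5×, 1×, 2.5×, 6×), and scatters each chemical's transcriptional
center around the apical BMD with log-SD 0.2 — the chemical-to-chemical
variation real multi-chemical comparisons show; without it the log-log
correlation is so tight that the 1:1 test detects percent-level estimation
bias.  Suite runs use 240 genes, 25% responsive, 16 pathways per chemical:
large enough for every approach to be computable, small enough that the
full six-chemical analysis runs in about half a minute on one CPU.

## Determinism and degenerate inputs

Every stochastic step (generator, permutations, optimizer restarts,
bootstrap) is seeded from an explicit integer; reruns are bit-identical and
the run summary records a hash of the full configuration.  Constant genes
get F = 0, p = 1; flat fitted curves report no BMD; an empty pathway file,
missing regulators, or zero enriched pathways degrade the affected
approaches to an explicit `unavailable` status rather than failing the run.
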