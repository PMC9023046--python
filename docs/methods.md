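# Methods

## Model

A crosswise question couples a sensitive statement (prevalence π,
unknown) with a non-sensitive statement (prevalence *p*, known, e.g. from
official birth-month statistics). The respondent reports whether they
agree with both statements or neither ("both/none") versus exactly one.
Assuming the randomizer is independent of the sensitive status, the
"both/none" probability is λ(π) = πp + (1−π)(1−p), linear in π with slope
2p − 1; the answer distribution of an arm of size n is Binomial(n, λ).

The closed-form estimator π̂ = (n′/n + p − 1)/(2p − 1) is the method-of-
moments inverse of λ. It is **not clamped** to [0, 1]: negative or
above-one values are informative misfit diagnostics and are surfaced via
an `out_of_range` flag instead of being silently truncated. Its standard
error is the delta-method transform of the binomial SE of n′/n.

The extended design (ECWM) runs two groups with complementary
randomization probabilities (here p₁ = .158, p₂ = .842). The pooled
estimate maximizes the equality-constrained two-arm binomial likelihood
over π ∈ [0, 1]; its SE is the inverse square root of the observed Fisher
information Σ_g n_g (2p_g − 1)² / (λ_g(1 − λ_g)) at the MLE. This SE
choice reproduces all the pooled standard errors printed in the packaged
study to within 0.01 percentage points, which is the evidence for
adopting it; a different (e.g. expected-information or profile) estimator
could differ in the third decimal. For a single arm the formula reduces
to the delta-method SE of the closed form, so per-group "closed-form" and
"single-arm ML" estimates coincide in this model.

## Tests

All tests are likelihood-ratio tests between nested binomial models,
referred to the χ² distribution:

* **Fit test** (1 df): saturated model (each arm's λ free at its observed
  frequency) against the pooled model. Rejection means the two group
  estimates disagree — the signature of a systematic answer bias such as
  a preference for the "exactly one" option.
* **Technique comparison** (1 df): baseline with one shared crosswise
  parameter plus a free DQ proportion, against a single common parameter
  across all arms (found numerically). With one crosswise arm this
  becomes a **bound comparison**, used when misfit makes the two group
  estimates lower/upper bounds of the truth. Pooled comparisons are
  reported even for misfitting items (with the bound analyses alongside),
  mirroring standard reporting practice.
* **Contingency test**: Pearson χ² without continuity correction (the
  uncorrected statistic is what reconstructed dropout counts reproduce),
  with Cramér's V = sqrt(χ²/(N·(min(r,c)−1))).

Likelihood-ratio additivity holds by construction: fit G² plus comparison
ΔG² equals the saturated-vs-fully-restricted statistic (tested to 1e−8).

## Numerical choices

* Scalar optimization: bounded Brent search on [0, 1], absolute tolerance
  1e−12, verified against exhaustive grid search at step 1e−7 for small
  arms. Deterministic; no seed involved.
* If the boundary value 0 or 1 matches or beats the interior optimum the
  estimate snaps to the boundary and is flagged (`at_boundary`); the
  symmetric Fisher SE is then only a one-sided caveat.
* 0·ln 0 = 0 throughout the likelihood code; a boundary λ with interior
  counts yields −∞, not an exception.
* G² values in (−1e−9, 0) from optimizer noise are clamped to 0; anything
  more negative raises.
* Count reconstruction rounds n·λ(π̂) to the nearest integer and records
  the pre-rounding residual. Residuals above 0.2 flag a printed
  estimate/arm-size inconsistency; all reconstructions in the packaged
  fixture land within 0.03 of an integer, which is what makes the study
  exactly recomputable from its printed numbers.

## Simulator

Each simulated respondent passes through a fixed pipeline: latent carrier
status ~ Bernoulli(π_true); social-desirability misreporting flips a
socially unfavorable truthful answer toward the favorable one with
probability `sd_rate_dq` (direct questioning) or `sd_rate_ecwm`
(crosswise, expected no larger); with probability `gamma_random` the
final answer is a fair coin; in crosswise arms, with probability
`beta_exactly_one` the respondent picks "exactly one" regardless of
truth. The mixture is applied in that order, chosen so that the crosswise
marginal obeys the known bias law exactly: under pure random responding
E[π̂] = (1−γ)π + γ/2, with π = ½ the fixed point.

`gamma_random` applies to all arms by default, matching the mixture's
definition. Because random responding is plausibly format-specific (the
crosswise format carries a heavier comprehension burden than a direct
question), `gamma_random_dq` can override the DQ arm's rate; the
noise-regime scenarios used to validate the pattern classifier set it to
zero, since a noise rate common to all arms shifts both techniques'
expectations identically and produces no discriminating pattern at all.

The randomizer is drawn independently of carrier status (a birthday has
no relation to the sensitive attribute). One RNG stream drives each
simulation call, and records are emitted respondent-major, so a fixed
seed yields byte-identical output. Two-item designs are emulated by
paired calls sharing arm assignment with independent latent truths; no
cross-item correlation is modeled. The simulator also makes no attempt
to model panel dropout, item-level wording effects, or Likert-scale
response styles — passing tests demonstrate estimator correctness under
the stated mixture, not robustness to every real-world response process.

Default study conditions follow the packaged fixture: arm sizes ≈ 540
(twice as many crosswise as DQ respondents overall, compensating the
randomization-induced efficiency loss — simulated crosswise SEs exceed DQ
SEs by a factor of ~2 at p = .158), p₁ = .158 / p₂ = .842, prevalences
around .25 ("low") and .75 ("high"). Power is estimated by Monte-Carlo
simulation of the full pipeline (simulate → estimate → ΔG² test) rather
than a closed form; the effect size is an explicit scenario input because
no single canonical value exists.

## Pattern classification

The 2×2 framework crosses desirability with prevalence. Successful
social-desirability control predicts crosswise > DQ for undesirable and
crosswise < DQ for desirable attributes, regardless of prevalence; random
responding predicts crosswise > DQ below 50% prevalence and crosswise <
DQ above it, regardless of desirability. The accounts disagree only in
the undesirable/high and desirable/low cells, so the overall verdict
counts significant comparisons in those diagnostic cells consistent with
each account; strictly more wins, ties give "mixed". Whether an overall
judgment should privilege the diagnostic cells or weight all attributes
equally is a genuinely open reporting choice, so an all-cells tally is
returned alongside the diagnostic one.

## Exclusion filter

The self-reported random-responding item ("I just randomly ticked one of
the answers", 1–7 Likert) drives an exclusion rule that **retains scores
strictly below the threshold** (default 2). The source wording for this
filter is ambiguous — it describes respondents scoring ≥ 2 as excluded
while attaching the retained-n to the same clause — and the implemented
semantics follow the stated retained fraction (86.39%).

## Packaged fixture

The fixture transcribes the printed quantities of a large pre-registered
German online-panel validation study: eight sensitive attributes (two per
design cell), per-group and pooled estimates with SEs, DQ estimates, arm
sizes, fit and comparison statistics, the dropout contingency table
(rebuilt from the initial N = 7172, 668 dropouts and per-technique
dropout rates), and the exclusion fraction. `reproduce_results()`
recomputes everything from reconstructed counts and reports deviations;
bound analyses are triggered exactly when the recomputed fit test rejects
at α = .05. Known printed-rounding quirks (e.g. a Δπ̂ that differs by
0.03 points from the difference of its printed operands) are not chased:
the reproduction layer reports recomputed differences.

## Reporting conventions

Probabilities are [0, 1] internally; percentages appear only at the
reporting layer, rendered with 2 decimals, G² with 2 decimals and
p-values with 3 (below .001 as "<.001") to match the fixture's style.
The significance threshold defaults to α = .05 and is configurable.
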