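# Methods

This note records the statistical model behind `wedesign`, the design rules
as implemented, what the synthetic-data generator does and does not emulate,
and the choices made where the design was genuinely open.

## Outcome model and selection criterion

A trial studies *m* regimens (doses of one agent, or dose pairs of two agents
under the product partial order of toxicity). Each patient contributes a
binary toxicity indicator and a continuous efficacy response; efficacy is
only interpretable in the absence of toxicity, so the patient-level outcome
is trinomial: (efficacy & no toxicity, no efficacy & no toxicity, toxicity)
with probabilities θ = (θ₁, θ₂, θ₃). Under independence of the two endpoints
the vector factorises through the marginal toxicity probability p_t and
efficacy probability p_e as θ = ((1−p_t)p_e, (1−p_t)(1−p_e), p_t).

Regimens are scored by the divergence of θ from a target profile γ:

δ(θ, γ) = γ₁²/θ₁ + γ₂²/θ₂ + (1−γ₁−γ₂)²/(1−θ₁−θ₂) − 1.

δ ≥ 0 with equality iff θ = γ; each term diverges as its outcome probability
vanishes, so inefficacious (θ₁→0), over-toxic (θ₂→0 or θ₃→1) and
severely under-dosed (θ₃→0) regimens are all penalised without a
dose–response model. The targets default to γ_t = 0.01, γ_e = 0.99. A
weighted variant raising each term to powers (ω₁, ω₂, 3−ω₁−ω₂) is exposed
(`CriterionWeights`) but defaults to the unweighted form; we make no claims
about the location of its optimum for ω ≠ (1, 1).

An important structural fact, verifiable from the true scenario parameters:
with near-boundary targets the criterion is dominated by 1/θ₁, so among two
regimens with efficacy well inside the feasible range the criterion alone can
prefer the more efficacious one even when its toxicity exceeds the clinical
ceiling φ. Safe-regimen selection therefore rests on the safety machinery
(below), not on the criterion by itself; the final recommendation filter
makes this explicit.

## Endpoint transformation

Continuous efficacy values are mapped to (0, 1) by T(ξ) = linkinv(α + βξ),
with the inverse logit by default and the probit or complementary log-log as
alternatives. (α, β) solve two anchor conditions: the lowest efficacy bound
ψ maps to p_low (default 0.01) and the best clinically feasible value ψ′ maps
to p_high (default 0.9):

β = (link(p_high) − link(p_low)) / (ψ′ − ψ),  α = link(p_low) − βψ.

For the tumour-marker setting (change in log SCCA; lower is better) ψ = 0 and
ψ′ = −4.5, giving α ≈ −4.595, β ≈ −1.509; β < 0 encodes the lower-is-better
orientation. Unlike a linear rescaling, the link imposes no truncation for
values outside [ψ′, ψ]. By default the alternative families reuse the
logistic-solved (α, β) so the three curves are directly comparable;
family-specific anchor solving is available via `solve_per_family=True`.
The anchors are configuration, not constants: the p_low = 0.5 variant is
reachable by passing different anchor probabilities.

## Conjugate posteriors

Each regimen is modelled independently (no borrowing — deliberate, so the
design applies when orderings of efficacy are unknown):

* Toxicity: prior Beta(ν, β_s − ν), i.e. prior mean ν/β_s carrying β_s
  pseudo-observations; after t toxicities in n patients the posterior is
  Beta(ν + t, (β_s − ν) + (n − t)) with mean (t + ν)/(n + β_s).
* Efficacy: x ~ N(μ, σ²) with (μ, σ²) ~ NIG(μ₀, λ, ζ, ζ′); the standard
  conjugate update applies — posterior mean μ̂ = (λμ₀ + Σx)/(λ + n_e),
  λ → λ + n_e, ζ → ζ + n_e/2,
  ζ′ → ζ′ + ½Σ(xᵢ − x̄)² + n_e λ(x̄ − μ₀)²/(2(λ + n_e)).

The safety rule uses the exact Beta upper tail P(p_t > φ). The futility rule
uses a normal approximation to the marginal posterior of μ with variance
rate/((ζ + n_e/2)(λ + n_e)) — chosen for simplicity over the exact Student-t
marginal; at the sample sizes involved (n_e ≥ 3 when the rule can bind) the
approximation error is far below the controlling-probability resolution. For
a lower-is-better endpoint the futility mass is the posterior probability
*above* the threshold ψ*; ψ* is interpreted on the original outcome scale
(default 0.20).

The efficacy sample size n_e may lag the per-regimen patient count n when
responses are delayed or missing; the posterior uses whatever is visible,
while the constraint schedules are evaluated at n (patients put at risk).

## Design rules

Defaults (the reference specification): φ = 0.3, ψ* = 0.20, cohort size 3,
N = 36 (single agent, m = 4) or N = 72 (4×2 combination), prior strengths
β_s = λ = 1, ζ = 2, ζ′ = 3, calibrated prior means
p̂_t = (0.10, 0.14, 0.18, 0.22) and μ₀ = (−1.000, −1.025, −1.050, −1.075)
(combination: second-agent row shifted one step), schedules
η₁(n) = max(0.95 − 0.02 n, 0.6) and η₂(n) = max(0.80 − 0.02 n, 0.3).

After every cohort:

1. Absorbing flags. Regimen j is flagged unsafe when P(p_t,j > φ) ≥ η₁(n_j)
   and futile when the futility mass reaches η₂(n_j). Flags never clear.
   Unsafety propagates to every regimen above j in the known toxicity
   ordering; futility does not propagate (efficacy ordering is unknown by
   design).
2. Coherence. Untried regimens are reachable only when all their immediate
   predecessors in the ordering have been tried (no skipping), and no
   regimen above a just-treated one is a candidate immediately after a
   cohort whose observed toxicity fraction there reached φ.
3. Allocation. Among the remaining candidates, the two smallest plug-in
   scores δ̂ compete; each patient of the next cohort is randomised between
   them with probabilities ∝ 1/δ̂ (ties broken by lower toxicity estimate,
   then lower index; two numerically-zero scores split evenly). The whole
   trial starts at the lowest regimen. `DesignConfig.allocation="cohort"`
   instead assigns the entire cohort to one sampled candidate; patient-level
   randomisation is the default because cohort-level sampling can leave the
   globally best regimen untried for an entire trial when the runner-up's
   data-driven score stays below the best regimen's prior score — in the
   strictly-increasing-efficacy scenarios this happens in a substantial
   fraction of trials and visibly degrades correct selection.
4. Termination. If no candidate remains, the trial stops without a
   recommendation.

Final analysis (after complete follow-up of all non-missing responses): the
recommendation is the regimen minimising δ̂ among tried regimens that (a) are
unflagged, (b) pass the end-of-trial controlling probabilities
(P(p_t > φ) < η̄₁ = 0.6, futility mass < η̄₂ = 0.3), and (c) satisfy the
trial's safety definition on the plug-in estimate, p̂_t ≤ φ. Filter (c) is
this package's design choice: because the criterion alone can prefer an
over-toxic regimen (see above), the recommended regimen is additionally
required to qualify as an optimal biological regimen on the final estimates.
Without it, a moderately over-toxic dose with a lucky low observed toxicity
rate is recommended noticeably more often than the reference operating
characteristics report.

One printed inconsistency is resolved in favour of the operative formula:
the futility schedule is described as increasing in n but printed as the
decreasing function max(0.8 − r_e n, η̄₂); we implement the printed formula,
whose floor η̄₂ is the final-analysis control.

## Synthetic data generator

Patients are generated by the latent bivariate-normal (Tate) construction:
(u, v) standard bivariate normal, toxicity = 1{Φ(u) > 1 − p_t}, efficacy =
μ + σv, with |corr| = r between the latents. The orientation is chosen so
that **positive r pairs toxicity with lower (better-coded) efficacy values**.
Both orientations are distributionally valid Tate constructions; this one
reproduces the reference sensitivity pattern, in which growing positive
correlation shifts selection toward the start of a dose-efficacy plateau:
safety screening retains low-toxicity observations, and under this pairing
the surviving observations at more toxic regimens are biased toward worse
observed efficacy. The marginals are exactly Bernoulli(p_t) and N(μ, σ²) for
any r. Defaults: σ = 1, r = 0.2.

Observation models: `delayed` makes a cohort's efficacy visible one decision
cycle after its toxicity ("twice as long to evaluate"), with the final
analysis waiting for complete follow-up; `missing_on_toxicity` removes toxic
patients' efficacy permanently. The burden metrics (average toxicity %, mean
efficacy response) always use all generated outcomes so they remain
comparable across observation models; only the estimators see the restricted
data.

What the generator does not emulate: patient heterogeneity beyond the
regimen means, time-to-event structure within a cycle, dropout unrelated to
toxicity, and non-normal efficacy distributions. Passing operating
characteristics therefore demonstrate the design's behaviour under the
stated generating model, not robustness to arbitrary real-world deviations.

Reproducibility: replicate k of a run with master seed s uses
`SeedSequence((s, k))`; a trial consumes two standard normals per patient
and one uniform per patient-allocation draw, so decision logs replay
bit-for-bit and common random numbers across design variants hold by
construction.

## Prior-mean calibration

The prior means act like a CRM skeleton. Candidates are linear profiles
p_j = start_tox + (j−1)·step_tox, μ₀,j = start_eff + (j−1)·step_eff over the
grid start_tox ∈ {0.05, 0.10, 0.15}, step_tox ∈ {0.03, …, 0.10},
start_eff ∈ {−0.80, …, −1.20}, step_eff ∈ {−0.01, −0.025, −0.05, −0.075,
−0.1} (600 sets), or a 15×15 step-only sweep at fixed starts. Candidates
must preserve the clinician's initial ordering — prior plug-in scores
strictly increasing in the regimen index under the configured transform —
and are scored by the geometric mean of correct-selection proportions under
two pivot scenarios with the optimal regimen at opposite ends of the range,
simulated with the safety/futility constraints disabled (coherence and the
start-at-lowest rule remain: they are part of the escalation rule, not of
the constraints). Common random numbers across candidates stabilise the
ranking at moderate replicate counts. The desk-scale sweep uses 500
replicates per candidate; at that depth the per-candidate score noise
(≈0.01) is comparable to the 1.5% near-optimal band, so band membership of
any single candidate is itself a noisy statement — consistent with the
reference finding that >100 parameter sets are statistically
indistinguishable from the optimum.

## Numerical choices

* Plug-in probabilities are clamped to ≥ 10⁻¹² before division; the
  criterion's poles become large finite penalties instead of infinities.
* The logistic map uses `scipy.special.expit`/`ndtr` (no overflow for any
  linear predictor); Beta tails use the regularised incomplete beta
  function.
* Ties in score ranking break by lower posterior toxicity mean, then lower
  regimen index — conservative and deterministic.
* Degenerate inputs: N = 0 terminates immediately; an empty efficacy update
  is the identity; equal anchor bounds and probabilities outside (0, 1) are
  rejected at construction.

## Known limitations

* Operating characteristics are reproduced within Monte-Carlo tolerance for
  the selection surfaces; the correlation-sensitivity *spread* of the
  plateau scenario between r = ±0.8 comes out larger here (~11–13
  percentage points at 10⁴ replicates) than the reference value (~7),
  with matching direction and matching per-arm baselines. The spread is an
  emergent property of the allocation/constraint dynamics and is not
  governed by any stated parameter; we report it as computed.
* The design treats regimens independently; when a reliable toxicity or
  efficacy ordering is known and borrowing is desired, a model-based design
  will be more efficient in small samples.
* The futility rule's normal approximation understates tail mass at very
  small n_e; since η₂ starts at 0.8 the rule cannot bind before data arrive,
  which bounds the practical impact.
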