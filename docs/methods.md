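# Methods

## Scope

`stepmeta` implements stepwise-hierarchical pooled analysis: a procedure for
interpreting meta-analyses that combine randomized controlled trials (RCTs)
and observational studies by pooling within cumulative validity strata and
classifying the cross-stratum trajectory of the pooled effect. It is an
interpretation layer on top of standard frequentist meta-analysis; it does
not attempt GRADE-style certainty rating, network meta-analysis integration,
publication-bias testing, or formal between-stratum interaction tests.

## Effect scales and elementary inference

Ratio measures (HR, OR, RR) are analysed on the natural-log scale, where
Wald intervals are symmetric; difference measures pass through unchanged.
Which ratio measure a study reports is retained only as metadata — the
analysis treats all ratio measures identically. Standard errors are
recovered from reported CIs as `se = (t(upper) − t(lower)) / (2·z_{(1+γ)/2})`
with `t` the analysis-scale transform and γ the confidence level. Inference
is normal (z) throughout rather than t: the per-stage p-values of published
stepwise analyses are reproduced exactly by z inference, and pooled
estimates in this setting conventionally use normal approximations. A
Hartung–Knapp-style small-sample adjustment is deliberately not applied.
p-values render journal-style (three decimals, `<.001` below 0.001).

Published inputs are rounded to three decimals, so a printed CI is symmetric
about the printed point estimate on the log scale only to ~10⁻³; internal
round-trips (estimate → CI → estimate) are exact to 10⁻⁹ relative tolerance
and are property-tested.

## Pooling

Fixed-effect pooling uses inverse-variance weights `w_i = 1/se_i²`.
Random-effects pooling uses the DerSimonian–Laird moment estimator
`τ² = max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`, with re-weighting
`w*_i = 1/(se_i² + τ²)`. DL is the only τ² estimator offered: it is the
simplest defensible default, and the method's output (a trajectory of
pooled points) is insensitive to the finer differences between REML or
Paule–Mandel and DL at typical stratum sizes. Heterogeneity is reported as
Cochran's Q with a χ²(df) p-value and `I² = max(0, (Q − df)/Q)·100`,
truncated at zero. Random effects is the default model for every stratum —
mixed-design strata are heterogeneous by construction — with fixed effect
available by flag. A single-study stratum returns that study's estimate
with τ² = 0 and a `single-study` flag rather than an error.

Heterogeneity statistics are reported alongside each stratum but play no
role in pattern classification: they are narrative support (low
heterogeneity in the upper strata strengthens confidence in the pooled
points), not a classification input.

## Hierarchy and strata

The default hierarchy has three levels. Level 3 admits RCTs whose
randomization and sample size are both adequate; level 2 admits
observational studies balanced by propensity matching, multivariable
adjustment, or an institutional design that distributes prognostic factors
evenly, plus RCTs demoted exactly one level for failing either adequacy
flag (no second demotion step exists); level 1 is everything else.
Adequacy and balance are data columns supplied by the reviewer — the tool
never judges study quality itself.

Strata are **cumulative** by default: stage j pools every study at level
≥ j, so stage 1 is always the complete portfolio and member sets are
nested. This matches the definition of stage 1 as "all studies" and the
admission of RCTs into the balanced stage; an exclusive (partition) mode
exists by flag for sensitivity analysis. Strata smaller than
`min_studies_per_stratum` (default 2) are flagged, not dropped — the tool
surfaces fragility instead of refusing to analyse. Empty strata are omitted
from the trajectory with a recorded warning; at least two non-empty strata
are required.

## Trajectory classification

The trend is measured on |θ| — distance from the null on the analysis
scale — making the classification invariant to inverting the direction of
benefit (a trajectory of ratios and its element-wise reciprocal classify
identically; property-tested). Significance is a per-stage boolean at
α = 0.05. Two choices here are deliberate:

- **"Significance increases gradually" is read as flags, not monotone
  p-values.** The canonical ascending example runs p = .053 → <.001 → .006,
  which is not monotone in p; the only consistent reading is "nonsignificant
  below, significant at the top".
- **A relative dead-band `tol` (default 0.01, i.e. 1% of |θ| per step)
  separates "gradually increases/decreases" from noise.** Steps inside the
  dead-band count as flat; the overall direction is taken from the first
  and last stages, and any interior step contradicting it makes the
  trajectory non-monotone → indeterminate.

Pattern mapping for monotone trajectories is by (direction,
all-significant?, top-significant?): ascending with top significance is P1,
or P2 if every stage is significant; descending is P4 if every stage is
significant, P3 if the top stage is not. A flat, same-direction,
all-significant trajectory is concordant. Two individually significant
strata with opposite-signed θ are contradictory (checked before anything
else). Everything else — including ascending with a nonsignificant top
stage and descending with a significant top but nonsignificant interior —
is indeterminate: the archetypes deliberately do not cover all trajectories,
and the tool does not invent interpretations for the remainder.

Verdicts: P1/P2 → `supported_strengthened`; concordant → `supported`;
P4 → `supported_weakened`; P3 → `rejected`. For contradictory and
indeterminate trajectories the verdict defers to the randomized stratum
alone: `supported` if the top stage is significant, `rejected` otherwise.
This is a design choice — the top stratum carries the decision whenever the
trend carries no signal — and it keeps the classifier total and
single-valued. p-values in [α, 0.10] are annotated "marginally
nonsignificant" in reports but count as nonsignificant, keeping the
classification binary and deterministic.

## Simulator

`generate_portfolio` draws, per study, a true effect
θ_i ~ N(θ_true + b_i, τ²) and an observed effect θ̂_i ~ N(θ_i, se_i²) with
se_i ~ Uniform(se_range). The confounding shift b_i is δ for unbalanced
observational studies, δ·`balanced_bias_fraction` for balanced ones
(default 0.25 — adjustment removes most but not all confounding), and 0 for
RCTs. Additive analysis-scale confounding is the simplest mechanism
consistent with the method's causal story (controlling confounders moves the
observational effect toward the truth); it is not a structural confounding
model. Default portfolio: θ_true = ln 1.5, τ = 0.05, δ = −0.25 (toward the
null), 30 unbalanced + 20 balanced observational studies + 10 RCTs,
se ∈ [0.1, 0.3] — a portfolio shape typical of oncology meta-analyses where
observational studies outnumber trials. Per-study SEs are independent of
design by default; a design-specific range can be emulated by running
groups separately.

What the simulator does *not* emulate: publication bias, survival-level
individual-patient data, correlated estimates from overlapping cohorts, and
non-normal sampling error. Passing Monte-Carlo checks therefore validate
the pipeline's internal logic under its own generative assumptions, not its
behaviour on arbitrary real portfolios.

All randomness derives from the single config seed through
`numpy.random.SeedSequence`; replicates use spawned child sequences, so
results are reproducible bit-for-bit and independent of replicate order.

## Monte-Carlo validation (what the acceptance script computes)

With δ = 0 and τ = 0 the pipeline is unbiased: over 1,000 replicates the
top-stratum pooled θ's mean error is within two Monte-Carlo standard errors
of zero, and all-studies CI coverage sits at the nominal 95% within
Monte-Carlo error. DL coverage in the smaller randomized stratum is
slightly conservative (the τ̂² ≥ 0 truncation widens intervals when the
truth is homogeneous), so its band is checked as [0.93, 0.98]. With δ
pointing toward the null, ascending patterns (P1/P2) dominate the pattern
frequency table; with δ away from the null, descending patterns (P4/P3)
dominate — the sign-coherence the interpretation rules rely on. Problem
sizes (1,000 null replicates, 300 per biased scenario, 1,000
oracle-equivalence instances with k ∈ [2, 12]) keep the whole validation in
the tens of seconds while leaving Monte-Carlo error well below the margins
being tested.

## Numerical notes and degenerate inputs

- Wald p-values use `erfc`, accurate in the far tail where `1 − Φ(|z|)`
  would underflow earlier.
- Q ≤ df ⇒ τ² = 0 and I² = 0 exactly (truncation, never negative).
- θ = 0 gives p = 1 exactly; zero-θ strata carry no direction and cannot
  create a contradiction.
- Pre-pooled stage estimates (classify mode) are wrapped in strata flagged
  `pre-pooled` with unknown k and heterogeneity; text forests print `-`
  for their study counts.
- Duplicate study ids, mixed effect-measure kinds, inverted or non-positive
  ratio CIs, and estimates outside their own CI are rejected with messages
  naming the offending row.

## Known limitations

The four archetypes cannot express every trajectory; the indeterminate
category is a catch-all with no attempted sub-interpretation. Classification
ignores heterogeneity and publication-bias diagnostics, which a full
clinical reading should consult alongside the pattern. The dead-band makes
"flat vs gradual" depend on `tol` near the boundary; `tol` is configurable
and reported in every classification. Verdicts are qualitative labels, not
certainty grades.
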