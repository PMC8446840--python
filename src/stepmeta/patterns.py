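"""Classify cross-stratum effect trajectories and emit interpretations.

The stepwise-hierarchical method reads an ordered sequence of pooled
stratum results (lowest validity first, randomized studies last) and asks
two questions: how does the effect-size *magnitude* move as validity rises,
and which strata are statistically significant?  Four archetypal monotone
patterns plus concordant / contradictory / indeterminate cover the answers:

* **P1** ascending magnitude, significance gained at the top — the
  hypothesis is strongly supported; observational studies under-estimated
  the effect (negative confounding).
* **P2** ascending, significant at every stage — supported, with milder
  confounding than P1.
* **P3** descending, top stratum non-significant — the hypothesis is
  rejected on the randomized evidence.
* **P4** descending yet significant throughout — supported but weakened;
  observational studies over-estimated the effect.

A flat trajectory that is significant everywhere and points one way is
*concordant*; significant strata pointing in opposite directions are
*contradictory*; everything else is *indeterminate*.  For the latter two the
verdict defers to the randomized (top) stratum's significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .effect_models import EffectEstimate
from .pooling import StratumResult

__all__ = [
    "Pattern",
    "DirectionTrend",
    "Verdict",
    "PatternClassification",
    "classify_trajectory",
    "interpret",
]


class Pattern(str, Enum):
    P1_ASCENDING_GAINING_SIGNIFICANCE = "P1_ascending_gaining_significance"
    P2_ASCENDING_ALL_SIGNIFICANT = "P2_ascending_all_significant"
    P3_DESCENDING_LOSING_SIGNIFICANCE = "P3_descending_losing_significance"
    P4_DESCENDING_ALL_SIGNIFICANT = "P4_descending_all_significant"
    CONCORDANT = "concordant"
    CONTRADICTORY = "contradictory"
    INDETERMINATE = "indeterminate"


class DirectionTrend(str, Enum):
    ASCENDING = "ascending"
    DESCENDING = "descending"
    FLAT = "flat"
    NON_MONOTONE = "non_monotone"


class Verdict(str, Enum):
    SUPPORTED_STRENGTHENED = "supported_strengthened"
    SUPPORTED = "supported"
    SUPPORTED_WEAKENED = "supported_weakened"
    REJECTED = "rejected"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PatternClassification:
    """Single-valued classification of one stratum trajectory."""

    pattern: Pattern
    direction_trend: DirectionTrend
    significant_flags: tuple[bool, ...]
    top_significant: bool
    verdict: Verdict
    rationale: str
    alpha: float = 0.05
    tol: float = 0.01
    marginal_flags: tuple[bool, ...] = field(default=())


def _theta_p(item: StratumResult | EffectEstimate) -> tuple[float, float]:
    if isinstance(item, StratumResult):
        return item.pooled.theta, item.pooled.p
    if isinstance(item, EffectEstimate):
        return item.theta, item.p
    raise TypeError(f"cannot classify objects of type {type(item).__name__}")


def _step_direction(m_from: float, m_to: float, tol: float) -> int:
    """-1 / 0 / +1 direction of one magnitude step, with a relative dead-band."""
    base = max(abs(m_from), 1e-12)
    rel = (m_to - m_from) / base
    if rel >= tol:
        return 1
    if rel <= -tol:
        return -1
    return 0


def classify_trajectory(
    strata: Sequence[StratumResult | EffectEstimate],
    alpha: float = 0.05,
    tol: float = 0.01,
) -> PatternClassification:
    """Classify an ordered (lowest→highest validity) stratum trajectory.

    The trend is measured on ``|theta|`` — distance from the null on the
    analysis scale — so the direction of benefit is irrelevant and a ratio
    trajectory classifies identically to its reciprocal.  Steps whose
    relative magnitude change is below ``tol`` count as flat.

    Raises
    ------
    ValueError
        For fewer than two strata, or :class:`StratumResult` inputs whose
        ``level_index`` is not strictly increasing.
    """
    if len(strata) < 2:
        raise ValueError("trajectory classification needs at least 2 strata")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if all(isinstance(s, StratumResult) for s in strata):
        levels = [s.level_index for s in strata]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(
                f"strata must be ordered by strictly increasing validity level, got {levels}"
            )

    thetas, ps = zip(*(_theta_p(s) for s in strata))
    mags = [abs(t) for t in thetas]
    sig = tuple(p < alpha for p in ps)
    marginal = tuple(alpha <= p <= 0.10 for p in ps)
    top_sig = sig[-1]
    all_sig = all(sig)

    # Contradiction: two individually significant strata pointing opposite ways.
    sig_signs = {1 if t > 0 else -1 for t, s in zip(thetas, sig) if s and t != 0}
    contradictory = len(sig_signs) == 2

    steps = [
        _step_direction(a, b, tol) for a, b in zip(mags, mags[1:])
    ]
    overall = _step_direction(mags[0], mags[-1], tol)
    if overall == 0 and all(s == 0 for s in steps):
        trend = DirectionTrend.FLAT
    elif overall != 0 and all(s * overall >= 0 for s in steps):
        trend = DirectionTrend.ASCENDING if overall > 0 else DirectionTrend.DESCENDING
    else:
        trend = DirectionTrend.NON_MONOTONE

    same_sign = len({1 if t > 0 else (-1 if t < 0 else 0) for t in thetas}) == 1

    pattern: Pattern
    if contradictory:
        pattern = Pattern.CONTRADICTORY
        rationale = (
            "Statistically significant strata point in opposite directions; "
            "the randomized and observational evidence contradict each other."
        )
    elif trend is DirectionTrend.FLAT and all_sig and same_sign:
        pattern = Pattern.CONCORDANT
        rationale = (
            "Effect sizes are similar across all stages and every stage is "
            "statistically significant."
        )
    elif trend is DirectionTrend.ASCENDING and top_sig and all_sig:
        pattern = Pattern.P2_ASCENDING_ALL_SIGNIFICANT
        rationale = (
            "Effect-size magnitude rises with validity and every stage is "
            "significant."
        )
    elif trend is DirectionTrend.ASCENDING and top_sig:
        pattern = Pattern.P1_ASCENDING_GAINING_SIGNIFICANCE
        rationale = (
            "Effect-size magnitude rises with validity; significance is "
            "reached at the highest (randomized) stage."
        )
    elif trend is DirectionTrend.DESCENDING and all_sig:
        pattern = Pattern.P4_DESCENDING_ALL_SIGNIFICANT
        rationale = (
            "Effect-size magnitude falls with validity although every stage "
            "remains significant."
        )
    elif trend is DirectionTrend.DESCENDING and not top_sig:
        pattern = Pattern.P3_DESCENDING_LOSING_SIGNIFICANCE
        rationale = (
            "Effect-size magnitude falls with validity and the randomized "
            "stage is not significant."
        )
    else:
        pattern = Pattern.INDETERMINATE
        rationale = (
            f"Trajectory (trend={trend.value}, significance pattern "
            f"{''.join('S' if s else 'n' for s in sig)}) matches none of the "
            "archetypal patterns."
        )

    verdict = _verdict_for(pattern, top_sig)
    if any(marginal):
        which = [i + 1 for i, m in enumerate(marginal) if m]
        rationale += (
            f" Stage(s) {which} are marginally nonsignificant "
            f"(p in [{alpha:g}, 0.10]), counted as nonsignificant."
        )
    return PatternClassification(
        pattern=pattern,
        direction_trend=trend,
        significant_flags=sig,
        top_significant=top_sig,
        verdict=verdict,
        rationale=rationale,
        alpha=alpha,
        tol=tol,
        marginal_flags=marginal,
    )


def _verdict_for(pattern: Pattern, top_significant: bool) -> Verdict:
    if pattern in (
        Pattern.P1_ASCENDING_GAINING_SIGNIFICANCE,
        Pattern.P2_ASCENDING_ALL_SIGNIFICANT,
    ):
        return Verdict.SUPPORTED_STRENGTHENED
    if pattern is Pattern.P4_DESCENDING_ALL_SIGNIFICANT:
        return Verdict.SUPPORTED_WEAKENED
    if pattern is Pattern.P3_DESCENDING_LOSING_SIGNIFICANCE:
        return Verdict.REJECTED
    if pattern is Pattern.CONCORDANT:
        return Verdict.SUPPORTED
    # Contradictory / indeterminate: weight the randomized stratum.
    return Verdict.SUPPORTED if top_significant else Verdict.REJECTED


# Canonical interpretation text, one template per pattern.  The confounding
# diagnosis follows the trend: ascending implies observational studies
# under-estimated the effect, descending implies over-estimation.
INTERPRETATION_TEMPLATES: dict[Pattern, str] = {
    Pattern.P1_ASCENDING_GAINING_SIGNIFICANCE: (
        "Effect size and statistical significance increase gradually with "
        "validity stage. The randomized-stage result is significant, "
        "strengthening support for the hypothesis: it is probably true and "
        "strongly positive. The observational effect size is lower than the "
        "true effect; controlling confounders raises it, and pooled analyses "
        "of confounded observational studies may fail to reach significance."
    ),
    Pattern.P2_ASCENDING_ALL_SIGNIFICANT: (
        "Effect size increases gradually and every stage is statistically "
        "significant. The randomized-stage result is significant and the "
        "ascending pattern strengthens the reliability of the hypothesis: it "
        "is probably true and strongly positive. The observational effect "
        "size is lower than the true effect; confounders act negatively on "
        "the observational results but, since those results remain "
        "significant, less strongly than in the gaining-significance pattern."
    ),
    Pattern.P3_DESCENDING_LOSING_SIGNIFICANCE: (
        "Effect size and statistical significance decrease gradually with "
        "validity stage. The hypothesis is rejected because the "
        "randomized-stage result is not significant. The observational "
        "effect sizes and significance are not trustworthy: observational "
        "studies are likely affected by confounders and researchers' bias, "
        "and their effect size is larger than the true effect."
    ),
    Pattern.P4_DESCENDING_ALL_SIGNIFICANT: (
        "Effect size decreases gradually although every stage is "
        "statistically significant. The hypothesis is judged true on the "
        "randomized-stage result, but the descending pattern lowers its "
        "reliability. The observational effect size is larger than the true "
        "effect; observational studies are likely affected by confounders "
        "and researchers' bias."
    ),
    Pattern.CONCORDANT: (
        "Effect sizes are similar in the pooled analyses of randomized and "
        "observational studies and all are statistically significant: the "
        "hypothesis is true."
    ),
    Pattern.CONTRADICTORY: (
        "The randomized and observational results contradict each other. The "
        "pooled results of the randomized studies should be weighted more "
        "heavily, and the contradiction investigated further; trend-based "
        "interpretation adds little here."
    ),
    Pattern.INDETERMINATE: (
        "The trajectory matches none of the archetypal patterns. The verdict "
        "defers to the randomized (highest-validity) stratum; interpret the "
        "remaining strata qualitatively, alongside heterogeneity and "
        "publication-bias diagnostics."
    ),
}

_CONFOUNDING_DIAGNOSIS = {
    DirectionTrend.ASCENDING: (
        "Confounding diagnosis: the observational effect size is lower than "
        "the true effect (negative confounding; controlling confounders "
        "increases the effect size)."
    ),
    DirectionTrend.DESCENDING: (
        "Confounding diagnosis: the observational effect size and "
        "significance are larger than the true effect (confounders and "
        "researchers' bias inflate the observational results)."
    ),
}


def interpret(classification: PatternClassification) -> dict:
    """Structured interpretation report for a classification.

    Returns a JSON-serialisable dict with the canonical interpretation
    paragraph, the confounding diagnosis where a trend supports one, and the
    verdict.
    """
    parts = [INTERPRETATION_TEMPLATES[classification.pattern]]
    diagnosis = _CONFOUNDING_DIAGNOSIS.get(classification.direction_trend)
    if diagnosis and classification.pattern not in (
        Pattern.CONTRADICTORY,
        Pattern.CONCORDANT,
    ):
        parts.append(diagnosis)
    return {
        "pattern": classification.pattern.value,
        "direction_trend": classification.direction_trend.value,
        "verdict": classification.verdict.value,
        "significant_flags": list(classification.significant_flags),
        "marginally_nonsignificant_flags": list(classification.marginal_flags),
        "top_significant": classification.top_significant,
        "alpha": classification.alpha,
        "tol": classification.tol,
        "rationale": classification.rationale,
        "interpretation": " ".join(parts),
    }
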