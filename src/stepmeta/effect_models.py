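"""Scale handling and elementary inference for single effect estimates.

Meta-analytic effect measures come in two families: ratio measures (hazard,
odds, risk ratios) whose sampling distribution is approximately normal on the
natural-log scale, and difference measures (mean differences) that are already
on an additive scale.  Everything downstream pools on the *analysis scale*
(log for ratios, identity for differences) and back-transforms for display.

The module recovers standard errors from reported confidence intervals,
performs two-sided Wald (z) tests, and bundles the pieces into an immutable
:class:`EffectEstimate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy import stats

__all__ = [
    "MeasureKind",
    "EffectEstimate",
    "se_from_ci",
    "wald_test",
    "make_estimate",
    "estimate_from_theta",
    "format_p",
]

_SQRT2 = math.sqrt(2.0)


class MeasureKind(str, Enum):
    """Effect-measure family, deciding the analysis-scale transform."""

    RATIO = "ratio"
    DIFFERENCE = "difference"

    @classmethod
    def coerce(cls, value: "MeasureKind | str") -> "MeasureKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown measure kind {value!r}; expected 'ratio' or 'difference'"
            ) from None


def _to_analysis(value: float, kind: MeasureKind) -> float:
    if kind is MeasureKind.RATIO:
        if value <= 0:
            raise ValueError(f"ratio-scale value must be positive, got {value}")
        return math.log(value)
    return float(value)


def _to_display(theta: float, kind: MeasureKind) -> float:
    return math.exp(theta) if kind is MeasureKind.RATIO else float(theta)


def _norm_quantile(ci_level: float) -> float:
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    return float(stats.norm.ppf(0.5 * (1.0 + ci_level)))


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with uncertainty, on both display and analysis scales.

    Attributes
    ----------
    measure_kind:
        Ratio or difference measure.
    display_value:
        Effect on the reported scale (e.g. a hazard ratio of 1.44).
    theta:
        Effect on the analysis scale: ``ln(display_value)`` for ratio
        measures, identical for difference measures.
    se:
        Standard error of ``theta`` (analysis scale), strictly positive.
    ci_level:
        Confidence level as a fraction, default 0.95.
    ci_lower, ci_upper:
        Confidence bounds on the *display* scale.
    z, p:
        Two-sided Wald statistic ``theta/se`` and its p-value.
    """

    measure_kind: MeasureKind
    display_value: float
    theta: float
    se: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    z: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")
        if not self.ci_lower < self.display_value < self.ci_upper:
            raise ValueError(
                "point estimate must lie strictly inside its CI: "
                f"{self.ci_lower} < {self.display_value} < {self.ci_upper} fails"
            )
        if self.measure_kind is MeasureKind.RATIO and self.ci_lower <= 0:
            raise ValueError("ratio-measure CI bounds must be positive")

    def display_tuple(self) -> tuple[float, float, float]:
        """(point, lower, upper) on the display scale."""
        return (self.display_value, self.ci_lower, self.ci_upper)


def se_from_ci(
    lower: float,
    upper: float,
    ci_level: float = 0.95,
    measure_kind: MeasureKind | str = MeasureKind.RATIO,
) -> float:
    """Recover the analysis-scale standard error from a reported CI.

    For a symmetric Wald interval the analysis-scale half-width is
    ``q * se`` with ``q`` the standard-normal quantile at ``(1+ci_level)/2``,
    so ``se = (t(upper) - t(lower)) / (2 q)`` where ``t`` is the
    analysis-scale transform.

    Raises
    ------
    ValueError
        If ratio bounds are non-positive, or ``lower >= upper``.
    """
    kind = MeasureKind.coerce(measure_kind)
    if kind is MeasureKind.RATIO and (lower <= 0 or upper <= 0):
        raise ValueError(
            f"ratio-measure CI bounds must be positive, got ({lower}, {upper})"
        )
    if lower >= upper:
        raise ValueError(f"CI bounds must satisfy lower < upper, got ({lower}, {upper})")
    q = _norm_quantile(ci_level)
    return (_to_analysis(upper, kind) - _to_analysis(lower, kind)) / (2.0 * q)


def wald_test(theta: float, se: float) -> tuple[float, float]:
    """Two-sided Wald test of ``theta = 0`` on the analysis scale.

    Returns ``(z, p)`` with ``z = theta/se`` and ``p = 2(1 - Phi(|z|))``,
    computed through :func:`math.erfc` for accuracy in the far tail.
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = theta / se
    p = math.erfc(abs(z) / _SQRT2)
    return z, min(p, 1.0)


def make_estimate(
    display_value: float,
    ci_lower: float,
    ci_upper: float,
    ci_level: float = 0.95,
    measure_kind: MeasureKind | str = MeasureKind.RATIO,
) -> EffectEstimate:
    """Build a fully populated :class:`EffectEstimate` from reported numbers."""
    kind = MeasureKind.coerce(measure_kind)
    if not ci_lower < display_value < ci_upper:
        raise ValueError(
            "point estimate must lie strictly inside its CI: "
            f"({ci_lower}, {display_value}, {ci_upper})"
        )
    theta = _to_analysis(display_value, kind)
    se = se_from_ci(ci_lower, ci_upper, ci_level, kind)
    z, p = wald_test(theta, se)
    return EffectEstimate(
        measure_kind=kind,
        display_value=float(display_value),
        theta=theta,
        se=se,
        ci_level=float(ci_level),
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        z=z,
        p=p,
    )


def estimate_from_theta(
    theta: float,
    se: float,
    ci_level: float = 0.95,
    measure_kind: MeasureKind | str = MeasureKind.RATIO,
) -> EffectEstimate:
    """Build an estimate from analysis-scale quantities (pooled results)."""
    kind = MeasureKind.coerce(measure_kind)
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    q = _norm_quantile(ci_level)
    z, p = wald_test(theta, se)
    return EffectEstimate(
        measure_kind=kind,
        display_value=_to_display(theta, kind),
        theta=float(theta),
        se=float(se),
        ci_level=float(ci_level),
        ci_lower=_to_display(theta - q * se, kind),
        ci_upper=_to_display(theta + q * se, kind),
        z=z,
        p=p,
    )


def format_p(p: float) -> str:
    """Render a p-value the way clinical journals print it.

    Three decimals without a leading zero; values below 0.001 become
    ``"<.001"``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"
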