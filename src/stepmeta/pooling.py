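"""Inverse-variance pooling with heterogeneity statistics.

Two standard models are provided:

* **fixed effect** — one common true effect; study weights are inverse
  sampling variances ``w_i = 1/se_i^2``;
* **random effects (DerSimonian–Laird)** — true effects vary between studies
  with variance ``tau^2`` estimated by the method of moments,
  ``tau^2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``,
  after which studies are re-weighted by ``1/(se_i^2 + tau^2)``.

Heterogeneity is summarised by Cochran's Q, its chi-square p-value, and
``I^2 = max(0, (Q - df)/Q) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_models import EffectEstimate, MeasureKind, estimate_from_theta

__all__ = [
    "PoolingModel",
    "StratumResult",
    "heterogeneity",
    "pool_fixed",
    "pool_random_dl",
    "pool",
]


class PoolingModel(str, Enum):
    FIXED = "fixed"
    RANDOM = "random"


@dataclass(frozen=True)
class StratumResult:
    """Pooled estimate plus heterogeneity statistics for one validity stratum.

    ``level_index`` counts validity levels from 1 (lowest, all studies) up.
    ``flags`` carries non-fatal warnings such as ``"single-study"`` or
    ``"below-min-studies"``.
    """

    label: str
    level_index: int
    k: int
    model: PoolingModel
    pooled: EffectEstimate
    Q: float
    df: int
    p_Q: float
    i_squared: float
    tau_squared: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("a stratum must pool at least one study")
        if self.df != self.k - 1:
            raise ValueError("df must equal k - 1")

    def with_flags(self, *extra: str) -> "StratumResult":
        return replace(self, flags=self.flags + tuple(extra))


def _check_inputs(estimates: Sequence[EffectEstimate]) -> MeasureKind:
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty set of estimates")
    kinds = {e.measure_kind for e in estimates}
    if len(kinds) > 1:
        raise ValueError(f"cannot pool mixed measure kinds: {sorted(k.value for k in kinds)}")
    return next(iter(kinds))


def heterogeneity(
    estimates: Sequence[EffectEstimate],
) -> tuple[float, int, float, float]:
    """Cochran's Q, its degrees of freedom and p-value, and I-squared.

    A single study carries no heterogeneity information: Q = 0, df = 0,
    p_Q = 1, I^2 = 0.
    """
    _check_inputs(estimates)
    k = len(estimates)
    if k == 1:
        return 0.0, 0, 1.0, 0.0
    theta = np.array([e.theta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, i2


def pool_fixed(
    estimates: Sequence[EffectEstimate],
    label: str = "",
    level_index: int = 1,
) -> StratumResult:
    """Fixed-effect (common-effect) inverse-variance pooling."""
    _check_inputs(estimates)
    kind = estimates[0].measure_kind
    theta = np.array([e.theta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled_theta = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q, df, p_q, i2 = heterogeneity(estimates)
    pooled = estimate_from_theta(
        pooled_theta, pooled_se, estimates[0].ci_level, kind
    )
    flags = ("single-study",) if len(estimates) == 1 else ()
    return StratumResult(
        label=label,
        level_index=level_index,
        k=len(estimates),
        model=PoolingModel.FIXED,
        pooled=pooled,
        Q=q,
        df=df,
        p_Q=p_q,
        i_squared=i2,
        tau_squared=0.0,
        flags=flags,
    )


def pool_random_dl(
    estimates: Sequence[EffectEstimate],
    label: str = "",
    level_index: int = 1,
) -> StratumResult:
    """DerSimonian–Laird random-effects pooling.

    With a single study the estimate is returned unchanged (tau^2 = 0) and
    flagged ``"single-study"``.  When the moment estimate of tau^2 truncates
    at zero the result coincides with :func:`pool_fixed`.
    """
    _check_inputs(estimates)
    kind = estimates[0].measure_kind
    k = len(estimates)
    theta = np.array([e.theta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    q, df, p_q, i2 = heterogeneity(estimates)
    if k == 1:
        tau2 = 0.0
        w_star = w
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = np.array([1.0 / (e.se**2 + tau2) for e in estimates])
    pooled_theta = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    pooled = estimate_from_theta(
        pooled_theta, pooled_se, estimates[0].ci_level, kind
    )
    flags = ("single-study",) if k == 1 else ()
    return StratumResult(
        label=label,
        level_index=level_index,
        k=k,
        model=PoolingModel.RANDOM,
        pooled=pooled,
        Q=q,
        df=df,
        p_Q=p_q,
        i_squared=i2,
        tau_squared=tau2,
        flags=flags,
    )


def pool(
    estimates: Sequence[EffectEstimate],
    model: PoolingModel | str = PoolingModel.RANDOM,
    label: str = "",
    level_index: int = 1,
) -> StratumResult:
    """Dispatch to the requested pooling model."""
    model = PoolingModel(model)
    fn = pool_fixed if model is PoolingModel.FIXED else pool_random_dl
    return fn(estimates, label=label, level_index=level_index)
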