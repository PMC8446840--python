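"""Synthetic study portfolios with known truth, for validating the method.

The generative model mirrors the causal story the stepwise-hierarchical
method is built on.  Each study *i* has a true analysis-scale effect

    theta_i ~ Normal(theta_true + b_i, tau^2)

where the confounding shift ``b_i`` is ``delta_obs`` for unbalanced
observational studies, ``delta_obs * balanced_bias_fraction`` for balanced
observational studies (adjustment removes most but not all confounding), and
0 for randomized trials.  The observed effect adds sampling error:

    theta_hat_i ~ Normal(theta_i, se_i^2),   se_i ~ Uniform(se_range)

A ``delta_obs`` whose sign opposes ``theta_true`` biases observational
studies toward the null and should produce ascending patterns; bias away
from the null produces descending patterns.

All randomness flows from the single ``seed`` via
:class:`numpy.random.SeedSequence`; identical configurations reproduce
bit-identical portfolios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effect_models import MeasureKind, estimate_from_theta
from .hierarchy import (
    BalanceMethod,
    Design,
    HierarchySpec,
    StudyRecord,
    run_stepwise,
)
from .patterns import Pattern
from .pooling import PoolingModel

__all__ = [
    "SimulationConfig",
    "OperatingCharacteristics",
    "generate_portfolio",
    "operating_characteristics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic study portfolio.

    Defaults describe a portfolio typical of an oncology meta-analysis mixing
    designs: a moderate protective/beneficial true effect (ratio 1.5 on the
    display scale), mild between-study heterogeneity, confounding that biases
    observational studies toward the null, and many more observational
    studies than randomized trials.
    """

    theta_true: float = float(np.log(1.5))
    tau: float = 0.05
    delta_obs: float = -0.25
    n_rct: int = 10
    n_obs_balanced: int = 20
    n_obs_unbalanced: int = 30
    balanced_bias_fraction: float = 0.25
    se_range: tuple[float, float] = (0.1, 0.3)
    seed: int = 0
    measure_kind: MeasureKind = MeasureKind.RATIO

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError(f"se_range must be positive and ordered, got {self.se_range}")
        counts = (self.n_rct, self.n_obs_balanced, self.n_obs_unbalanced)
        if any(c < 0 for c in counts):
            raise ValueError(f"portfolio counts must be >= 0, got {counts}")
        if sum(counts) < 1:
            raise ValueError("portfolio must contain at least one study")
        if not 0.0 <= self.balanced_bias_fraction <= 1.0:
            raise ValueError(
                f"balanced_bias_fraction must lie in [0, 1], got {self.balanced_bias_fraction}"
            )
        object.__setattr__(self, "measure_kind", MeasureKind.coerce(self.measure_kind))


_GROUPS = (
    # (prefix, design, balance_method, bias multiplier attr)
    ("obs_u", Design.OBSERVATIONAL, BalanceMethod.NONE, 1.0),
    ("obs_b", Design.OBSERVATIONAL, BalanceMethod.PROPENSITY_MATCHING, None),
    ("rct", Design.RANDOMIZED, BalanceMethod.RANDOMIZATION, 0.0),
)


def generate_portfolio(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[StudyRecord]:
    """Draw one synthetic portfolio of :class:`StudyRecord` objects.

    Order is unbalanced observational, balanced observational, randomized;
    downstream results are order-invariant anyway.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = {
        "obs_u": config.n_obs_unbalanced,
        "obs_b": config.n_obs_balanced,
        "rct": config.n_rct,
    }
    records: list[StudyRecord] = []
    for prefix, design, balance, mult in _GROUPS:
        if mult is None:
            mult = config.balanced_bias_fraction
        bias = config.delta_obs * mult
        for i in range(counts[prefix]):
            theta_i = rng.normal(config.theta_true + bias, config.tau)
            se_i = rng.uniform(*config.se_range)
            theta_hat = rng.normal(theta_i, se_i)
            records.append(
                StudyRecord(
                    study_id=f"{prefix}_{i + 1:03d}",
                    design=design,
                    balance_method=balance,
                    estimate=estimate_from_theta(
                        theta_hat, se_i, measure_kind=config.measure_kind
                    ),
                )
            )
    return records


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summary of the pipeline under a known generative truth."""

    config: SimulationConfig
    n_replicates: int
    pattern_counts: dict[str, int]
    #: per stratum label: mean(pooled theta) - theta_true
    bias: dict[str, float]
    #: Monte-Carlo standard error of each bias entry
    bias_mc_se: dict[str, float]
    rmse: dict[str, float]
    #: fraction of replicates whose stratum CI covers theta_true
    coverage: dict[str, float]

    def pattern_fraction(self, *patterns: Pattern | str) -> float:
        wanted = {Pattern(p).value for p in patterns}
        total = sum(self.pattern_counts.values())
        hit = sum(c for p, c in self.pattern_counts.items() if p in wanted)
        return hit / total if total else float("nan")


def operating_characteristics(
    config: SimulationConfig,
    n_replicates: int = 500,
    alpha: float = 0.05,
    spec: HierarchySpec | None = None,
    model: PoolingModel | str = PoolingModel.RANDOM,
    tol: float = 0.01,
) -> OperatingCharacteristics:
    """Run the full pipeline over many replicates and tabulate its behaviour.

    Per replicate: generate a portfolio, run the stepwise analysis, record
    the classified pattern and each stratum's pooled estimate.  Reports
    pattern frequencies and, per stratum, bias / RMSE of the pooled
    analysis-scale effect against ``theta_true`` and empirical CI coverage.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    pattern_counts: dict[str, int] = {}
    errors: dict[str, list[float]] = {}
    covered: dict[str, int] = {}
    seen: dict[str, int] = {}
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        records = generate_portfolio(config, rng=rng)
        result = run_stepwise(records, spec=spec, model=model, alpha=alpha, tol=tol)
        pat = result.classification.pattern.value
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1
        for stratum in result.strata:
            lbl = stratum.label
            errors.setdefault(lbl, []).append(stratum.pooled.theta - config.theta_true)
            seen[lbl] = seen.get(lbl, 0) + 1
            lo, hi = stratum.pooled.ci_lower, stratum.pooled.ci_upper
            if config.measure_kind is MeasureKind.RATIO:
                lo, hi = np.log(lo), np.log(hi)
            if lo <= config.theta_true <= hi:
                covered[lbl] = covered.get(lbl, 0) + 1
    bias = {lbl: float(np.mean(v)) for lbl, v in errors.items()}
    bias_se = {
        lbl: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        for lbl, v in errors.items()
    }
    rmse = {lbl: float(np.sqrt(np.mean(np.square(v)))) for lbl, v in errors.items()}
    coverage = {lbl: covered.get(lbl, 0) / seen[lbl] for lbl in seen}
    return OperatingCharacteristics(
        config=config,
        n_replicates=n_replicates,
        pattern_counts=dict(sorted(pattern_counts.items())),
        bias=bias,
        bias_mc_se=bias_se,
        rmse=rmse,
        coverage=coverage,
    )
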