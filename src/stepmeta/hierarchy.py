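"""Validity-level assignment and the stepwise analysis over cumulative strata.

The default evidence hierarchy has three levels:

1. *All studies* — every included study, balanced or not.
2. *Balanced studies* — observational studies whose major confounders were
   controlled (propensity matching, multivariable adjustment, or an
   institutional design that distributes prognostic factors evenly), plus
   randomized trials demoted one level for a suboptimal design (unreliable
   randomization or inadequate sample size).
3. *Randomized studies* — adequately designed randomized trials.

Strata are cumulative by default: stage *j* pools every study assigned level
*j* or higher, so stage 1 is always the full portfolio and the member sets
are nested.  The per-stage pooled results are then classified as a
trajectory (see :mod:`stepmeta.patterns`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .effect_models import EffectEstimate
from .patterns import PatternClassification, classify_trajectory, interpret
from .pooling import PoolingModel, StratumResult, pool

__all__ = [
    "Design",
    "BalanceMethod",
    "StudyRecord",
    "HierarchySpec",
    "StepwiseResult",
    "default_hierarchy",
    "assign_level",
    "build_strata",
    "run_stepwise",
    "run_prepooled",
]


class Design(str, Enum):
    RANDOMIZED = "randomized"
    OBSERVATIONAL = "observational"


class BalanceMethod(str, Enum):
    RANDOMIZATION = "randomization"
    PROPENSITY_MATCHING = "propensity_matching"
    MULTIVARIABLE_ADJUSTMENT = "multivariable_adjustment"
    INSTITUTIONAL_DESIGN = "institutional_design"
    NONE = "none"
    UNKNOWN = "unknown"


#: Balance methods that qualify an observational study as "balanced".
BALANCED_METHODS = frozenset(
    {
        BalanceMethod.PROPENSITY_MATCHING,
        BalanceMethod.MULTIVARIABLE_ADJUSTMENT,
        BalanceMethod.INSTITUTIONAL_DESIGN,
    }
)


@dataclass(frozen=True)
class StudyRecord:
    """One extracted study: design, balance metadata, and its effect estimate."""

    study_id: str
    design: Design
    balance_method: BalanceMethod
    estimate: EffectEstimate
    randomization_adequate: bool = True
    sample_size_adequate: bool = True
    n: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if (
            self.design is Design.RANDOMIZED
            and self.balance_method is not BalanceMethod.RANDOMIZATION
        ):
            raise ValueError(
                f"randomized study {self.study_id!r} must have "
                "balance_method='randomization'"
            )
        if (
            self.design is Design.OBSERVATIONAL
            and self.balance_method is BalanceMethod.RANDOMIZATION
        ):
            raise ValueError(
                f"observational study {self.study_id!r} cannot claim "
                "randomization as its balance method"
            )


@dataclass(frozen=True)
class HierarchySpec:
    """Validity hierarchy: ordered stage labels (lowest→highest) and options.

    The default three-stage hierarchy is all / balanced / randomized; the
    highest stage admits only adequately designed randomized studies.
    """

    labels: tuple[str, ...] = ("All studies", "Balanced studies", "Randomized studies")
    cumulative: bool = True
    min_studies_per_stratum: int = 2

    def __post_init__(self) -> None:
        if len(self.labels) < 3:
            raise ValueError("a hierarchy needs at least 3 levels")
        if self.min_studies_per_stratum < 1:
            raise ValueError("min_studies_per_stratum must be >= 1")

    @property
    def n_levels(self) -> int:
        return len(self.labels)

    @classmethod
    def from_dict(cls, cfg: dict) -> "HierarchySpec":
        known = {"labels", "cumulative", "min_studies_per_stratum"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown hierarchy config keys: {sorted(unknown)}")
        out = dict(cfg)
        if "labels" in out:
            out["labels"] = tuple(out["labels"])
        return cls(**out)


def default_hierarchy() -> HierarchySpec:
    return HierarchySpec()


@dataclass(frozen=True)
class StepwiseResult:
    """The ordered stratum trajectory, its classification, and the verdict."""

    strata: tuple[StratumResult, ...]
    classification: PatternClassification
    report: dict
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        levels = [s.level_index for s in self.strata]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("strata must be ordered by strictly increasing level")


def assign_level(record: StudyRecord, spec: HierarchySpec | None = None) -> int:
    """Assign a study to a validity level (1 = lowest).

    Default three-level rules: adequately designed randomized trials sit at
    the top; balanced observational studies and demoted randomized trials
    (either adequacy flag false) sit one below; everything else is level 1.
    With more than three configured levels the same rules apply relative to
    the top (extra intermediate levels are reachable only via a custom
    pipeline, which keeps assignment total and deterministic).
    """
    spec = spec or default_hierarchy()
    top = spec.n_levels
    if record.design is Design.RANDOMIZED:
        adequate = record.randomization_adequate and record.sample_size_adequate
        return top if adequate else top - 1
    if record.balance_method in BALANCED_METHODS:
        return top - 1
    return 1


def build_strata(
    records: Sequence[StudyRecord],
    spec: HierarchySpec | None = None,
) -> list[tuple[str, list[str], list[str]]]:
    """Group studies into validity strata.

    Returns one ``(label, member_study_ids, flags)`` triple per stage,
    ordered lowest→highest.  Under the cumulative default, stage *j*
    contains every study with level >= *j*; stage 1 is always the full
    portfolio.  Strata with fewer than ``min_studies_per_stratum`` members
    are flagged, never dropped; an empty top stratum (e.g. no randomized
    trials at all) is flagged ``"empty"``.
    """
    spec = spec or default_hierarchy()
    if len(records) == 0:
        raise ValueError("cannot build strata from an empty study list")
    ids = [r.study_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate study_id values: {dupes}")

    levels = {r.study_id: assign_level(r, spec) for r in records}
    out: list[tuple[str, list[str], list[str]]] = []
    member_sets: list[set[str]] = []
    for j, label in enumerate(spec.labels, start=1):
        if spec.cumulative:
            members = [r.study_id for r in records if levels[r.study_id] >= j]
        else:
            members = [r.study_id for r in records if levels[r.study_id] == j]
        flags: list[str] = []
        if len(members) == 0:
            flags.append("empty")
        elif len(members) < spec.min_studies_per_stratum:
            flags.append("below-min-studies")
        member_sets.append(set(members))
        out.append((label, members, flags))
    if len(set(map(frozenset, member_sets))) == 1:
        for _, _, flags in out:
            flags.append("degenerate-hierarchy")
    return out


def run_stepwise(
    records: Sequence[StudyRecord],
    spec: HierarchySpec | None = None,
    model: PoolingModel | str = PoolingModel.RANDOM,
    alpha: float = 0.05,
    tol: float = 0.01,
) -> StepwiseResult:
    """Run the full stepwise-hierarchical analysis on a study portfolio.

    Pools each stratum, classifies the lowest→highest trajectory, and
    attaches the interpretation report.  Deterministic given inputs and
    configuration.  Empty strata are omitted from the trajectory with a
    recorded warning.
    """
    spec = spec or default_hierarchy()
    strata_members = build_strata(records, spec)
    by_id = {r.study_id: r for r in records}

    warnings: list[str] = []
    results: list[StratumResult] = []
    for level_index, (label, members, flags) in enumerate(strata_members, start=1):
        if not members:
            warnings.append(f"stratum {level_index} ({label!r}) is empty; omitted")
            continue
        estimates = [by_id[sid].estimate for sid in members]
        res = pool(estimates, model=model, label=label, level_index=level_index)
        extra = tuple(f for f in flags if f != "empty")
        if extra:
            res = res.with_flags(*extra)
            warnings.extend(f"stratum {level_index} ({label!r}): {f}" for f in extra)
        results.append(res)

    if len(results) < 2:
        raise ValueError(
            "stepwise analysis needs at least 2 non-empty strata; "
            f"got {len(results)}"
        )
    classification = classify_trajectory(results, alpha=alpha, tol=tol)
    report = interpret(classification)
    return StepwiseResult(
        strata=tuple(results),
        classification=classification,
        report=report,
        warnings=tuple(warnings),
    )


def run_prepooled(
    labels: Sequence[str],
    estimates: Sequence[EffectEstimate],
    alpha: float = 0.05,
    tol: float = 0.01,
) -> StepwiseResult:
    """Classify pre-pooled stratum estimates (classify mode).

    Published stepwise analyses report one pooled (effect, CI) per stage;
    this entry point accepts those directly, ordered lowest→highest
    validity, wrapping each in a ``"pre-pooled"``-flagged stratum whose
    study count and heterogeneity statistics are unknown.
    """
    if len(labels) != len(estimates):
        raise ValueError("labels and estimates must have equal length")
    if len(estimates) < 2:
        raise ValueError("classification needs at least 2 strata")
    strata = tuple(
        StratumResult(
            label=str(lbl),
            level_index=j,
            k=1,
            model=PoolingModel.RANDOM,
            pooled=est,
            Q=0.0,
            df=0,
            p_Q=1.0,
            i_squared=0.0,
            tau_squared=0.0,
            flags=("pre-pooled",),
        )
        for j, (lbl, est) in enumerate(zip(labels, estimates), start=1)
    )
    classification = classify_trajectory(strata, alpha=alpha, tol=tol)
    return StepwiseResult(
        strata=strata,
        classification=classification,
        report=interpret(classification),
        warnings=("strata are pre-pooled inputs; k and heterogeneity unknown",),
    )
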