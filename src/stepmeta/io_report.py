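"""Study-table I/O, analysis reports, and forest plots.

Two CSV input modes exist:

* **study tables** (normal mode) — one row per study with design and balance
  metadata plus an effect estimate; columns ``study_id, design,
  balance_method, estimate`` and either ``ci_lower, ci_upper`` or ``se`` are
  required, with optional ``randomization_adequate, sample_size_adequate,
  measure_kind, ci_level, n, notes``;
* **stratum tables** (classify mode) — one row per *pre-pooled* stratum
  (``label, estimate, ci_lower, ci_upper``), the form in which published
  stepwise analyses report their stage results.

Reports serialise to JSON and round-trip losslessly; forest plots render as
deterministic plain text or as SVG via matplotlib.
"""

from __future__ import annotations

import io
import json
import math
import warnings as _warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _version
from .effect_models import EffectEstimate, MeasureKind, estimate_from_theta, format_p, make_estimate
from .hierarchy import (
    BalanceMethod,
    Design,
    StepwiseResult,
    StudyRecord,
)
from .pooling import StratumResult

__all__ = [
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "read_stratum_table",
    "AnalysisReport",
    "build_report",
    "render_forest",
]


class StudyTableError(ValueError):
    """Schema- or row-level problem in an input table."""


_REQUIRED = ("study_id", "design", "balance_method", "estimate")
_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value, default: bool, column: str, line: int) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return default
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise StudyTableError(f"line {line}: cannot parse boolean {column}={value!r}")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _row_to_record(row: pd.Series, line: int) -> StudyRecord:
    kind = MeasureKind.coerce(row.get("measure_kind", "ratio") or "ratio")
    ci_level = float(row.get("ci_level", 0.95) or 0.95)
    est = float(row["estimate"])
    has_ci = not (_is_missing(row.get("ci_lower")) or _is_missing(row.get("ci_upper")))
    if has_ci:
        lo, hi = float(row["ci_lower"]), float(row["ci_upper"])
        if lo >= hi:
            raise StudyTableError(f"line {line}: ci_lower >= ci_upper ({lo} >= {hi})")
        if not lo < est < hi:
            raise StudyTableError(
                f"line {line}: estimate {est} outside its CI ({lo}, {hi})"
            )
        estimate = make_estimate(est, lo, hi, ci_level, kind)
    elif not _is_missing(row.get("se")):
        theta = math.log(est) if kind is MeasureKind.RATIO else est
        estimate = estimate_from_theta(theta, float(row["se"]), ci_level, kind)
    else:
        raise StudyTableError(
            f"line {line}: need either (ci_lower, ci_upper) or se"
        )
    try:
        design = Design(str(row["design"]).strip().lower())
    except ValueError:
        raise StudyTableError(
            f"line {line}: unknown design {row['design']!r}"
        ) from None
    try:
        balance = BalanceMethod(str(row["balance_method"]).strip().lower())
    except ValueError:
        raise StudyTableError(
            f"line {line}: unknown balance_method {row['balance_method']!r}"
        ) from None
    n_val = row.get("n")
    try:
        return StudyRecord(
            study_id=str(row["study_id"]),
            design=design,
            balance_method=balance,
            estimate=estimate,
            randomization_adequate=_parse_bool(
                row.get("randomization_adequate"), True, "randomization_adequate", line
            ),
            sample_size_adequate=_parse_bool(
                row.get("sample_size_adequate"), True, "sample_size_adequate", line
            ),
            n=None if _is_missing(n_val) else int(n_val),
            notes="" if _is_missing(row.get("notes")) else str(row.get("notes")),
        )
    except ValueError as exc:
        raise StudyTableError(f"line {line}: {exc}") from None


def read_study_table(path: str | Path, on_error: str = "raise") -> list[StudyRecord]:
    """Read and validate a study-level CSV into :class:`StudyRecord` objects.

    ``on_error="raise"`` (default) aborts on the first invalid row, naming
    its line number; ``on_error="skip"`` drops invalid rows with a warning
    and returns the valid remainder.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise StudyTableError(f"{path}: file is empty or has no header") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if not any(c in df.columns for c in ("ci_lower", "se")):
        missing.append("ci_lower/ci_upper or se")
    if missing:
        raise StudyTableError(f"{path}: missing required column(s): {missing}")
    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            records.append(_row_to_record(row, line))
        except StudyTableError as exc:
            if on_error == "raise":
                raise
            _warnings.warn(f"{path}: skipping row — {exc}", stacklevel=2)
    ids = [r.study_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise StudyTableError(f"{path}: duplicate study_id values: {dupes}")
    return records


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records back to the standard study-table CSV schema."""
    rows = []
    for r in records:
        e = r.estimate
        rows.append(
            {
                "study_id": r.study_id,
                "design": r.design.value,
                "balance_method": r.balance_method.value,
                "randomization_adequate": r.randomization_adequate,
                "sample_size_adequate": r.sample_size_adequate,
                "measure_kind": e.measure_kind.value,
                "estimate": e.display_value,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "ci_level": e.ci_level,
                "se": e.se,
                "n": r.n,
                "notes": r.notes,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stratum_table(
    path: str | Path,
) -> tuple[list[str], list[EffectEstimate]]:
    """Read a pre-pooled stratum CSV (classify mode).

    Required columns: ``label, estimate, ci_lower, ci_upper``; optional
    ``measure_kind`` and ``ci_level``.  Rows are taken in file order as
    lowest→highest validity.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise StudyTableError(f"{path}: file is empty or has no header") from None
    missing = [c for c in ("label", "estimate", "ci_lower", "ci_upper") if c not in df.columns]
    if missing:
        raise StudyTableError(f"{path}: missing required column(s): {missing}")
    labels: list[str] = []
    estimates: list[EffectEstimate] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        kind = MeasureKind.coerce(row.get("measure_kind", "ratio") or "ratio")
        ci_level = float(row.get("ci_level", 0.95) or 0.95)
        try:
            estimates.append(
                make_estimate(
                    float(row["estimate"]),
                    float(row["ci_lower"]),
                    float(row["ci_upper"]),
                    ci_level,
                    kind,
                )
            )
        except ValueError as exc:
            raise StudyTableError(f"{path}: line {line}: {exc}") from None
        labels.append(str(row["label"]))
    if len(labels) < 2:
        raise StudyTableError(f"{path}: need at least 2 stratum rows")
    return labels, estimates


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable summary of one stepwise-hierarchical analysis."""

    input_summary: dict
    strata: tuple[dict, ...]
    classification: dict
    warnings: tuple[str, ...]
    provenance: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = list(d["strata"])
        d["warnings"] = list(d["warnings"])
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(
            input_summary=d["input_summary"],
            strata=tuple(d["strata"]),
            classification=d["classification"],
            warnings=tuple(d["warnings"]),
            provenance=d["provenance"],
        )

    @classmethod
    def from_json(cls, s: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(s))


def _stratum_row(s: StratumResult) -> dict:
    e = s.pooled
    return {
        "label": s.label,
        "level_index": s.level_index,
        "k": s.k,
        "model": s.model.value,
        "effect": round(e.display_value, 6),
        "ci_lower": round(e.ci_lower, 6),
        "ci_upper": round(e.ci_upper, 6),
        "ci_level": e.ci_level,
        "p": round(e.p, 6),
        "p_text": format_p(e.p),
        "Q": round(s.Q, 6),
        "df": s.df,
        "p_Q": round(s.p_Q, 6),
        "i_squared": round(s.i_squared, 3),
        "tau_squared": round(s.tau_squared, 8),
        "flags": list(s.flags),
    }


def build_report(
    result: StepwiseResult,
    records: Sequence[StudyRecord] | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Assemble the canonical JSON-serialisable report for a result."""
    summary: dict = {
        "n_strata": len(result.strata),
        "k_per_stratum": {s.label: s.k for s in result.strata},
    }
    if records is not None:
        summary["n_studies"] = len(records)
        summary["by_design"] = {
            d.value: sum(1 for r in records if r.design is d) for d in Design
        }
        summary["by_balance_method"] = {
            b.value: c
            for b in BalanceMethod
            if (c := sum(1 for r in records if r.balance_method is b)) > 0
        }
    prov = {"tool": "stepmeta", "version": _version}
    prov.update(provenance or {})
    return AnalysisReport(
        input_summary=summary,
        strata=tuple(_stratum_row(s) for s in result.strata),
        classification=dict(result.report),
        warnings=tuple(result.warnings),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# forest rendering

_TEXT_WIDTH = 40


def _text_forest(result: StepwiseResult) -> str:
    strata = result.strata
    ratio = strata[0].pooled.measure_kind is MeasureKind.RATIO

    def to_axis(x: float) -> float:
        return math.log(x) if ratio else x

    los = [to_axis(s.pooled.ci_lower) for s in strata]
    his = [to_axis(s.pooled.ci_upper) for s in strata]
    null = 0.0
    amin = min(min(los), null)
    amax = max(max(his), null)
    span = (amax - amin) or 1.0
    amin -= 0.05 * span
    amax += 0.05 * span
    span = amax - amin

    def col(x: float) -> int:
        return round((to_axis(x) - amin) / span * (_TEXT_WIDTH - 1))

    null_col = round((null - amin) / span * (_TEXT_WIDTH - 1))
    lbl_w = max(len(s.label) for s in strata)
    lines = [
        f"{'Stage':<{lbl_w + 9}}  k  {'effect [CI]':<26} p       "
        f"{'axis (' + ('log ' if ratio else '') + 'scale)'}"
    ]
    for s in strata:
        e = s.pooled
        axis = [" "] * _TEXT_WIDTH
        axis[null_col] = "|"
        for c in range(col(e.ci_lower), col(e.ci_upper) + 1):
            axis[c] = "-"
        axis[col(e.ci_lower)] = "["
        axis[col(e.ci_upper)] = "]"
        axis[col(e.display_value)] = "◆"
        ci = f"{e.display_value:.3f} [{e.ci_lower:.3f}, {e.ci_upper:.3f}]"
        k_text = "-" if "pre-pooled" in s.flags else str(s.k)
        lines.append(
            f"Stage {s.level_index}: {s.label:<{lbl_w}} {k_text:>3}  {ci:<26} "
            f"{format_p(e.p):<7} {''.join(axis)}"
        )
    cls = result.classification
    lines.append("")
    lines.append(
        f"Trend: {cls.direction_trend.value}  Pattern: {cls.pattern.value}  "
        f"Verdict: {cls.verdict.value}"
    )
    if len(strata) == 1 or any("single-study" in s.flags for s in strata):
        lines.append("Warning: stratum with a single study; interpret with caution.")
    for w in result.warnings:
        lines.append(f"Warning: {w}")
    return "\n".join(lines) + "\n"


def _svg_forest(result: StepwiseResult) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    strata = result.strata
    ratio = strata[0].pooled.measure_kind is MeasureKind.RATIO
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.8 * len(strata)))
    ys = list(range(len(strata), 0, -1))
    for y, s in zip(ys, strata):
        e = s.pooled
        ax.plot([e.ci_lower, e.ci_upper], [y, y], color="black", lw=1.2)
        ax.plot(
            [e.display_value], [y], marker="D", color="darkred", markersize=7
        )
        ax.annotate(
            f"{e.display_value:.3f} [{e.ci_lower:.3f}, {e.ci_upper:.3f}]  "
            f"p={format_p(e.p)}  k={s.k}",
            (e.ci_upper, y),
            textcoords="offset points",
            xytext=(8, -3),
            fontsize=8,
        )
    ax.axvline(1.0 if ratio else 0.0, color="grey", ls="--", lw=0.8)
    if ratio:
        ax.set_xscale("log")
        ax.set_xlabel("effect size (ratio, log axis)")
    else:
        ax.set_xlabel("effect size (difference)")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"Stage {s.level_index}: {s.label}" for s in strata])
    ax.set_ylim(0.4, len(strata) + 0.6)
    cls = result.classification
    ax.set_title(
        f"Stepwise-hierarchical analysis — {cls.pattern.value} "
        f"({cls.direction_trend.value})",
        fontsize=10,
    )
    fig.tight_layout()
    buf = io.StringIO()
    fig.savefig(buf, format="svg")
    plt.close(fig)
    return buf.getvalue()


def render_forest(result: StepwiseResult, format: str = "text") -> str:
    """Render a per-stratum forest plot as ``"text"`` or ``"svg"``.

    The text renderer is deterministic byte-for-byte for a fixed result:
    point markers and CI whiskers per stratum on a shared axis (log scale
    for ratio measures), lowest validity stage first.
    """
    if format == "text":
        return _text_forest(result)
    if format == "svg":
        return _svg_forest(result)
    raise ValueError(f"unknown forest format {format!r}; use 'text' or 'svg'")
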