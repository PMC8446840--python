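"""Packaged worked examples.

Two published stepwise-hierarchical meta-analyses ship as pre-pooled
stratum tables (per-stage effect size and 95% CI, ratio measures):

* ``gastric_adjuvant_crt`` — disease-free-survival benefit of adjuvant
  radiochemotherapy versus chemotherapy after D2 gastrectomy for gastric
  cancer; the archetypal *ascending* example.
* ``oligometastases_lct`` — overall-survival benefit of local consolidative
  treatment for oligometastatic disease; the archetypal *descending*
  example.

Only stage-level pooled results are available (the underlying study-level
extractions were not republished), so these load in classify mode.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .effect_models import EffectEstimate
from .io_report import read_stratum_table

__all__ = ["available", "example_path", "load_example"]

_EXAMPLES = {
    "gastric_adjuvant_crt": "gastric_adjuvant_crt_strata.csv",
    "oligometastases_lct": "oligometastases_lct_strata.csv",
}


def available() -> list[str]:
    """Names of the packaged worked examples."""
    return sorted(_EXAMPLES)


def example_path(name: str) -> Path:
    if name not in _EXAMPLES:
        raise KeyError(f"unknown example {name!r}; available: {available()}")
    return Path(resources.files("stepmeta.data") / _EXAMPLES[name])


def load_example(name: str) -> tuple[list[str], list[EffectEstimate]]:
    """Load a packaged example as (stage labels, pre-pooled estimates)."""
    return read_stratum_table(example_path(name))
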