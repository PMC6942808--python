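"""Packaged reference tables.

Three small tables ship with the package as plain-text data files:

* the second-round Delphi per-item statistics (47 items: mean score,
  coefficient of variation, full-mark rate) together with the printed
  summary rows (mean, sd, thresholds),
* the core-symptom -> phenotype-term (HPO) mapping, including the symptoms
  with no ontology counterpart (tongue/fur and pulse findings),
* the cohort 2x2 contingency counts for gender and age group.

These are inputs for reproduction tests and worked examples; everything
else the pipeline consumes is produced by :mod:`ghrspipe.simulate`.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .delphi import ThresholdSet

__all__ = [
    "load_delphi_items",
    "load_delphi_summary",
    "load_symptom_term_map",
    "load_cohort_contingency",
    "load_paper_fixtures",
]

_DATA = resources.files("ghrspipe") / "data"


def _read_text(name: str) -> str:
    path = _DATA / name
    try:
        return path.read_text()
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover - corrupt install
        raise IOError(f"packaged fixture {name!r} is missing or unreadable") from exc


def load_delphi_items() -> pd.DataFrame:
    """47-item statistics table with a ``deleted`` flag column."""
    import io

    frame = pd.read_csv(io.StringIO(_read_text("delphi_round2_items.csv")))
    frame = frame.set_index("item")
    frame["deleted"] = frame["deleted"].astype(bool)
    return frame


def load_delphi_summary() -> dict:
    """Printed summary rows (mean, sd) and the printed threshold row.

    The threshold row is returned both raw and as a :class:`ThresholdSet`
    under the key ``"thresholds"``.
    """
    summary = json.loads(_read_text("delphi_round2_summary.json"))
    t = summary["threshold"]
    summary["thresholds"] = ThresholdSet(
        score_min=t["score_min"], cv_max=t["cv_max"], fullmark_min=t["fullmark_min"]
    )
    return summary


def load_symptom_term_map() -> dict[str, list[str]]:
    """Core symptom -> list of phenotype-term IDs; empty list = no counterpart."""
    mapping: dict[str, list[str]] = {}
    text = _read_text("core_symptom_hpo_terms.tsv")
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        symptom = parts[0]
        terms = [t for t in parts[1].split(",")] if len(parts) > 1 and parts[1] else []
        mapping[symptom] = terms
    return mapping


def load_cohort_contingency() -> dict:
    """2x2 gender and age-group counts of the positive/negative groups."""
    return json.loads(_read_text("cohort_contingency.json"))


def load_paper_fixtures() -> tuple[pd.DataFrame, dict[str, list[str]], dict]:
    """All three packaged tables: (item stats, symptom-term map, contingency)."""
    return load_delphi_items(), load_symptom_term_map(), load_cohort_contingency()
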