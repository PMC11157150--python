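"""Behaviour vocabularies and the 12-to-5 consolidation used for analysis.

Collar bursts are labelled with one of twelve ethogram behaviours from
direct observation.  For the heat-response analysis these are consolidated
into five major categories: foraging is folded into walking (both are slow
locomotion with head movement), sleeping and low-activity become resting,
and five rare behaviours (drinking, salt-licking, grooming, trotting,
running — together only a few percent of records) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: The twelve observable ethogram behaviours.
ETHOGRAM_LABELS: tuple[str, ...] = (
    "browsing",
    "drinking",
    "foraging",
    "grazing",
    "grooming",
    "low-activity",
    "ruminating",
    "running",
    "salt-licking",
    "sleeping",
    "trotting",
    "walking",
)

#: The five analysis categories after consolidation.
ANALYSIS_CATEGORIES: tuple[str, ...] = (
    "browsing",
    "grazing",
    "walking",
    "ruminating",
    "resting",
)

#: Sentinel for behaviours dropped from the analysis.
EXCLUDED = "EXCLUDED"

#: Total map from ethogram label to analysis category (or EXCLUDED).
CONSOLIDATION_MAP: dict[str, str] = {
    "browsing": "browsing",
    "grazing": "grazing",
    "foraging": "walking",
    "walking": "walking",
    "ruminating": "ruminating",
    "low-activity": "resting",
    "sleeping": "resting",
    "drinking": EXCLUDED,
    "salt-licking": EXCLUDED,
    "grooming": EXCLUDED,
    "trotting": EXCLUDED,
    "running": EXCLUDED,
}


def consolidate(label: str) -> str:
    """Map one ethogram label to its analysis category (or ``EXCLUDED``).

    Idempotent on the five analysis categories (each is a fixed point);
    raises ``KeyError`` for anything outside either vocabulary.
    """
    if label in CONSOLIDATION_MAP:
        return CONSOLIDATION_MAP[label]
    if label in ANALYSIS_CATEGORIES:
        return label
    raise KeyError(
        f"unknown behaviour label {label!r}; expected one of {ETHOGRAM_LABELS}"
    )


@dataclass(frozen=True)
class ConsolidationReport:
    """Outcome of consolidating a set of predicted behaviour records."""

    n_input: int
    n_excluded: int

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n_input if self.n_input else 0.0


def consolidate_records(
    records: pd.DataFrame, label_col: str = "behaviour", category_col: str = "category"
) -> tuple[pd.DataFrame, ConsolidationReport]:
    """Consolidate predicted behaviour records, dropping excluded ones.

    ``records`` needs a ``label_col`` column of ethogram labels.  Returns a
    copy with an added ``category_col`` restricted to the five analysis
    categories, plus a report of how many records were excluded.
    """
    unknown = set(records[label_col].unique()) - set(CONSOLIDATION_MAP)
    if unknown:
        raise KeyError(f"unknown behaviour labels: {sorted(unknown)}")
    out = records.copy()
    out[category_col] = out[label_col].map(CONSOLIDATION_MAP)
    keep = out[category_col] != EXCLUDED
    report = ConsolidationReport(n_input=len(out), n_excluded=int((~keep).sum()))
    return out.loc[keep].reset_index(drop=True), report


def write_consolidation_map(path) -> None:
    """Emit the consolidation map as a two-column text table for audit."""
    pd.DataFrame(
        {"ethogram_label": list(CONSOLIDATION_MAP), "category": list(CONSOLIDATION_MAP.values())}
    ).to_csv(path, index=False)
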