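"""Cross-cohort overlap and concordance of screen candidates.

Two cohorts (e.g. young and aged animals) are compared on their dysregulated
candidate sets: the overlap is the set of proteins called up or down in BOTH
cohorts — "unchanged" and "insufficient" exclude a protein — and each
overlapping protein is classified as concordantly up, concordantly down, or
reversed. Matching is by protein-group identifier only; gene symbols are
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from bonlac.screen import CandidateCall

__all__ = ["ConcordanceResult", "ConcordanceError", "concordance_table"]

CONCORDANCE_CATEGORIES = ("both_up", "both_down", "reversed")


class ConcordanceError(ValueError):
    """Invalid cross-cohort comparison input."""


@dataclass(frozen=True)
class ConcordanceEntry:
    protein_id: str
    class_a: str
    class_b: str
    concordance: str


@dataclass(frozen=True)
class ConcordanceResult:
    """Overlap of two cohorts' candidate sets with per-protein concordance."""

    entries: tuple[ConcordanceEntry, ...]
    n_candidates_a: int
    n_candidates_b: int

    @property
    def overlap_size(self) -> int:
        return len(self.entries)

    @property
    def overlap_ids(self) -> list[str]:
        return [e.protein_id for e in self.entries]

    def count(self, category: str) -> int:
        if category not in CONCORDANCE_CATEGORIES:
            raise ConcordanceError(f"unknown concordance category {category!r}")
        return sum(e.concordance == category for e in self.entries)

    @property
    def counts(self) -> dict[str, int]:
        return {cat: self.count(cat) for cat in CONCORDANCE_CATEGORIES}

    def format_counts(self) -> dict[str, str]:
        """Counts in the 'k/overlap' reporting style (e.g. '11/31')."""
        n = self.overlap_size
        return {cat: f"{self.count(cat)}/{n}" for cat in CONCORDANCE_CATEGORIES}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "class_a": e.class_a,
                    "class_b": e.class_b,
                    "concordance": e.concordance,
                }
                for e in self.entries
            ]
        )


def _candidate_classes(calls: Iterable[CandidateCall], label: str) -> dict[str, str]:
    classes: dict[str, str] = {}
    for call in calls:
        if call.protein_id in classes:
            raise ConcordanceError(
                f"duplicate protein id {call.protein_id!r} in cohort {label}"
            )
        classes[call.protein_id] = call.klass
    return {pid: k for pid, k in classes.items() if k in ("up", "down")}


def concordance_table(
    calls_a: Iterable[CandidateCall], calls_b: Iterable[CandidateCall]
) -> ConcordanceResult:
    """Overlap and concordance of the dysregulated sets of two cohorts.

    ``both_up``/``both_down`` count proteins shifted in the same direction in
    both cohorts; ``reversed`` counts opposite shifts. The three categories
    partition the overlap.
    """
    cand_a = _candidate_classes(calls_a, "a")
    cand_b = _candidate_classes(calls_b, "b")
    entries = []
    for pid in sorted(set(cand_a) & set(cand_b)):
        ka, kb = cand_a[pid], cand_b[pid]
        if ka == kb:
            concordance = "both_up" if ka == "up" else "both_down"
        else:
            concordance = "reversed"
        entries.append(ConcordanceEntry(pid, ka, kb, concordance))
    return ConcordanceResult(
        entries=tuple(entries),
        n_candidates_a=len(cand_a),
        n_candidates_b=len(cand_b),
    )
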