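"""The coincidence-detection ("C-score") candidate screen.

A protein is a candidate only if three replicate-level filters coincide:

1. **majority detection** — a ratio is quantified in strictly more than half
   of the replicates (3 of 5, 4 of 7), configurable via ``min_detected``;
2. **average fold-change threshold** — the mean oriented ratio over the
   detected replicates is at or beyond a ±20% band (≥1.2 up, ≤0.8 down);
3. **direction consistency** — a strict majority of the detected replicates
   shift in the called direction (ratios exactly 1 count toward neither).

Proteins passing filter 1 but not 2+3 are "unchanged"; proteins failing
filter 1 are "insufficient" and excluded from the screened denominator.
No multiple-testing correction is applied; the filters are the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from bonlac.ratio_io import RatioTable

__all__ = [
    "ScreenConfig",
    "CandidateCall",
    "ScreenSummary",
    "ScreenError",
    "classify_protein",
    "run_screen",
    "summarize_screen",
    "calls_to_frame",
    "majority_of",
]

CLASSES = ("up", "down", "unchanged", "insufficient")


class ScreenError(ValueError):
    """Invalid screen configuration or input."""


def majority_of(n_replicates: int) -> int:
    """Strictly more than half: 3 of 5, 4 of 7."""
    return n_replicates // 2 + 1


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and rules of the candidate screen.

    ``min_detected="auto"`` applies the strict-majority rule to the cohort's
    replicate count; an integer fixes the detection floor explicitly (e.g. 5
    to require ≥5/7).  ``mean_type`` selects how replicate ratios are
    averaged; the arithmetic mean mirrors the original procedure, the
    geometric mean is the symmetric alternative on the log scale.
    """

    fc_up_threshold: float = 1.2
    fc_down_threshold: float = 0.8
    min_detected: int | Literal["auto"] = "auto"
    mean_type: Literal["arithmetic", "geometric"] = "arithmetic"

    def __post_init__(self) -> None:
        if not (self.fc_down_threshold < 1.0 < self.fc_up_threshold):
            raise ScreenError(
                "thresholds must satisfy fc_down < 1 < fc_up, got "
                f"{self.fc_down_threshold} / {self.fc_up_threshold}"
            )
        if self.min_detected != "auto" and int(self.min_detected) < 1:
            raise ScreenError("min_detected must be >= 1")
        if self.mean_type not in ("arithmetic", "geometric"):
            raise ScreenError(f"unknown mean_type {self.mean_type!r}")

    def detection_floor(self, n_replicates: int) -> int:
        if self.min_detected == "auto":
            return majority_of(n_replicates)
        return int(self.min_detected)


@dataclass(frozen=True)
class CandidateCall:
    """Screen classification of one protein."""

    protein_id: str
    n_detected: int
    mean_ratio: float
    n_up: int
    n_down: int
    klass: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ScreenError(f"unknown class {self.klass!r}")

    @property
    def is_candidate(self) -> bool:
        return self.klass in ("up", "down")


@dataclass(frozen=True)
class ScreenSummary:
    """Cohort-level counts and percentages over the screened proteins.

    Percentages are fractions of ``n_detected_majority`` (the proteins that
    met the detection filter), rounded half-up to one decimal.
    """

    n_total: int
    n_detected_majority: int
    n_up: int
    n_down: int
    n_unchanged: int
    pct_up: float
    pct_down: float
    pct_unchanged: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_ratio(values: np.ndarray, mean_type: str) -> float:
    if mean_type == "geometric":
        return float(np.exp(np.mean(np.log(values))))
    return float(np.mean(values))


def pct_of(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    frac = Decimal(count) * Decimal(100) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_protein(
    ratios: Sequence[float] | np.ndarray,
    n_replicates: int,
    config: ScreenConfig = ScreenConfig(),
    protein_id: str = "",
    gene: str = "",
) -> CandidateCall:
    """Apply the three screen filters to one protein's replicate ratios.

    ``ratios`` has one entry per replicate with NaN/None marking missing
    quantifications.  Ratios must be oriented (affected/control) and
    strictly positive.
    """
    arr = np.asarray([np.nan if r is None else r for r in ratios], dtype=float)
    if arr.shape != (n_replicates,):
        raise ScreenError(f"expected {n_replicates} ratios, got {arr.shape[0]}")
    present = arr[~np.isnan(arr)]
    if np.any(present <= 0) or np.any(np.isinf(present)):
        raise ScreenError(f"ratios must be positive and finite, got {present}")

    n_detected = int(present.size)
    n_up = int(np.sum(present > 1.0))
    n_down = int(np.sum(present < 1.0))

    if n_detected < config.detection_floor(n_replicates):
        return CandidateCall(
            protein_id, n_detected, float("nan"), n_up, n_down, "insufficient", gene
        )

    mean_ratio = _mean_ratio(present, config.mean_type)
    if mean_ratio >= config.fc_up_threshold and n_up > n_down:
        klass = "up"
    elif mean_ratio <= config.fc_down_threshold and n_down > n_up:
        klass = "down"
    else:
        klass = "unchanged"
    return CandidateCall(protein_id, n_detected, mean_ratio, n_up, n_down, klass, gene)


def run_screen(
    table: RatioTable, config: ScreenConfig = ScreenConfig()
) -> list[CandidateCall]:
    """Classify every protein in an oriented ratio table.

    Returns one call per protein in stable protein-id order; an empty table
    yields an empty list.
    """
    if not table.oriented:
        raise ScreenError("ratio table must be oriented before screening")
    n = table.n_replicates
    calls = []
    for pid in sorted(table.protein_ids):
        calls.append(
            classify_protein(
                table.ratios_of(pid),
                n,
                config,
                protein_id=pid,
                gene=str(table.genes.loc[pid]),
            )
        )
    return calls


def summarize_screen(calls: Iterable[CandidateCall]) -> ScreenSummary:
    """Cohort-level counts and one-decimal percentages of the screened set."""
    calls = list(calls)
    n_total = len(calls)
    screened = [c for c in calls if c.klass != "insufficient"]
    n_maj = len(screened)
    n_up = sum(c.klass == "up" for c in screened)
    n_down = sum(c.klass == "down" for c in screened)
    n_unchanged = n_maj - n_up - n_down
    return ScreenSummary(
        n_total=n_total,
        n_detected_majority=n_maj,
        n_up=n_up,
        n_down=n_down,
        n_unchanged=n_unchanged,
        pct_up=pct_of(n_up, n_maj),
        pct_down=pct_of(n_down, n_maj),
        pct_unchanged=pct_of(n_unchanged, n_maj),
    )


def calls_from_tsv(path) -> list[CandidateCall]:
    """Read back a per-protein calls TSV written from :func:`calls_to_frame`."""
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateCall(
            protein_id=str(rec["protein_id"]),
            n_detected=int(rec["n_detected"]),
            mean_ratio=float(rec["mean_ratio"]),
            n_up=int(rec["n_up"]),
            n_down=int(rec["n_down"]),
            klass=str(rec["class"]),
            gene="" if pd.isna(rec.get("gene")) else str(rec.get("gene", "")),
        )
        for rec in df.to_dict("records")
    ]


def calls_to_frame(calls: Iterable[CandidateCall]) -> pd.DataFrame:
    """Tabular view of screen calls (one row per protein)."""
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "gene": c.gene,
                "n_detected": c.n_detected,
                "mean_ratio": c.mean_ratio,
                "n_up": c.n_up,
                "n_down": c.n_down,
                "class": c.klass,
            }
            for c in calls
        ]
    )
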