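"""Synthetic BONLAC experiments and western blots with known ground truth.

The generator emulates the statistical structure of a pulsed-SILAC de novo
proteome comparison between an affected genotype and wild-type controls:

* a minority of proteins carry a true fold change (up or down), the rest
  are null;
* each replicate's oriented ratio is the true fold change under
  multiplicative log-normal noise, split evenly between the two isotope
  channels;
* isotope labels alternate between replicates (label swap), so raw H/M
  ratios of swapped replicates are emitted inverted;
* quantification failures are missing-not-at-random: each channel drops out
  with a probability that is logistic in its realized latent log-abundance,
  and a globally reduced synthesis rate in the affected genotype
  (``global_synthesis_scale`` < 1) shifts that genotype's channel toward
  dropout. A ratio is missing if either channel drops out — the mechanism
  by which globally suppressed synthesis inflates apparent upregulation
  among surviving ratios.

Defaults describe the young-cohort design: 5 replicates, ~4% true up and
~6% true down at ±60%/−37.5% effects, 0.25 log2 replicate noise, and a 20%
global synthesis reduction in the affected genotype.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from bonlac.ratio_io import (
    LabelDesign,
    RatioTable,
    ReplicateDesign,
    orient_ratios,
)

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_blot",
    "write_maxquant_fixture",
    "FixtureError",
]

LOG10_2 = math.log10(2.0)


class SimConfigError(ValueError):
    """Non-finite, non-positive, or mutually inconsistent simulation parameters."""


class FixtureError(ValueError):
    """Fixture writing failed preconditions."""


def _alternating_swaps(n: int) -> tuple[bool, ...]:
    return tuple(i % 2 == 1 for i in range(n))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated BONLAC experiment.

    ``swap_pattern`` lists one flag per replicate (True = labels swapped);
    the default alternates, matching how label assignment is rotated across
    biological replicates. ``dropout_midpoint``/``dropout_slope`` place the
    logistic missingness curve on the log10 latent-abundance axis; set
    ``dropout=False`` to disable missingness entirely.
    """

    n_proteins: int = 2000
    n_replicates: int = 5
    frac_up: float = 0.04
    frac_down: float = 0.06
    effect_fc_up: float = 1.6
    effect_fc_down: float = 0.625
    noise_sd_log2: float = 0.25
    base_abundance_log10_mean: float = 7.0
    base_abundance_log10_sd: float = 1.0
    global_synthesis_scale: float = 0.8
    dropout: bool = True
    dropout_midpoint: float = 6.0
    dropout_slope: float = 2.0
    swap_pattern: tuple[bool, ...] | None = None
    cohort: str = "young"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swap_pattern is None:
            object.__setattr__(self, "swap_pattern", _alternating_swaps(self.n_replicates))
        else:
            object.__setattr__(self, "swap_pattern", tuple(bool(s) for s in self.swap_pattern))
        self.validate()

    def validate(self) -> None:
        for name in (
            "frac_up",
            "frac_down",
            "effect_fc_up",
            "effect_fc_down",
            "noise_sd_log2",
            "base_abundance_log10_mean",
            "base_abundance_log10_sd",
            "global_synthesis_scale",
            "dropout_midpoint",
            "dropout_slope",
        ):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise SimConfigError(f"{name} must be finite, got {v!r}")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise SimConfigError("n_proteins and n_replicates must be >= 1")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise SimConfigError("frac_up and frac_down must be in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise SimConfigError("frac_up + frac_down must be <= 1")
        if not (self.effect_fc_down < 1.0 < self.effect_fc_up):
            raise SimConfigError("effects must satisfy effect_fc_down < 1 < effect_fc_up")
        if self.effect_fc_down <= 0:
            raise SimConfigError("effect_fc_down must be positive")
        if self.noise_sd_log2 < 0:
            raise SimConfigError("noise_sd_log2 must be >= 0")
        if self.base_abundance_log10_sd < 0:
            raise SimConfigError("base_abundance_log10_sd must be >= 0")
        if not (0 < self.global_synthesis_scale <= 1):
            raise SimConfigError("global_synthesis_scale must be in (0, 1]")
        if self.dropout and self.dropout_slope <= 0:
            raise SimConfigError("dropout_slope must be positive")
        if len(self.swap_pattern) != self.n_replicates:
            raise SimConfigError("swap_pattern length must equal n_replicates")

    def label_design(self) -> LabelDesign:
        return LabelDesign(
            tuple(
                ReplicateDesign(
                    replicate_id=f"rep{i + 1}",
                    orientation="swapped" if swapped else "forward",
                    cohort=self.cohort,
                )
                for i, swapped in enumerate(self.swap_pattern)
            )
        )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["swap_pattern"] = list(self.swap_pattern)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("swap_pattern") is not None:
            doc["swap_pattern"] = tuple(doc["swap_pattern"])
        return cls(**doc)


@dataclass(frozen=True)
class SimulatedExperiment:
    """Raw (swap-encoded) ratio table, its label design, and the ground truth."""

    raw: RatioTable
    design: LabelDesign
    truth: pd.DataFrame  # protein_id index; true_class, true_fc

    @property
    def oriented(self) -> RatioTable:
        return orient_ratios(self.raw, self.design)


def _dropout_probability(log10_abundance: np.ndarray, config: SimConfig) -> np.ndarray:
    # logistic decreasing in abundance: p = 1 / (1 + exp(slope * (logA - mid)))
    z = config.dropout_slope * (log10_abundance - config.dropout_midpoint)
    return 1.0 / (1.0 + np.exp(z))


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate one BONLAC-like experiment with known ground truth.

    Reproducible: the same config (including seed) yields byte-identical
    tables. Randomness is drawn from per-protein sub-streams spawned from
    one experiment-level seed sequence, so per-protein draws are stable
    under changes to unrelated proteins' parameters.
    """
    config.validate()
    n, r = config.n_proteins, config.n_replicates
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n + 1)
    rng0 = np.random.default_rng(children[0])

    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    order = rng0.permutation(n)
    classes = np.array(["null"] * n, dtype=object)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"
    fold_changes = np.where(
        classes == "up",
        config.effect_fc_up,
        np.where(classes == "down", config.effect_fc_down, 1.0),
    )
    base_log10 = rng0.normal(
        config.base_abundance_log10_mean, config.base_abundance_log10_sd, size=n
    )

    ids = [f"P{i + 1:05d}" for i in range(n)]
    swapped = np.asarray(config.swap_pattern, dtype=bool)
    channel_sd = config.noise_sd_log2 / math.sqrt(2.0)

    raw = np.full((n, r), np.nan)
    for i in range(n):
        rng = np.random.default_rng(children[i + 1])
        eps_affected = rng.normal(0.0, channel_sd, size=r) if channel_sd > 0 else np.zeros(r)
        eps_control = rng.normal(0.0, channel_sd, size=r) if channel_sd > 0 else np.zeros(r)
        oriented = fold_changes[i] * 2.0 ** (eps_affected - eps_control)
        keep = np.ones(r, dtype=bool)
        if config.dropout:
            log_control = base_log10[i] + eps_control * LOG10_2
            log_affected = (
                base_log10[i]
                + math.log10(config.global_synthesis_scale)
                + math.log10(fold_changes[i])
                + eps_affected * LOG10_2
            )
            u = rng.uniform(size=(2, r))
            keep = (u[0] >= _dropout_probability(log_affected, config)) & (
                u[1] >= _dropout_probability(log_control, config)
            )
        row = np.where(swapped, 1.0 / oriented, oriented)
        raw[i] = np.where(keep, row, np.nan)

    data = pd.DataFrame(
        raw,
        index=pd.Index(ids, name="protein_id"),
        columns=[f"rep{j + 1}" for j in range(r)],
    )
    genes = pd.Series([f"Gene{i + 1}" for i in range(n)], index=data.index, name="gene")
    truth = pd.DataFrame(
        {"true_class": classes, "true_fc": fold_changes},
        index=pd.Index(ids, name="protein_id"),
    )
    table = RatioTable(data=data, genes=genes, oriented=False, cohort=config.cohort)
    return SimulatedExperiment(raw=table, design=config.label_design(), truth=truth)


def simulate_blot(
    n_wt: int,
    n_tg: int,
    true_ratio: float,
    noise_sd: float,
    seed: int = 0,
    blot_id: str = "blot1",
) -> pd.DataFrame:
    """Generate one western blot's band and total-protein densities.

    Normalized relative densities are Gaussian around 1 (WT) and
    ``true_ratio`` (TG) with standard deviation ``noise_sd``, so as
    ``noise_sd`` → 0 the normalized TG mean over WT mean converges to
    ``true_ratio`` exactly. Lane total-protein densities vary between lanes
    to exercise the in-lane normalization.
    """
    if n_wt < 2 or n_tg < 2:
        raise SimConfigError("each group needs at least 2 lanes")
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be >= 0")
    if true_ratio <= 0:
        raise SimConfigError("true_ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    totals = rng.uniform(80.0, 120.0, size=n_wt + n_tg)
    target = np.concatenate(
        [
            1.0 + noise_sd * rng.standard_normal(n_wt) if noise_sd > 0 else np.ones(n_wt),
            true_ratio + noise_sd * rng.standard_normal(n_tg)
            if noise_sd > 0
            else np.full(n_tg, true_ratio),
        ]
    )
    target = np.clip(target, 1e-9, None)  # densities cannot be negative
    # power-of-two fraction keeps band/total exactly proportional to target
    band_fraction = 0.25
    return pd.DataFrame(
        {
            "lane_id": [f"lane{i + 1}" for i in range(n_wt + n_tg)],
            "group": ["WT"] * n_wt + ["TG"] * n_tg,
            "band_density": target * totals * band_fraction,
            "total_density": totals,
            "blot_id": blot_id,
        }
    )


def write_maxquant_fixture(
    table: RatioTable,
    path: str | Path,
    n_contaminants: int = 0,
    n_reverse: int = 0,
    n_only_site: int = 0,
    seed: int = 0,
) -> None:
    """Write a ratio table as a proteinGroups-dialect TSV fixture.

    Optionally sprinkles contaminant ("CON__"), reverse-decoy ("REV__") and
    site-only artifact rows with arbitrary ratios, to exercise the reader's
    filters. Reading the file back yields the identical table.
    """
    if table.data.shape[0] == 0:
        raise FixtureError("refusing to write an empty ratio table")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ratio_cols = [f"Ratio H/M normalized {rep}" for rep in table.replicate_ids]

    def row(pid: str, gene: str, ratios: Sequence[float], rev="", con="", site=""):
        rec = {
            "Protein IDs": pid,
            "Gene names": gene,
            "Reverse": rev,
            "Potential contaminant": con,
            "Only identified by site": site,
        }
        for col, v in zip(ratio_cols, ratios):
            rec[col] = "" if (v is None or (isinstance(v, float) and math.isnan(v))) else repr(v)
        return rec

    records = [
        row(pid, str(table.genes.loc[pid]), table.data.loc[pid].tolist())
        for pid in table.protein_ids
    ]
    r = table.n_replicates
    for k in range(n_reverse):
        records.append(row(f"REV__D{k + 1:03d}", "", rng.uniform(0.5, 2.0, r), rev="+"))
    for k in range(n_contaminants):
        records.append(row(f"CON__C{k + 1:03d}", "", rng.uniform(0.5, 2.0, r), con="+"))
    for k in range(n_only_site):
        records.append(row(f"SITE{k + 1:03d}", "", rng.uniform(0.5, 2.0, r), site="+"))

    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
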