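"""Generate the two synthetic BONLAC cohorts used by the downstream analyses.

Young cohort: 5 replicate experiments (two excluded from the original design
of 7), ~4% planted upregulation and ~6% downregulation at ±60%/−37.5%
effects. Aged cohort: 7 replicates, a shallower de novo proteome (stronger
abundance-dependent dropout) and an up-shifted candidate mix, mirroring the
reduced global synthesis and the excess of apparent upregulation seen with
age. Writes MaxQuant-dialect fixtures, label designs and truth tables under
results/sim/.
"""

import argparse
from pathlib import Path

from bonlac import SimConfig, simulate_experiment, write_maxquant_fixture

RESULTS = Path(__file__).resolve().parents[1] / "results" / "sim"


def cohort_configs(seed: int) -> dict[str, SimConfig]:
    young = SimConfig(cohort="young", seed=seed)  # defaults are the young design
    aged = SimConfig(
        cohort="aged",
        n_replicates=7,
        swap_pattern=None,
        frac_up=0.10,
        frac_down=0.03,
        dropout_midpoint=6.8,  # shallower de novo proteome in aged tissue
        seed=seed + 1,
    )
    return {"young": young, "aged": aged}


def main(seed: int = 1) -> None:
    for name, config in cohort_configs(seed).items():
        outdir = RESULTS / name
        outdir.mkdir(parents=True, exist_ok=True)
        sim = simulate_experiment(config)
        write_maxquant_fixture(
            sim.raw, outdir / "proteinGroups.txt", n_contaminants=3, n_reverse=3
        )
        sim.design.to_tsv(outdir / "design.tsv")
        sim.truth.to_csv(outdir / "truth.tsv", sep="\t")
        config.to_yaml(outdir / "config.yaml")
        n_missing = sim.raw.data.isna().mean().mean()
        print(
            f"{name}: {config.n_proteins} proteins x {config.n_replicates} replicates, "
            f"{n_missing:.0%} missing ratios -> {outdir}"
        )


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    main(**vars(parser.parse_args()))
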