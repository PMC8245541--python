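"""Validation statistics on simulated western blots.

For a handful of candidate-like proteins with known expression ratios,
simulates blot band/total densities, normalizes in-lane and to the WT mean,
runs unpaired two-tailed pooled t-tests reported legend-style (t, df, p,
95% CI, effect ± SE), and regresses the de novo (BONLAC-style) fold change
against the blot fold change. Writes results/validation/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from bonlac import linear_regression, normalize_blot, simulate_blot, unpaired_t_test

ROOT = Path(__file__).resolve().parents[1] / "results"

# candidate name -> (true blot ratio TG/WT, lanes per group)
CANDIDATES = {
    "APP": (2.2, 8),       # positive control, strongly up in the transgenics
    "GAP43": (0.65, 6),    # synaptic protein, down with age
    "RPL13": (0.75, 9),    # large-subunit ribosomal protein, down
    "HSPA1A": (1.4, 3),    # chaperone, up
    "EAAT1": (1.25, 3),    # glutamate transporter
    "RPL18": (1.15, 7),    # trend-level up
}
NOISE_SD = 0.15  # sd of normalized relative density


def main(seed: int = 1) -> None:
    outdir = ROOT / "validation"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    results = {}
    blot_fc, denovo_fc = [], []
    for i, (name, (ratio, n)) in enumerate(CANDIDATES.items()):
        blot = simulate_blot(n, n, true_ratio=ratio, noise_sd=NOISE_SD, seed=seed + i)
        rel = normalize_blot(blot)
        wt = rel[blot["group"] == "WT"]
        tg = rel[blot["group"] == "TG"]
        t = unpaired_t_test(wt, tg)
        results[name] = {"true_ratio": ratio, "n_per_group": n, **t.as_dict()}
        blot_fc.append(float(tg.mean()))
        # de novo fold change: the same underlying ratio seen through
        # SILAC-replicate noise rather than blot noise
        denovo_fc.append(ratio * float(np.exp(rng.normal(0, 0.10))))
        print(
            f"{name:7s} true {ratio:.2f}: t = {t.t:+.3f}, df = {t.df}, "
            f"p = {t.as_dict()['p_formatted']}, effect = {t.effect:.3f} ± {t.effect_se:.3f}"
        )

    reg = linear_regression(blot_fc, denovo_fc)
    print(
        f"de novo vs. blot fold change: slope {reg.slope:.3f}, "
        f"r^2 = {reg.r_squared:.3f}, p = {reg.as_dict()['p_formatted']}"
    )
    with open(outdir / "validation.json", "w") as fh:
        json.dump({"ttests": results, "regression": reg.as_dict()}, fh, indent=2)


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    main(**vars(parser.parse_args()))
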