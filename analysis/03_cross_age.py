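"""Compare the two cohorts' candidate sets: overlap and concordance.

Proteins called up or down in BOTH cohorts form the overlap; each is
classified as concordantly up, concordantly down, or reversed. Ground-truth
classes from the generator are joined in for reference. Writes
results/cross_age/.
"""

import json
from pathlib import Path

from bonlac import concordance_table
from bonlac.screen import calls_from_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_calls(name: str):
    return calls_from_tsv(ROOT / "screen" / f"{name}_calls.tsv")


def main() -> None:
    outdir = ROOT / "cross_age"
    outdir.mkdir(parents=True, exist_ok=True)
    result = concordance_table(load_calls("young"), load_calls("aged"))
    result.as_frame().to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    payload = {
        "n_candidates_young": result.n_candidates_a,
        "n_candidates_aged": result.n_candidates_b,
        "overlap": result.overlap_size,
        **result.counts,
        "style": result.format_counts(),
    }
    with open(outdir / "concordance.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(
        f"{result.n_candidates_a} young and {result.n_candidates_b} aged candidates; "
        f"{result.overlap_size} dysregulated in both "
        f"(both up {result.format_counts()['both_up']}, "
        f"both down {result.format_counts()['both_down']}, "
        f"reversed {result.format_counts()['reversed']})"
    )


if __name__ == "__main__":
    main()
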