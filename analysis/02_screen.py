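"""Ingest, orient and screen both cohorts' ratio tables.

Reads the proteinGroups fixtures written by 01_simulate.py, filters artifact
rows, resolves label swaps against each cohort's design file, runs the
coincidence-detection screen at the ±20% band with the strict-majority
rules, and writes per-protein calls plus cohort summaries under
results/screen/.
"""

import json
from pathlib import Path

from bonlac import (
    LabelDesign,
    calls_to_frame,
    orient_ratios,
    read_protein_groups,
    run_screen,
    summarize_screen,
    write_oriented_tsv,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def screen_cohort(name: str) -> None:
    indir = ROOT / "sim" / name
    outdir = ROOT / "screen"
    outdir.mkdir(parents=True, exist_ok=True)

    raw, report = read_protein_groups(indir / "proteinGroups.txt")
    design = LabelDesign.from_tsv(indir / "design.tsv")
    oriented = orient_ratios(raw, design)
    write_oriented_tsv(oriented, outdir / f"{name}_oriented.tsv")

    calls = run_screen(oriented)
    calls_to_frame(calls).to_csv(outdir / f"{name}_calls.tsv", sep="\t", index=False)
    summary = summarize_screen(calls)
    with open(outdir / f"{name}_summary.json", "w") as fh:
        json.dump({"filter_report": report.__dict__, **summary.as_dict()}, fh, indent=2)

    print(
        f"{name}: filtered {report.total} artifact rows; "
        f"{summary.n_detected_majority}/{summary.n_total} majority-detected; "
        f"{summary.n_up} up ({summary.pct_up}%), {summary.n_down} down "
        f"({summary.pct_down}%), {summary.n_unchanged} unchanged "
        f"({summary.pct_unchanged}%)"
    )


def main() -> None:
    for name in ("young", "aged"):
        screen_cohort(name)


if __name__ == "__main__":
    main()
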