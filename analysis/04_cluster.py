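"""Cluster the cross-cohort fold-change patterns of shared proteins.

Builds the mean-normalized log2 fold-change matrix over proteins
majority-detected in both cohorts, annotates the ±15% broad window, clusters
rows with average linkage on Euclidean distances, cuts six flat clusters,
and exports the matrix, assignments, Newick tree and a heatmap under
results/cluster/.
"""

from pathlib import Path

from bonlac import average_linkage_tree, build_fc_matrix, cut_tree, read_oriented_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
N_CLUSTERS = 6


def main() -> None:
    outdir = ROOT / "cluster"
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = {
        name: read_oriented_tsv(ROOT / "screen" / f"{name}_oriented.tsv", cohort=name)
        for name in ("young", "aged")
    }
    matrix = build_fc_matrix(cohorts, broad_window=(0.85, 1.15))
    matrix.values.to_csv(outdir / "fc_matrix.tsv", sep="\t")

    tree = average_linkage_tree(matrix)
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    groups = cut_tree(tree, N_CLUSTERS)
    groups.to_csv(outdir / "clusters.tsv", sep="\t", header=True)

    sizes = groups.value_counts().sort_index()
    print(
        f"{matrix.values.shape[0]} proteins detected in both cohorts "
        f"({int(matrix.outside_broad_window.sum())} outside the ±15% window); "
        f"{N_CLUSTERS} clusters of sizes {sizes.tolist()}"
    )

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ordered = matrix.values.iloc[tree.leaf_order()]
        fig, ax = plt.subplots(figsize=(4, 8))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(ordered.shape[1]), ordered.columns)
        ax.set_yticks([])
        ax.set_title("mean-normalized log2 fold change")
        fig.colorbar(im, ax=ax, shrink=0.5)
        fig.savefig(outdir / "heatmap.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        print(f"heatmap -> {outdir / 'heatmap.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped heatmap")


if __name__ == "__main__":
    main()
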