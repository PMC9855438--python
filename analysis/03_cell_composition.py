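"""Per-sample composition, group comparison, 2-group clustering, correlations.

Writes the per-10,000 composition table, the per-type PT-vs-BM comparison,
the Ward dendrogram (Newick) with its PT/BM agreement, and the type-type
proportion correlation matrix.
"""

from common import QC_DIR, RESULTS

from tmecompare import composition as comp_mod
from tmecompare import syndata


def main() -> None:
    adata = syndata.read_tenx_dir(QC_DIR)
    comp = comp_mod.composition(adata.obs)
    comp["per_10k"].round(1).to_csv(RESULTS / "composition_per10k.csv")

    shifts = comp_mod.compare_group_proportions(comp)
    shifts.to_csv(RESULTS / "composition_group_tests.csv", index=False)
    top = shifts.sort_values("p").iloc[0]
    print(
        f"most shifted type: {top.cell_type} "
        f"({top.mean_per10k_PT:.0f} vs {top.mean_per10k_BM:.0f} per 10,000 cells, "
        f"p={top.p:.2g})"
    )

    clust = comp_mod.cluster_samples_by_composition(comp)
    (RESULTS / "composition_dendrogram.nwk").write_text(clust["newick"] + "\n")
    print(f"2-group composition clustering agrees with PT/BM at {clust['agreement']:.2f}")

    R, P = comp_mod.proportion_correlations(comp)
    R.round(3).to_csv(RESULTS / "composition_correlations.csv")
    print(f"strongest off-diagonal correlation: {R.where(~(R == 1)).abs().max().max():.2f}")


if __name__ == "__main__":
    main()
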