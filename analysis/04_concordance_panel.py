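#!/usr/bin/env python
"""Select the representative cell-line model by signed-gene concordance.

Compares the cross-cohort tissue gene list against each cell line's DEG
list: overlap n, sign-consistent count k, ratio k/n, one-sided binomial
tail p and BH-adjusted p across the panel. Also reports the pairwise
cell-line vs cell-line table. The representative model is the panel member
with the highest ratio among those with adjusted p < 0.05.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_design import CONSISTENCY_ALPHA, DEG_FDR, SEED, study

from reopair.concordance import (
    evaluate_panel,
    format_pvalue,
    pairwise_dataset_consistency,
)
from reopair.io import read_signed_gene_list
from reopair.sam import sam_fdr, select_degs
from reopair.survival import screen_survival_genes
from reopair.pipeline import cross_tissue_consistent
from study_design import TISSUE_FDR

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    data = study()
    tissue_lists = [
        screen_survival_genes(expr, cohort, TISSUE_FDR)[1]
        for expr, cohort in data["tissue"].values()
    ]
    cross = cross_tissue_consistent(tissue_lists)
    panel = {}
    for name, (expr, design, _) in data["celllines"].items():
        panel[name] = select_degs(
            sam_fdr(expr, design, n_perm=1000, seed=SEED), DEG_FDR
        )

    table = evaluate_panel(cross, panel)
    table.to_csv(RESULTS / "concordance_panel.tsv", sep="\t", index=False)
    print("tissue vs cell-line concordance:")
    for row in table.itertuples():
        print(
            f"  {row.dataset}: n={row.n_overlap} k={row.n_consistent} "
            f"ratio={row.ratio:.4f} p={format_pvalue(row.p)} "
            f"p_adj={format_pvalue(row.p_adj)}"
        )
    ok = table[table["p_adj"] < CONSISTENCY_ALPHA]
    best = ok.loc[ok["ratio"].idxmax(), "dataset"]
    print(f"representative cell-line model: {best}")

    pairwise = pairwise_dataset_consistency(panel)
    pairwise.to_csv(RESULTS / "concordance_pairwise.tsv", sep="\t", index=False)
    print(f"pairwise cell-line table: {len(pairwise)} comparisons")


if __name__ == "__main__":
    main()
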