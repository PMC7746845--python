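#!/usr/bin/env python
"""Univariate Cox screen of every gene in each tissue cohort.

For each cohort, fits a one-gene Cox proportional-hazards model per gene,
BH-adjusts the Wald p-values, and keeps genes at FDR < 20% with the sign of
their coefficient (+1 risk-increasing, -1 protective). The cross-cohort
gene list — genes significant in every cohort with the same sign — is the
tissue "gold standard" the cell-line panel is judged against.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_design import TISSUE_FDR, study

from reopair.io import write_signed_gene_list
from reopair.pipeline import cross_tissue_consistent
from reopair.survival import screen_survival_genes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    data = study()
    planted = set(data["planted"])
    lists = []
    for name, (expr, cohort) in data["tissue"].items():
        table, signed = screen_survival_genes(expr, cohort, TISSUE_FDR)
        table.to_csv(RESULTS / f"tissue_screen_{name}.tsv", sep="\t", index=False)
        write_signed_gene_list(signed, RESULTS / f"tissue_genes_{name}.tsv")
        lists.append(signed)
        hits_planted = len(signed.genes & planted)
        print(
            f"{name}: {len(signed)} survival genes at FDR < {TISSUE_FDR} "
            f"({hits_planted} of {len(planted)} planted)"
        )
    cross = cross_tissue_consistent(lists)
    write_signed_gene_list(cross, RESULTS / "tissue_genes_cross.tsv")
    print(
        f"cross-cohort consistent: {len(cross)} genes, "
        f"{len(cross.genes & planted)} planted, "
        f"{len(cross.genes - planted)} false"
    )


if __name__ == "__main__":
    main()
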