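#!/usr/bin/env python
"""Build and validate the REO gene-pair signature.

From the tissue/cell-line-consistent candidate genes: screen all candidate
gene-pair ordering indicators against relapse-free survival in the training
cohort (Set 1 -> Set 2 at FDR < 10%), exhaustively search all Set 2 subset
combinations for the maximum-C-index majority-vote signature (Set 3), and
evaluate the signature's risk groups on the training and held-out cohorts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_design import DEG_FDR, PAIR_FDR, SEED, TISSUE_FDR, study

from reopair.pipeline import select_candidates
from reopair.sam import sam_fdr, select_degs
from reopair.signature import (
    evaluate_signature,
    optimize_combination,
    screen_pairs,
)
from reopair.survival import screen_survival_genes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    data = study()
    tissue_lists = [
        screen_survival_genes(expr, cohort, TISSUE_FDR)[1]
        for expr, cohort in data["tissue"].values()
    ]
    expr_s, design_s, _ = data["celllines"]["cl_strong"]
    degs = select_degs(sam_fdr(expr_s, design_s, n_perm=1000, seed=SEED), DEG_FDR)
    candidates = select_candidates(tissue_lists, degs)
    print(f"candidate genes: {len(candidates)} "
          f"(all planted: {set(candidates) <= set(data['planted'])})")

    train_expr, train_coh = data["tissue"]["tisA"]
    ledger = screen_pairs(train_expr, train_coh, candidates, fdr=PAIR_FDR)
    print(f"Set 1: {ledger.set1_size} pairs; Set 2: {len(ledger.set2)} pairs "
          f"at FDR < {PAIR_FDR}")

    signature, cindex = optimize_combination(ledger.set2, train_expr, train_coh)
    signature.to_json(RESULTS / "signature.json")
    pairs = ", ".join(f"({r.gene_hi} > {r.gene_lo})" for r in signature.rules)
    print(f"Set 3 signature: {len(signature.rules)} pairs [{pairs}], "
          f"training C-index {cindex:.4f}")

    rows = []
    cohorts = {"training:tisA": (train_expr, train_coh)}
    cohorts.update(
        {f"validation:{k}": v for k, v in data["validation"].items()}
    )
    for name, (expr, cohort) in cohorts.items():
        ev = evaluate_signature(signature, expr, cohort)
        rows.append(
            (name, ev.n_high, ev.n_low, ev.hr, ev.hr_ci95[0], ev.hr_ci95[1],
             ev.logrank_chi2, ev.logrank_p)
        )
        print(
            f"{name}: {ev.n_high} high / {ev.n_low} low risk, "
            f"HR = {ev.hr:.3f} [{ev.hr_ci95[0]:.3f}, {ev.hr_ci95[1]:.3f}], "
            f"log-rank p = {ev.logrank_p:.3g}"
        )
    pd.DataFrame(
        rows,
        columns=["cohort", "n_high", "n_low", "hr", "hr_lo", "hr_hi",
                 "logrank_chi2", "logrank_p"],
    ).to_csv(RESULTS / "signature_evaluation.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
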