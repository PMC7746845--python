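"""End-to-end orchestration: tissue survival screening → cell-line DEGs →
concordance-based cell-line model selection → candidate genes → REO pair
signature → validation.

The stages mirror the study design the package implements: tissue cohorts
define survival-related genes (the clinical gold standard); each candidate
cell-line experiment contributes a signed DEG list; the cell line whose DEG
directions best reproduce the tissue directions (maximum consistency ratio
among panel members with BH-adjusted binomial p < alpha) is selected as the
representative model; genes consistent between tissue and that cell line
become the candidates from which the gene-pair signature is built and then
evaluated on held-out cohorts.

Every artifact is written under a run directory with a manifest recording
seeds and thresholds, so multi-dataset bookkeeping stays auditable. Reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .concordance import evaluate_panel
from .io import (
    ExpressionMatrix,
    GroupDesign,
    SignedGeneList,
    SurvivalCohort,
    read_expression_matrix,
    read_phenotype,
    write_signed_gene_list,
)
from .sam import sam_fdr, select_degs
from .signature import (
    MAX_EXHAUSTIVE,
    PairSignature,
    SetLedger,
    SignatureEvaluation,
    evaluate_signature,
    greedy_combination,
    optimize_combination,
    screen_pairs,
)
from .survival import screen_survival_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dataset:
    """A named expression matrix with optional survival and/or group phenotype."""

    name: str
    expr: ExpressionMatrix
    cohort: SurvivalCohort | None = None
    design: GroupDesign | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and thresholds for one full run.

    ``tissue`` cohorts (>= 1, with survival) drive gene screening; the first
    one doubles as the signature-training cohort unless ``training`` is
    given. ``celllines`` (>= 1, with group labels) form the concordance
    panel. ``validation`` cohorts are only classified and evaluated.
    """

    tissue: tuple[Dataset, ...]
    celllines: tuple[Dataset, ...]
    validation: tuple[Dataset, ...] = ()
    training: Dataset | None = None
    tissue_fdr: float = 0.2
    deg_fdr: float = 0.2
    pair_fdr: float = 0.1
    consistency_alpha: float = 0.05
    require_significant_cellline: bool = True
    max_signature_size: int | None = None
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.tissue_fdr, self.deg_fdr, self.pair_fdr,
                    self.consistency_alpha):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if not self.tissue:
            raise ValueError("need >= 1 tissue cohort")
        if not self.celllines:
            raise ValueError("need >= 1 cell-line dataset")
        for ds in self.tissue:
            if ds.cohort is None:
                raise ValueError(f"tissue dataset {ds.name!r} lacks survival data")
        for ds in self.celllines:
            if ds.design is None:
                raise ValueError(f"cell-line dataset {ds.name!r} lacks group labels")

    @property
    def training_dataset(self) -> Dataset:
        return self.training if self.training is not None else self.tissue[0]

    def thresholds(self) -> dict[str, float]:
        return {
            "tissue_fdr": self.tissue_fdr,
            "deg_fdr": self.deg_fdr,
            "pair_fdr": self.pair_fdr,
            "consistency_alpha": self.consistency_alpha,
        }


@dataclass(frozen=True)
class RunReport:
    """Everything a run produced, in memory; ``write`` persists it."""

    config_summary: dict
    tissue_screens: dict[str, pd.DataFrame]
    tissue_lists: dict[str, SignedGeneList]
    cross_tissue: SignedGeneList
    deg_lists: dict[str, SignedGeneList]
    panel_table: pd.DataFrame
    best_cellline: str
    candidates: list[str]
    ledger: SetLedger
    signature: PairSignature
    train_cindex: float
    evaluations: dict[str, SignatureEvaluation]

    def summary(self) -> dict:
        evals = {
            name: {
                "n_high": ev.n_high,
                "n_low": ev.n_low,
                "hr": ev.hr,
                "hr_ci95": list(ev.hr_ci95),
                "logrank_chi2": ev.logrank_chi2,
                "logrank_p": ev.logrank_p,
            }
            for name, ev in self.evaluations.items()
        }
        return {
            "config": self.config_summary,
            "n_tissue_genes": {k: len(v) for k, v in self.tissue_lists.items()},
            "n_cross_tissue_consistent": len(self.cross_tissue),
            "n_degs": {k: len(v) for k, v in self.deg_lists.items()},
            "best_cellline": self.best_cellline,
            "n_candidates": len(self.candidates),
            "set1_size": self.ledger.set1_size,
            "set2_size": len(self.ledger.set2),
            "signature_pairs": [
                [r.gene_hi, r.gene_lo] for r in self.signature.rules
            ],
            "train_cindex": self.train_cindex,
            "evaluations": evals,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = self.summary()
        for name, table in self.tissue_screens.items():
            table.to_csv(outdir / f"tissue_screen_{name}.tsv", sep="\t",
                         index=False)
        for name, lst in self.deg_lists.items():
            write_signed_gene_list(lst, outdir / f"degs_{name}.tsv")
        write_signed_gene_list(self.cross_tissue, outdir / "cross_tissue.tsv")
        self.panel_table.to_csv(outdir / "concordance_panel.tsv", sep="\t",
                                index=False)
        pd.DataFrame({"gene": self.candidates}).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                (r.gene_hi, r.gene_lo, r.beta, r.p, r.q)
                for r in self.ledger.set2
            ],
            columns=["gene_hi", "gene_lo", "beta", "p", "q"],
        ).to_csv(outdir / "set2.tsv", sep="\t", index=False)
        self.signature.to_json(outdir / "signature.json")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
        )


def cross_tissue_consistent(tissue_lists: Sequence[SignedGeneList]) -> SignedGeneList:
    """Genes present in every tissue list with identical sign throughout."""
    if not tissue_lists:
        raise ValueError("need >= 1 tissue list")
    shared = reduce(lambda a, b: a & b, (l.genes for l in tissue_lists))
    out = {}
    for g in shared:
        signs = {l.sign(g) for l in tissue_lists}
        if len(signs) == 1:
            out[g] = signs.pop()
    if not out:
        raise ValueError("empty candidate set: no sign-consistent shared genes")
    return SignedGeneList(out)


def select_candidates(
    tissue_lists: Sequence[SignedGeneList], best_cell: SignedGeneList
) -> list[str]:
    """Genes sign-consistent across all tissue lists *and* with the selected
    cell line's DEG direction — the clinical drug-resistance candidates."""
    cross = cross_tissue_consistent(tissue_lists)
    out = sorted(
        g for g in cross.genes & best_cell.genes
        if cross.sign(g) == best_cell.sign(g)
    )
    if not out:
        raise ValueError("empty candidate set: no tissue/cell-line consistent genes")
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute all stages in order; see the module docstring for the flow."""
    stage = "tissue_screen"
    try:
        tissue_screens: dict[str, pd.DataFrame] = {}
        tissue_lists: dict[str, SignedGeneList] = {}
        for ds in config.tissue:
            table, signed = screen_survival_genes(
                ds.expr, ds.cohort, config.tissue_fdr
            )
            tissue_screens[ds.name] = table
            tissue_lists[ds.name] = signed
            logger.info("pipeline: %s -> %d survival genes (FDR < %g)",
                        ds.name, len(signed), config.tissue_fdr)
        cross = cross_tissue_consistent(list(tissue_lists.values()))

        stage = "cellline_degs"
        sam_seeds = synthetic.spawn_seeds(config.seed, len(config.celllines))
        deg_lists: dict[str, SignedGeneList] = {}
        for ds, s in zip(config.celllines, sam_seeds):
            result = sam_fdr(ds.expr, ds.design, n_perm=config.n_perm, seed=s)
            deg_lists[ds.name] = select_degs(result, config.deg_fdr)
            logger.info("pipeline: %s -> %d DEGs (FDR < %g)",
                        ds.name, len(deg_lists[ds.name]), config.deg_fdr)

        stage = "concordance"
        panel = evaluate_panel(cross, deg_lists)
        ok = panel[(panel["p_adj"] < config.consistency_alpha)
                   & panel["ratio"].notna()]
        if len(ok):
            best = ok.loc[ok["ratio"].idxmax(), "dataset"]
        elif not config.require_significant_cellline:
            usable = panel[panel["ratio"].notna()]
            if not len(usable):
                raise ValueError("no cell line overlaps the tissue gene list")
            best = usable.loc[usable["ratio"].idxmax(), "dataset"]
            logger.warning("pipeline: no significant cell line; proceeding with "
                           "max-ratio dataset %s (override enabled)", best)
        else:
            raise ValueError(
                "no representative cell line: no panel member reached "
                f"adjusted p < {config.consistency_alpha}"
            )
        logger.info("pipeline: selected cell-line model %s", best)

        stage = "candidate_selection"
        candidates = select_candidates(list(tissue_lists.values()),
                                       deg_lists[best])

        stage = "pair_screen"
        train = config.training_dataset
        ledger = screen_pairs(train.expr, train.cohort, candidates,
                              fdr=config.pair_fdr)
        if not ledger.set2:
            raise ValueError("Set 2 is empty: no survival-associated gene pairs")

        stage = "combination_optimization"
        if (len(ledger.set2) <= MAX_EXHAUSTIVE
                or config.max_signature_size is not None):
            signature, cindex = optimize_combination(
                ledger.set2, train.expr, train.cohort,
                max_size=config.max_signature_size,
            )
        else:
            logger.info("pipeline: Set 2 size %d > %d; greedy forward search",
                        len(ledger.set2), MAX_EXHAUSTIVE)
            signature, cindex = greedy_combination(
                ledger.set2, train.expr, train.cohort
            )
        ledger = SetLedger(ledger.set1_size, ledger.set2, signature, cindex)

        stage = "evaluation"
        evaluations: dict[str, SignatureEvaluation] = {
            f"training:{train.name}": evaluate_signature(
                signature, train.expr, train.cohort
            )
        }
        for ds in config.validation:
            if ds.cohort is None:
                raise ValueError(f"validation dataset {ds.name!r} lacks survival")
            evaluations[f"validation:{ds.name}"] = evaluate_signature(
                signature, ds.expr, ds.cohort
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        config_summary={
            "seed": config.seed,
            "n_perm": config.n_perm,
            **config.thresholds(),
            "tissue_datasets": [ds.name for ds in config.tissue],
            "cellline_datasets": [ds.name for ds in config.celllines],
            "validation_datasets": [ds.name for ds in config.validation],
            "training_dataset": train.name,
        },
        tissue_screens=tissue_screens,
        tissue_lists=tissue_lists,
        cross_tissue=cross,
        deg_lists=deg_lists,
        panel_table=panel,
        best_cellline=str(best),
        candidates=candidates,
        ledger=ledger,
        signature=signature,
        train_cindex=cindex,
        evaluations=evaluations,
    )
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# config-file loading
# ---------------------------------------------------------------------------


def _baseline_from_dict(spec: dict) -> synthetic.ExponentialBaseline | synthetic.WeibullBaseline:
    kind = spec.get("kind", "exponential")
    if kind == "exponential":
        return synthetic.ExponentialBaseline(rate=float(spec["rate"]))
    if kind == "weibull":
        return synthetic.WeibullBaseline(
            shape=float(spec["shape"]), scale=float(spec["scale"])
        )
    raise ValueError(f"unknown baseline kind {kind!r}")


def _dataset_from_dict(entry: dict, base: Path) -> Dataset:
    name = entry["name"]
    if "simulate" in entry:
        sim = dict(entry["simulate"])
        kind = sim.pop("kind")
        if kind == "tissue":
            sim["baseline"] = _baseline_from_dict(sim["baseline"])
            cfg = synthetic.TissueSimConfig(**sim)
            expr, cohort, _ = synthetic.simulate_tissue(cfg)
            return Dataset(name, expr, cohort=cohort)
        if kind == "cellline":
            cfg = synthetic.CellLineSimConfig(**sim)
            expr, design, _ = synthetic.simulate_cellline(cfg)
            return Dataset(name, expr, design=design)
        raise ValueError(f"unknown simulate kind {kind!r}")
    expr = read_expression_matrix(base / entry["expr"])
    cohort, design = read_phenotype(base / entry["pheno"])
    return Dataset(name, expr, cohort=cohort, design=design)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Dataset entries carry either ``expr``/``pheno`` paths (relative to the
    config file) or a ``simulate`` block with generator parameters.
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    base = path.parent
    kwargs = {
        k: payload[k]
        for k in ("tissue_fdr", "deg_fdr", "pair_fdr", "consistency_alpha",
                  "require_significant_cellline", "max_signature_size",
                  "n_perm", "seed")
        if k in payload
    }
    tissue = tuple(_dataset_from_dict(e, base) for e in payload["tissue"])
    celllines = tuple(_dataset_from_dict(e, base) for e in payload["celllines"])
    validation = tuple(
        _dataset_from_dict(e, base) for e in payload.get("validation", [])
    )
    training = None
    if "training" in payload:
        training = _dataset_from_dict(payload["training"], base)
    return PipelineConfig(
        tissue=tissue, celllines=celllines, validation=validation,
        training=training, **kwargs,
    )
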