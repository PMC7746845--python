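"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators and a coupler:

* :func:`simulate_cellline` — two-group (sensitive vs resistant) log-scale
  expression with a planted set of differentially expressed genes.
* :func:`simulate_tissue` — tissue expression plus proportional-hazards
  relapse-free survival driven by planted Cox coefficients, with uniform
  administrative censoring, via the inverse cumulative-hazard transform.
* :func:`simulate_matched` — links the two so that a tunable fraction of
  planted cell-line DEG signs agrees with planted tissue coefficient signs,
  mirroring the hypothesis that genes up in resistant cell lines are
  risk-increasing in tissue.

Expression is Gaussian on the log scale (RMA-like), which keeps
within-sample orderings well defined (ties have probability zero). A single
master seed spawns per-stage child streams through
``numpy.random.SeedSequence``, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    RESISTANT,
    SENSITIVE,
    ExpressionMatrix,
    GroupDesign,
    SignedGeneList,
    SurvivalCohort,
)

# log2-intensity location/spread of the per-gene baselines (RMA-like scale)
BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


@dataclass(frozen=True)
class ExponentialBaseline:
    """Constant-hazard baseline, H0(t) = rate * t."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("exponential rate must be > 0")

    def inverse_cumulative_hazard(self, h: np.ndarray) -> np.ndarray:
        return h / self.rate

    def survival(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-self.rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull baseline, H0(t) = (t / scale) ** shape."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")

    def inverse_cumulative_hazard(self, h: np.ndarray) -> np.ndarray:
        return self.scale * np.power(h, 1.0 / self.shape)

    def survival(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-np.power(np.asarray(t, dtype=float) / self.scale, self.shape))


@dataclass(frozen=True)
class CellLineSimConfig:
    """Two-group cell-line experiment design.

    ``lfc`` is the mean log-expression shift of planted DE genes in resistant
    relative to sensitive samples (split ±lfc/2 around the gene baseline);
    ``noise_sd`` is the residual Gaussian SD per observation.
    """

    n_genes: int
    n_per_group: int
    n_de: int
    lfc: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("need 0 <= n_de <= n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")


@dataclass(frozen=True)
class TissueSimConfig:
    """Tissue cohort with proportional-hazards survival.

    ``beta_map`` carries the true per-gene Cox log-hazard-ratios (genes not
    listed have beta 0). ``censor_horizon`` is the upper bound of the uniform
    administrative censoring time, in the same units as the baseline (months);
    ``None`` disables censoring entirely.
    """

    n_genes: int
    n_samples: int
    beta_map: Mapping[str, float]
    baseline: ExponentialBaseline | WeibullBaseline
    censor_horizon: float | None
    seed: int

    def __post_init__(self) -> None:
        if self.censor_horizon is not None and self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0 (or None for no censoring)")
        object.__setattr__(self, "beta_map", dict(self.beta_map))


@dataclass(frozen=True)
class MatchedSimConfig:
    """Coupled tissue + cell-line simulation.

    ``consistency_rho`` is the fraction of planted genes whose cell-line DEG
    sign matches the sign of its planted tissue coefficient; the remaining
    planted genes get the opposite sign.
    """

    consistency_rho: float
    cellline: CellLineSimConfig
    tissue: TissueSimConfig

    def __post_init__(self) -> None:
        if not 0.0 <= self.consistency_rho <= 1.0:
            raise ValueError("consistency_rho must lie in [0, 1]")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cellline(
    config: CellLineSimConfig,
    planted: Mapping[str, int] | None = None,
) -> tuple[ExpressionMatrix, GroupDesign, SignedGeneList]:
    """Generate a sensitive/resistant expression matrix with planted DEGs.

    Each value is gene baseline (drawn once per gene) + group shift
    (±lfc/2 for DE genes, direction per the planted sign) + Gaussian noise.
    ``planted`` optionally fixes which genes are DE and in which direction
    (used by :func:`simulate_matched`); by default ``n_de`` genes are chosen
    at random with random signs. Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    if planted is None:
        de_genes = list(rng.choice(genes, size=config.n_de, replace=False))
        signs = rng.choice([-1, 1], size=config.n_de)
        planted = dict(zip(de_genes, (int(s) for s in signs)))
    else:
        planted = {str(g): int(s) for g, s in planted.items()}
        if len(planted) != config.n_de:
            raise ValueError(
                f"planted map has {len(planted)} genes but n_de={config.n_de}"
            )
        missing = set(planted) - set(genes)
        if missing:
            raise ValueError(f"planted genes not in matrix: {sorted(missing)}")

    n = config.n_per_group
    samples = [f"S{i:02d}" for i in range(1, n + 1)] + [
        f"R{i:02d}" for i in range(1, n + 1)
    ]
    labels = (SENSITIVE,) * n + (RESISTANT,) * n

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    sign_lookup = np.array([planted.get(g, 0) for g in genes], dtype=float)
    shift = sign_lookup * config.lfc / 2.0
    # sensitive at baseline - shift/... resistant gets +lfc/2*sign, sensitive -lfc/2*sign
    means = np.empty((config.n_genes, 2 * n))
    means[:, :n] = (baseline - shift)[:, None]
    means[:, n:] = (baseline + shift)[:, None]
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    design = GroupDesign(tuple(samples), labels)
    truth = SignedGeneList(planted)
    return expr, design, truth


def simulate_tissue(
    config: TissueSimConfig,
) -> tuple[ExpressionMatrix, SurvivalCohort, dict[str, float]]:
    """Generate tissue expression and proportional-hazards survival.

    Event times come from the inverse-transform construction
    ``T = H0^{-1}(-log U / exp(eta))`` with linear predictor
    ``eta_s = sum_g beta_g x_{g,s}``, which satisfies the Cox model exactly.
    Censoring times are uniform on (0, censor_horizon), independent of
    covariates. A configuration that produces zero events is an error.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    missing = set(config.beta_map) - set(genes)
    if missing:
        raise ValueError(f"beta_map genes not in matrix: {sorted(missing)}")
    samples = [f"P{i:04d}" for i in range(1, config.n_samples + 1)]

    baseline_expr = rng.normal(BASELINE_MEAN, 1.0, size=config.n_genes)
    values = baseline_expr[:, None] + rng.normal(
        0.0, 1.0, size=(config.n_genes, config.n_samples)
    )
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    beta = np.array([config.beta_map.get(g, 0.0) for g in genes])
    centered = values - values.mean(axis=1, keepdims=True)
    eta = beta @ centered  # centering keeps the event-rate scale stable

    u = rng.uniform(size=config.n_samples)
    event_time = config.baseline.inverse_cumulative_hazard(-np.log(u) / np.exp(eta))
    if config.censor_horizon is None:
        time, event = event_time, np.ones(config.n_samples, dtype=int)
    else:
        censor = rng.uniform(0.0, config.censor_horizon, size=config.n_samples)
        event = (event_time <= censor).astype(int)
        time = np.minimum(event_time, censor)
    time = np.maximum(time, 1e-9)  # guard against pathological zero times
    if event.sum() == 0:
        raise ValueError(
            "simulation produced no events; increase censor_horizon "
            "(all follow-up was censored before the first event)"
        )
    cohort = SurvivalCohort(tuple(samples), time, event)
    return expr, cohort, dict(config.beta_map)


def simulate_matched(
    config: MatchedSimConfig,
) -> tuple[
    tuple[ExpressionMatrix, SurvivalCohort, dict[str, float]],
    tuple[ExpressionMatrix, GroupDesign, SignedGeneList],
]:
    """Generate a tissue cohort and a cell-line experiment with linked truths.

    The planted genes are the keys of the tissue ``beta_map``; exactly
    ``round(consistency_rho * n_planted)`` of them receive a cell-line DEG
    sign equal to ``sign(beta)``, the rest the opposite sign. Requires the
    two embedded configs to plant the same number of genes on the same gene
    universe.
    """
    tissue_cfg = config.tissue
    cell_cfg = config.cellline
    if cell_cfg.n_genes != tissue_cfg.n_genes:
        raise ValueError("embedded configs must share n_genes")
    planted_genes = sorted(tissue_cfg.beta_map)
    if len(planted_genes) != cell_cfg.n_de:
        raise ValueError(
            f"tissue plants {len(planted_genes)} genes but cell-line config "
            f"plants n_de={cell_cfg.n_de}; they must match"
        )
    n_agree = round(config.consistency_rho * len(planted_genes))
    planted_signs: dict[str, int] = {}
    for i, gene in enumerate(planted_genes):
        beta_sign = 1 if tissue_cfg.beta_map[gene] > 0 else -1
        planted_signs[gene] = beta_sign if i < n_agree else -beta_sign

    tissue = simulate_tissue(tissue_cfg)
    cellline = simulate_cellline(cell_cfg, planted=planted_signs)
    return tissue, cellline


def simulate_pair_signature(
    n_pairs: int,
    n_decoy_genes: int,
    n_samples: int,
    log_hr: float,
    baseline: ExponentialBaseline | WeibullBaseline,
    censor_horizon: float | None,
    seed: int,
) -> tuple[ExpressionMatrix, SurvivalCohort, list[tuple[str, str]]]:
    """Cohort whose hazard is driven by within-sample gene-pair orderings.

    Plants ``n_pairs`` gene pairs; each sample's hazard is multiplied by
    ``exp(log_hr)`` whenever the pair's first gene is expressed above its
    second (the risk orientation), so each planted pair carries a hazard
    ratio of ``exp(log_hr)`` between its two orderings. ``n_decoy_genes``
    additional genes carry no survival signal. Returns the expression
    matrix, the cohort and the planted (gene_hi, gene_lo) pairs.
    """
    rng = np.random.default_rng(seed)
    n_genes = 2 * n_pairs + n_decoy_genes
    genes = _gene_ids(n_genes)
    samples = [f"P{i:04d}" for i in range(1, n_samples + 1)]
    baseline_expr = rng.normal(BASELINE_MEAN, 1.0, size=n_genes)
    values = baseline_expr[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs)]
    eta = np.zeros(n_samples)
    for hi, lo in pairs:
        indicator = values[genes.index(hi)] > values[genes.index(lo)]
        eta += log_hr * (indicator - indicator.mean())

    u = rng.uniform(size=n_samples)
    event_time = baseline.inverse_cumulative_hazard(-np.log(u) / np.exp(eta))
    if censor_horizon is None:
        time, event = event_time, np.ones(n_samples, dtype=int)
    else:
        censor = rng.uniform(0.0, censor_horizon, size=n_samples)
        event = (event_time <= censor).astype(int)
        time = np.minimum(event_time, censor)
    time = np.maximum(time, 1e-9)
    if event.sum() == 0:
        raise ValueError("no events; increase censor_horizon")
    cohort = SurvivalCohort(tuple(samples), time, event)
    return expr, cohort, pairs


def tissue_truth_signs(beta_map: Mapping[str, float]) -> SignedGeneList:
    """Signed gene list from true coefficients: +1 risk-increasing, −1 protective."""
    return SignedGeneList(
        {g: (1 if b > 0 else -1) for g, b in beta_map.items() if b != 0}
    )


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    seq = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(n)]
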