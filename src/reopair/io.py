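"""Domain containers and tabular readers/writers shared by all analysis stages.

Expression values are gene-by-sample log-scale intensities (e.g. RMA-style
log2 microarray summaries). Survival follow-up uses relapse-free-survival
semantics: time from surgery to relapse/death, with right censoring.

All tables are TSV by default; comma-separated input is accepted via
``sep=","``. Writers are repr-faithful so a write→read round trip preserves
float values exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"


class DataError(ValueError):
    """Raised when an input table violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample matrix of finite log-scale expression values.

    ``values`` is a pandas DataFrame indexed by unique gene ids with unique
    sample-id columns. Missing or non-finite entries are rejected at
    construction: silent imputation would corrupt within-sample orderings.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(
                f"duplicate gene ids {dup}; summarize duplicates first "
                "(see collapse_duplicate_genes)"
            )
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression values must be numeric")
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite expression value at gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-sample follow-up time (months, > 0) and event indicator (1 = relapse/death)."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        ids = list(self.sample_ids)
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise DataError(f"duplicate sample ids {dup}")
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.shape != (len(ids),) or event.shape != (len(ids),):
            raise DataError("time/event length must match sample_ids")
        if not np.all(np.isfinite(time)):
            raise DataError("non-finite follow-up time")
        if np.any(time <= 0):
            bad = ids[int(np.argmax(time <= 0))]
            raise DataError(f"non-positive follow-up time for sample {bad!r}")
        if not np.isin(event, (0, 1)).all():
            bad = ids[int(np.argmax(~np.isin(event, (0, 1))))]
            raise DataError(f"event indicator must be 0/1 (sample {bad!r})")
        object.__setattr__(self, "sample_ids", tuple(ids))
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalCohort":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [index[s] for s in sample_ids]
        return SurvivalCohort(tuple(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class GroupDesign:
    """Two-group phenotype labels (sensitive vs resistant) keyed by sample id."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = list(self.sample_ids)
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample ids in group design")
        bad = sorted({l for l in self.labels if l not in (SENSITIVE, RESISTANT)})
        if bad:
            raise DataError(
                f"group labels must be {SENSITIVE!r}/{RESISTANT!r}, got {bad}"
            )
        if len(self.labels) != len(ids):
            raise DataError("labels length must match sample_ids")
        object.__setattr__(self, "sample_ids", tuple(ids))
        object.__setattr__(self, "labels", tuple(self.labels))

    def samples_with(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def require_two_per_group(self) -> None:
        for label in (SENSITIVE, RESISTANT):
            n = len(self.samples_with(label))
            if n < 2:
                raise DataError(f"group {label!r} has {n} samples; need >= 2")


@dataclass(frozen=True)
class SignedGeneList:
    """Genes tagged +1 (up in resistant / risk-increasing) or −1 (down / protective)."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise DataError(f"signs must be +1/-1, got {bad}")
        object.__setattr__(self, "entries", dict(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def sign(self, gene: str) -> int:
        return self.entries[gene]

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.entries), "sign": list(self.entries.values())}
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) with descriptions; members deduplicated."""

    sets: Mapping[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, tuple[str, ...]]] = {}
        for set_id, (desc, genes) in self.sets.items():
            uniq = tuple(dict.fromkeys(genes))
            if not uniq:
                raise DataError(f"gene set {set_id!r} is empty")
            clean[set_id] = (desc, uniq)
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def genes_of(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes × samples table (first column gene id, header = sample ids).

    Duplicate gene rows are an error directing the caller to
    :func:`collapse_duplicate_genes`; any non-numeric cell (including ``NA``)
    is an error citing its coordinates.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids {dup} in {path}")
    numeric = {}
    for col in df.columns:
        try:
            # astype uses the correctly-rounded parser, keeping round trips exact
            vals = df[col].astype(float)
            bad = ~np.isfinite(vals.to_numpy())
        except (TypeError, ValueError):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna().to_numpy()
        if bad.any():
            gene = df.index[int(np.argmax(bad))]
            raw = df.loc[gene, col]
            raise DataError(
                f"non-numeric expression value {raw!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        numeric[col] = vals.astype(float)
    out = pd.DataFrame(numeric, index=df.index)
    if out.index.has_duplicates:
        dup = out.index[out.index.duplicated()].unique().tolist()
        raise DataError(
            f"duplicate gene ids {dup} in {path}; summarize duplicate rows "
            "with collapse_duplicate_genes before loading"
        )
    return ExpressionMatrix(out)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene")


def collapse_duplicate_genes(
    rows: Iterable[tuple[str, Sequence[float]]],
    sample_ids: Sequence[str],
    policy: str = "max_variance",
) -> ExpressionMatrix:
    """Summarize multiple rows per gene (e.g. multiple probes) into one.

    ``max_variance`` keeps the row with the largest variance across samples
    (the most informative probe); ``mean`` averages rows element-wise.
    """
    if policy not in ("max_variance", "mean"):
        raise ValueError(f"unknown collapse policy {policy!r}")
    grouped: dict[str, list[np.ndarray]] = {}
    for gene, values in rows:
        grouped.setdefault(str(gene), []).append(np.asarray(values, dtype=float))
    if not grouped:
        raise DataError("no rows to collapse")
    out = {}
    for gene, vals in grouped.items():
        if len(vals) == 1:
            out[gene] = vals[0]
        elif policy == "mean":
            out[gene] = np.mean(vals, axis=0)
        else:
            variances = [float(np.var(v)) for v in vals]
            out[gene] = vals[int(np.argmax(variances))]
    df = pd.DataFrame.from_dict(out, orient="index", columns=list(sample_ids))
    return ExpressionMatrix(df)


def read_phenotype(
    path: str | Path, sep: str = "\t"
) -> tuple[SurvivalCohort, GroupDesign | None]:
    """Read a phenotype table: columns ``sample``, ``time``, ``event``[, ``group``]."""
    df = pd.read_csv(path, sep=sep, dtype={"sample": str})
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"phenotype table {path} lacks columns {sorted(missing)}")
    cohort = SurvivalCohort(
        tuple(df["sample"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
    )
    design = None
    if "group" in df.columns:
        design = GroupDesign(cohort.sample_ids, tuple(df["group"].astype(str)))
    return cohort, design


def write_phenotype(
    cohort: SurvivalCohort,
    path: str | Path,
    design: GroupDesign | None = None,
    sep: str = "\t",
) -> None:
    df = cohort.to_frame()
    if design is not None:
        labels = dict(zip(design.sample_ids, design.labels))
        df["group"] = [labels[s] for s in cohort.sample_ids]
    df.to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``set_id <tab> description <tab> gene...`` per line."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"GMT line {lineno} has {len(fields)} fields; need >= 3"
                )
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            n_dup += len(genes) - len(uniq)
            sets[set_id] = (desc, tuple(uniq))
    if not sets:
        raise DataError(f"no sets in GMT file {path}")
    if n_dup:
        logger.info("read_gmt: deduplicated %d repeated gene memberships", n_dup)
    return GeneSetCollection(sets)


def read_signed_gene_list(path: str | Path, sep: str = "\t") -> SignedGeneList:
    df = pd.read_csv(path, sep=sep, dtype={"gene": str})
    if not {"gene", "sign"} <= set(df.columns):
        raise DataError(f"signed gene list {path} needs columns gene, sign")
    return SignedGeneList(dict(zip(df["gene"], df["sign"].astype(int))))


def write_signed_gene_list(
    genes: SignedGeneList, path: str | Path, sep: str = "\t"
) -> None:
    genes.to_frame().to_csv(path, sep=sep, index=False)


def align_samples(
    expr: ExpressionMatrix, cohort: SurvivalCohort
) -> tuple[ExpressionMatrix, SurvivalCohort]:
    """Join matrix and phenotype on sample id (order-independent).

    Unmatched samples on either side are dropped with a warning; fewer than
    two shared samples is an error.
    """
    shared = [s for s in expr.sample_ids if s in set(cohort.sample_ids)]
    n_drop = (expr.n_samples - len(shared)) + (cohort.n_samples - len(shared))
    if len(shared) < 2:
        raise DataError(
            f"only {len(shared)} samples shared between expression matrix "
            "and phenotype table; need >= 2"
        )
    if n_drop:
        logger.warning("align_samples: dropped %d unmatched samples", n_drop)
    return expr.subset_samples(shared), cohort.subset(shared)
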