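"""Replicate differential-expression tables: reading, averaging, ranking, hit selection.

The substrate of the whole pipeline is a gene x replicate table of log2
expression differences (the output of an upstream normalisation such as RMA
applied to microarrays, or a quantitative proteomics ratio table). This
module turns such a table into per-gene summaries (mean, standard deviation
across biological replicates), total orderings by regulation strength, and
top-n hit lists with a protein-coding filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("coexnet")

Direction = Literal["up", "down"]

#: Color-bin labels for node shading, strongest down to strongest up.
COLOR_BINS = ("down-strong", "down-weak", "neutral", "up-weak", "up-strong")

#: Legend thresholds: |x| > 1 is strong, |x| > 0.25 is weak, the rest neutral.
#: Boundary points belong to the weaker bin (the legend's inequalities are
#: strict, so exactly 1.0 is "weak" and exactly 0.25 is "neutral").
STRONG_THRESHOLD = 1.0
WEAK_THRESHOLD = 0.25

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class GeneSummary:
    """Mean and standard deviation of a gene's replicate log2 differences."""

    gene: str
    mean: float
    sd: float
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"negative sd for gene {self.gene!r}")


@dataclass
class DifferentialExpressionTable:
    """Gene x replicate log2 differential-expression values.

    ``values`` is a DataFrame indexed by gene id with one column per
    replicate; missing measurements are NaN.  ``coding`` flags protein-coding
    genes (non-coding genes are excluded from hit lists).
    """

    values: pd.DataFrame
    coding: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.shape[1] < 1:
            raise ValueError("table needs at least one replicate column")
        if not self.values.index.equals(self.coding.index):
            raise ValueError("coding flags must cover exactly the table's genes")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Ranking:
    """1-based total order of genes by mean log2 differential expression.

    ``direction='up'`` puts the most upregulated gene at position 1,
    ``direction='down'`` the most downregulated.  Ties are broken by
    lexicographic gene id so the order is deterministic.
    """

    ordered_genes: tuple[str, ...]
    direction: Direction
    positions: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positions:
            object.__setattr__(
                self,
                "positions",
                {g: i + 1 for i, g in enumerate(self.ordered_genes)},
            )

    def __len__(self) -> int:
        return len(self.ordered_genes)

    def position(self, gene: str) -> int | None:
        """1-based position, or None if the gene is not ranked."""
        return self.positions.get(gene)


@dataclass(frozen=True)
class HitList:
    """Top-n genes of a ranking after the protein-coding filter."""

    genes: tuple[str, ...]
    direction: Direction
    n_requested: int

    def __len__(self) -> int:
        return len(self.genes)


def read_expression_table(
    path: str | Path,
    *,
    sep: str = "\t",
    missing: str = MISSING_TOKEN,
) -> DifferentialExpressionTable:
    """Read a TSV differential-expression table.

    Layout: header row; first column gene id; optional ``coding`` boolean
    column; every remaining column one replicate of log2 expression
    differences.  ``missing`` marks absent measurements.

    Raises
    ------
    ValueError
        On duplicate gene ids (naming the gene) or non-numeric cells
        (naming row and column).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene column plus >=1 replicate column")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    if (genes == "").any():
        raise ValueError(f"{path}: empty gene id in row {int((genes == '').idxmax())}")
    dup_mask = genes.duplicated()
    if dup_mask.any():
        raise ValueError(f"duplicate gene id: {genes[dup_mask].iloc[0]!r}")

    rest = df.drop(columns=[gene_col])
    if "coding" in rest.columns:
        coding = rest.pop("coding").map(_parse_bool)
        coding.index = genes
    else:
        coding = pd.Series(True, index=genes)

    values = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for col in rest.columns:
        raw = rest[col].str.strip()
        cell = raw.replace({missing: None, "": None})
        numeric = pd.to_numeric(cell, errors="coerce")
        bad = numeric.isna() & cell.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} at row {row} column {col!r}"
            )
        values[col] = numeric.to_numpy()
    return DifferentialExpressionTable(values=values, coding=coding.astype(bool))


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in {"1", "true", "t", "yes"}:
        return True
    if t in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean coding flag {token!r}")


def write_expression_table(
    table: DifferentialExpressionTable, path: str | Path, *, sep: str = "\t"
) -> None:
    """Write a table in the dialect :func:`read_expression_table` accepts."""
    out = table.values.copy()
    out.insert(0, "coding", table.coding.map({True: "true", False: "false"}))
    out.to_csv(path, sep=sep, na_rep=MISSING_TOKEN, index_label="gene")


def average_replicates(table: DifferentialExpressionTable) -> list[GeneSummary]:
    """Per-gene mean and sample standard deviation across replicates.

    Missing replicate values are skipped gene-wise; the sd uses the n-1
    denominator and is 0 by convention for a single present value.  Genes
    with no present values are dropped with a warning.
    """
    summaries: list[GeneSummary] = []
    means = table.values.mean(axis=1, skipna=True)
    sds = table.values.std(axis=1, ddof=1, skipna=True)
    counts = table.values.notna().sum(axis=1)
    for gene in table.genes:
        n = int(counts[gene])
        if n == 0:
            logger.warning("gene %s has no replicate values; excluded", gene)
            continue
        sd = 0.0 if n == 1 else float(sds[gene])
        summaries.append(GeneSummary(gene=gene, mean=float(means[gene]), sd=sd, n_replicates=n))
    return summaries


def rank_genes(summaries: Sequence[GeneSummary], direction: Direction) -> Ranking:
    """Rank genes by mean log2 difference.

    'up': descending mean (position 1 = most upregulated); 'down': ascending.
    Ties broken by lexicographic gene id.
    """
    if not summaries:
        raise ValueError("cannot rank an empty summary list")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    sign = -1.0 if direction == "up" else 1.0
    ordered = sorted(summaries, key=lambda s: (sign * s.mean, s.gene))
    return Ranking(ordered_genes=tuple(s.gene for s in ordered), direction=direction)


def select_hits(
    ranking: Ranking,
    n: int,
    coding: pd.Series | dict[str, bool],
) -> HitList:
    """Top-n genes of a ranking, then drop non-protein-coding genes.

    The filter runs after truncation and the list is not refilled, so the
    result may hold fewer than ``n`` genes.
    """
    if n <= 0:
        raise ValueError(f"hit count must be positive, got {n}")
    if n > len(ranking):
        raise ValueError(f"n={n} exceeds ranking size {len(ranking)}")
    top = ranking.ordered_genes[:n]
    kept = tuple(g for g in top if bool(coding[g]))
    dropped = n - len(kept)
    if dropped:
        logger.info("select_hits: %d non-coding genes dropped from top-%d", dropped, n)
    return HitList(genes=kept, direction=ranking.direction, n_requested=n)


def color_bin(log2_diff: float) -> str:
    """Bin a log2 expression difference into the five-shade node color scale.

    x < -1 -> down-strong; -1 <= x < -0.25 -> down-weak;
    |x| <= 0.25 -> neutral; 0.25 < x <= 1 -> up-weak; x > 1 -> up-strong.
    """
    x = float(log2_diff)
    if not np.isfinite(x):
        raise ValueError(f"log2 difference must be finite, got {x!r}")
    if x < -STRONG_THRESHOLD:
        return "down-strong"
    if x < -WEAK_THRESHOLD:
        return "down-weak"
    if x <= WEAK_THRESHOLD:
        return "neutral"
    if x <= STRONG_THRESHOLD:
        return "up-weak"
    return "up-strong"


def summary_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    """Gene, mean, sd, rank in both directions and color bin, as one table."""
    up = rank_genes(summaries, "up")
    down = rank_genes(summaries, "down")
    rows = [
        {
            "gene": s.gene,
            "mean": s.mean,
            "sd": s.sd,
            "rank_up": up.position(s.gene),
            "rank_down": down.position(s.gene),
            "color_bin": color_bin(s.mean),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).set_index("gene")
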