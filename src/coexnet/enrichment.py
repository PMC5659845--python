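"""Target-class ranking enrichment (DAF-16 Class I / Class II style analysis).

A genome-wide target ranking orders all genes by how strongly a
transcription factor is inferred to regulate them: the top block (Class I)
holds targets the factor upregulates, the bottom block (Class II) targets
it downregulates, and the middle band is not considered a target.  Given a
gene cluster, this module locates each member in that ranking, histograms
the positions, and tests whether the cluster holds more targets than the
genome-wide target fraction predicts (exact binomial test).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASS_I = "class_I"
CLASS_II = "class_II"
NON_TARGET = "non_target"


@dataclass(frozen=True)
class TargetRanking:
    """Genome-wide ordered gene list with positional class boundaries.

    The top ``n_class1`` positions are Class I targets, the bottom
    ``n_class2`` positions Class II targets; class membership is determined
    purely by position.
    """

    ordered_genes: tuple[str, ...]
    n_class1: int
    n_class2: int

    def __post_init__(self) -> None:
        if self.n_class1 < 0 or self.n_class2 < 0:
            raise ValueError("class sizes must be non-negative")
        if self.n_class1 + self.n_class2 > len(self.ordered_genes):
            raise ValueError(
                f"class sizes {self.n_class1}+{self.n_class2} exceed "
                f"genome of {len(self.ordered_genes)} genes"
            )
        if len(set(self.ordered_genes)) != len(self.ordered_genes):
            raise ValueError("target ranking contains duplicate genes")
        object.__setattr__(
            self, "_positions", {g: i + 1 for i, g in enumerate(self.ordered_genes)}
        )

    def __len__(self) -> int:
        return len(self.ordered_genes)

    def position(self, gene: str) -> int | None:
        return self._positions.get(gene)  # type: ignore[attr-defined]

    def gene_class(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise ValueError(f"position {position} outside 1..{len(self)}")
        if position <= self.n_class1:
            return CLASS_I
        if position > len(self) - self.n_class2:
            return CLASS_II
        return NON_TARGET

    @property
    def target_fraction(self) -> float:
        return (self.n_class1 + self.n_class2) / len(self)


def load_target_ranking(path: str | Path) -> TargetRanking:
    """Read a TSV of (gene, rank); a ``#classes<TAB>n1<TAB>n2`` first line
    gives the Class I / Class II sizes."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if first[0] != "#classes" or len(first) != 3:
        raise ValueError(f"{path}: expected first line '#classes\\tN1\\tN2'")
    n1, n2 = int(first[1]), int(first[2])
    df = pd.read_csv(path, sep="\t", skiprows=1, dtype={"gene": str, "rank": int})
    ordered = tuple(df.sort_values("rank")["gene"])
    return TargetRanking(ordered_genes=ordered, n_class1=n1, n_class2=n2)


def write_target_ranking(tr: TargetRanking, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#classes\t{tr.n_class1}\t{tr.n_class2}\n")
        fh.write("gene\trank\n")
        for i, gene in enumerate(tr.ordered_genes, start=1):
            fh.write(f"{gene}\t{i}\n")


def member_positions(
    cluster: Iterable[str], tr: TargetRanking
) -> tuple[pd.DataFrame, list[str]]:
    """Locate cluster genes in the target ranking.

    Returns a (gene, position, class) table for genes found in the ranking,
    plus the list of genes the ranking does not contain (reported
    separately, never silently dropped).
    """
    found = []
    missing = []
    for gene in sorted(set(cluster)):
        pos = tr.position(gene)
        if pos is None:
            missing.append(gene)
        else:
            found.append({"gene": gene, "position": pos, "class": tr.gene_class(pos)})
    df = pd.DataFrame(found, columns=["gene", "position", "class"])
    return df, missing


def class_histogram(
    positions: pd.DataFrame, bins: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Histogram cluster positions over bin edges covering the whole ranking."""
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bins must be strictly increasing edges with >= 2 entries")
    counts, _ = np.histogram(positions["position"].to_numpy(), bins=edges)
    if counts.sum() != len(positions):
        raise ValueError("bin edges do not cover all member positions")
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    observed_pct: float
    expected_pct: float
    p: float
    n_found: int
    n_targets: int
    n_class1: int
    n_class2: int
    n_missing: int


def target_fraction_enrichment(
    cluster: Iterable[str], tr: TargetRanking
) -> EnrichmentResult:
    """Observed vs expected percentage of targets (Class I or II) in a cluster.

    The expectation under random gene placement is the genome-wide target
    fraction; the p-value is an exact one-sided binomial test of the
    observed target count against that fraction.  Genes missing from the
    ranking are excluded from both percentages.
    """
    positions, missing = member_positions(cluster, tr)
    n_found = len(positions)
    if n_found == 0:
        raise ValueError("no cluster gene appears in the target ranking")
    n_c1 = int((positions["class"] == CLASS_I).sum())
    n_c2 = int((positions["class"] == CLASS_II).sum())
    n_targets = n_c1 + n_c2
    expected = tr.target_fraction
    test = stats.binomtest(n_targets, n_found, expected, alternative="greater")
    return EnrichmentResult(
        observed_pct=100.0 * n_targets / n_found,
        expected_pct=100.0 * expected,
        p=float(test.pvalue),
        n_found=n_found,
        n_targets=n_targets,
        n_class1=n_c1,
        n_class2=n_c2,
        n_missing=len(missing),
    )
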