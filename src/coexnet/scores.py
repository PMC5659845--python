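"""Rank-sum regulation scores: CoRegScore and UpRegScore.

Both statistics compare the summed 1-based positions of a gene set in a
genome-wide expression ranking against the best and worst placements that
set could have, mapped onto a fixed [-100, 100] scale:

    score = 100 - 200 * (real - best) / (worst - best)

CoRegScore evaluates network-predicted genes: the ideal placement is the
block of positions immediately below the hit block (a perfect prediction of
hits n+1 .. n+m scores 100), the worst is the bottom of the ranking.
UpRegScore evaluates an arbitrary gene set (typically one cluster) in one
experiment's ranking: the ideal placement is the very top (score 100), the
worst the very bottom (score -100).  Genes absent from a ranking are
omitted and both reference sums shrink accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GeneSummary, Ranking, color_bin
from .network import ConnectionNetwork, ClusterAssignment


@dataclass(frozen=True)
class ScoreResult:
    """A position-sum score with its components.

    ``added_real`` is the observed sum of 1-based positions of the evaluated
    genes, ``added_best``/``added_worst`` the ideal and worst possible sums
    for the same number of genes; omitted genes were absent from the ranking.

    When the evaluated genes cannot enter the reference blocks (the usual
    case), ``added_best <= added_real <= added_worst`` and the score lies in
    [-100, 100].  A prediction-score exception exists: if an evaluated gene
    outranks the ideal block (possible for random-control hit lists, whose
    "ideal" block is still the positions just below a hypothetical hit
    block), the formula yields a value above 100; it is reported as
    computed rather than clamped, so null distributions stay unbiased.
    """

    score: float
    added_real: int
    added_best: int
    added_worst: int
    n_evaluated: int
    omitted: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_evaluated > 0 and self.added_best > self.added_worst:
            raise ValueError(
                f"reference position sums out of order: best={self.added_best} "
                f"> worst={self.added_worst}"
            )


def _scale(real: int, best: int, worst: int) -> float:
    if worst == best:
        raise ValueError("degenerate score: best and worst position sums coincide")
    return 100.0 - 200.0 * (real - best) / (worst - best)


def co_reg_score(
    predicted: Sequence[str],
    ranking: Ranking,
    n_hits: int,
) -> ScoreResult:
    """Prediction-accuracy score of network-predicted genes in [-100, 100].

    With m predicted genes found in a G-gene ranking, the ideal sum places
    them at positions ``n_hits+1 .. n_hits+m`` (score 100) and the worst sum
    at the bottom m positions (score -100).
    """
    if not predicted:
        raise ValueError("no predicted genes to score")
    if n_hits < 0:
        raise ValueError(f"n_hits must be >= 0, got {n_hits}")
    positions, omitted = _lookup(predicted, ranking)
    m = len(positions)
    if m == 0:
        raise ValueError("none of the predicted genes appear in the ranking")
    G = len(ranking)
    if G < n_hits + m:
        raise ValueError(f"ranking of {G} genes too small for {n_hits} hits + {m} predictions")
    real = sum(positions)
    best = _block_sum(n_hits + 1, n_hits + m)
    worst = _block_sum(G - m + 1, G)
    return ScoreResult(
        score=_scale(real, best, worst),
        added_real=real,
        added_best=best,
        added_worst=worst,
        n_evaluated=m,
        omitted=tuple(omitted),
    )


def up_reg_score(gene_set: Iterable[str], ranking: Ranking) -> ScoreResult:
    """Regulation score of a gene set in one experiment's ranking.

    100 when the set occupies the very top positions of the ranking, -100
    when it occupies the very bottom.  Genes absent from the ranking are
    omitted and the ideal/worst sums are recomputed for the genes found.
    """
    genes = sorted(set(gene_set))
    positions, omitted = _lookup(genes, ranking)
    n = len(positions)
    if n == 0:
        raise ValueError("no genes of the set appear in the ranking")
    G = len(ranking)
    real = sum(positions)
    best = _block_sum(1, n)
    worst = _block_sum(G - n + 1, G)
    return ScoreResult(
        score=_scale(real, best, worst),
        added_real=real,
        added_best=best,
        added_worst=worst,
        n_evaluated=n,
        omitted=tuple(omitted),
    )


def _lookup(genes: Sequence[str], ranking: Ranking) -> tuple[list[int], list[str]]:
    positions: list[int] = []
    omitted: list[str] = []
    for gene in genes:
        pos = ranking.position(gene)
        if pos is None:
            omitted.append(gene)
        else:
            positions.append(pos)
    return positions, omitted


def _block_sum(first: int, last: int) -> int:
    """Sum of the integer positions first..last inclusive."""
    return (last - first + 1) * (first + last) // 2


def cluster_profile(
    clusters: ClusterAssignment,
    rankings: Sequence[tuple[str, Ranking]],
) -> tuple[pd.DataFrame, dict[tuple[str, str], ScoreResult | None]]:
    """UpRegScore of every marked cluster in every experiment.

    Returns a cluster x experiment DataFrame of scores (NaN where every
    cluster gene was absent from an experiment) plus the full ScoreResult
    per cell (None for the flagged cells).
    """
    if not rankings:
        raise ValueError("no experiment rankings supplied")
    labels = clusters.numbered_labels()
    if not labels:
        raise ValueError("no marked clusters to profile")
    results: dict[tuple[str, str], ScoreResult | None] = {}
    matrix = pd.DataFrame(index=labels, columns=[lab for lab, _ in rankings], dtype=float)
    for cluster_label in labels:
        members = clusters.members(cluster_label)
        for exp_label, ranking in rankings:
            try:
                res: ScoreResult | None = up_reg_score(members, ranking)
            except ValueError:
                res = None
            results[(cluster_label, exp_label)] = res
            matrix.loc[cluster_label, exp_label] = np.nan if res is None else res.score
    return matrix, results


def project_experiment(
    net: ConnectionNetwork,
    external: Sequence[GeneSummary] | Mapping[str, float],
) -> pd.DataFrame:
    """Color the network's nodes with an external experiment's values.

    Each node gets the external mean log2 difference and the corresponding
    color bin; nodes absent from the external experiment are flagged
    ``omitted`` (and colored "NA").  Attributes are also stored on the graph
    under ``ext_mean`` / ``ext_color_bin``.
    """
    if isinstance(external, Mapping):
        means = dict(external)
    else:
        means = {s.gene: s.mean for s in external}
    rows = []
    for node in sorted(net.graph.nodes):
        present = node in means
        mean = means.get(node)
        bin_label = color_bin(mean) if present else "NA"
        net.graph.nodes[node]["ext_mean"] = mean
        net.graph.nodes[node]["ext_color_bin"] = bin_label
        rows.append(
            {"gene": node, "mean_log2_diff": mean, "color_bin": bin_label, "omitted": not present}
        )
    return pd.DataFrame(rows).set_index("gene")


def score_report(results: Mapping[str, ScoreResult]) -> pd.DataFrame:
    """Tabular report of named ScoreResults (for TSV/JSON export)."""
    rows = [
        {
            "name": name,
            "score": r.score,
            "added_real": r.added_real,
            "added_best": r.added_best,
            "added_worst": r.added_worst,
            "n_evaluated": r.n_evaluated,
            "n_omitted": len(r.omitted),
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(rows).set_index("name")
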