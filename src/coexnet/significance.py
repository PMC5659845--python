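"""Random-gene-list null distributions and one-tailed Z-test significance.

Any score or connectivity metric can be calibrated against random gene
lists: draw many same-sized uniform samples from the gene universe, apply
the identical analysis to each, and summarise the resulting null by its
mean and standard deviation.  An observed value is then converted to a
Z-score and a one-tailed normal p-value.  An empirical tail probability
(rank of the observed value among the null values) is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("coexnet")

DEFAULT_N_LISTS = 100

TailDirection = Literal["upper", "lower"]


@dataclass(frozen=True)
class NullDistribution:
    """Metric values over random gene lists with their mean and sd."""

    values: tuple[float, ...]
    mean: float
    sd: float
    n_dropped: int = 0
    seed: int | None = None

    @property
    def n_lists(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SignificanceResult:
    observed: float
    z: float
    p: float
    p_empirical: float
    direction: TailDirection


def random_gene_lists(
    universe: Iterable[str],
    size: int,
    n_lists: int = DEFAULT_N_LISTS,
    seed: int = 1,
) -> list[tuple[str, ...]]:
    """Uniform same-sized random gene lists, reproducible under ``seed``.

    Each list is a sample without replacement of ``size`` genes from the
    universe; sampling order inside a list is discarded (lists are sorted)
    so downstream set-based metrics are stable.
    """
    pool = np.array(sorted(set(universe)))
    if size > pool.size:
        raise ValueError(f"size {size} exceeds universe of {pool.size} genes")
    if size < 1 or n_lists < 1:
        raise ValueError("size and n_lists must be positive")
    rng = np.random.default_rng(seed)
    return [
        tuple(sorted(rng.choice(pool, size=size, replace=False)))
        for _ in range(n_lists)
    ]


def null_distribution(
    metric: Callable[[Sequence[str]], float],
    lists: Sequence[Sequence[str]],
    seed: int | None = None,
) -> NullDistribution:
    """Evaluate a metric on each random list and summarise the null.

    Lists on which the metric raises ValueError (e.g. a score undefined
    because no gene is ranked) are dropped with a warning; the drop count is
    retained.  The sd uses the sample (n-1) estimator.
    """
    if len(lists) < 2:
        raise ValueError("need at least two random lists for a null distribution")
    values: list[float] = []
    dropped = 0
    for genes in lists:
        try:
            values.append(float(metric(genes)))
        except ValueError as exc:
            dropped += 1
            logger.warning("null list dropped: %s", exc)
    if len(values) < 2:
        raise ValueError("fewer than two null lists yielded a defined metric")
    arr = np.asarray(values)
    return NullDistribution(
        values=tuple(values),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n_dropped=dropped,
        seed=seed,
    )


def significance(
    observed: float,
    null: NullDistribution,
    direction: TailDirection = "upper",
) -> SignificanceResult:
    """One-tailed normal significance of an observed value against a null.

    ``direction='upper'`` tests for values above the null (upregulation,
    enrichment); ``'lower'`` for values below it.  A degenerate null
    (sd = 0) is rejected.
    """
    if null.sd <= 0:
        raise ValueError("degenerate null distribution: sd is zero")
    z = (observed - null.mean) / null.sd
    if direction == "upper":
        p = float(stats.norm.sf(z))
        p_emp = (1 + sum(v >= observed for v in null.values)) / (1 + null.n_lists)
    elif direction == "lower":
        p = float(stats.norm.cdf(z))
        p_emp = (1 + sum(v <= observed for v in null.values)) / (1 + null.n_lists)
    else:
        raise ValueError(f"direction must be 'upper' or 'lower', got {direction!r}")
    return SignificanceResult(
        observed=float(observed), z=float(z), p=p, p_empirical=float(p_emp), direction=direction
    )
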