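"""Gene -> top-K coregulated-partner database (modSEEK-style clustering prior).

Each gene maps to an ordered list of its most strongly coexpressed partner
genes, ranked by coexpression strength across many public expression
experiments, together with a multiplicity count (how often the pair is
marked coexpressed in the source compendium).  Partner lists are directed as
stored: gene A may list B without B listing A; symmetry appears only when
networks are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger("coexnet")

DEFAULT_K = 40


class Neighborhood(NamedTuple):
    """Ordered partner list of one gene; ``absent`` marks genes the database
    does not know (Table-style '-' entries)."""

    partners: tuple[tuple[str, int], ...]
    absent: bool


@dataclass
class CoexpressionDatabase:
    """Top-K coregulated partners per gene with pair multiplicities."""

    K: int
    partner_lists: dict[str, tuple[tuple[str, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        for gene, partners in self.partner_lists.items():
            if len(partners) > self.K:
                raise ValueError(f"gene {gene!r} has {len(partners)} > K={self.K} partners")
            for partner, mult in partners:
                if partner == gene:
                    raise ValueError(f"self-partner for gene {gene!r}")
                if mult < 1:
                    raise ValueError(f"non-positive multiplicity for pair ({gene}, {partner})")

    def __contains__(self, gene: str) -> bool:
        return gene in self.partner_lists

    def neighborhood(self, gene: str) -> Neighborhood:
        """Stored partner list in rank order; empty with ``absent=True`` when
        the gene is missing from the database."""
        if gene not in self.partner_lists:
            return Neighborhood(partners=(), absent=True)
        return Neighborhood(partners=self.partner_lists[gene], absent=False)


def neighborhood(db: CoexpressionDatabase, gene: str) -> Neighborhood:
    """Functional alias for :meth:`CoexpressionDatabase.neighborhood`."""
    return db.neighborhood(gene)


def load_partner_db(path: str | Path, K: int = DEFAULT_K) -> CoexpressionDatabase:
    """Load a partner database from TSV, keeping the top-K partners per gene.

    Expected columns: ``gene``, ``partner``, ``rank`` (1 = strongest) and an
    optional ``count`` multiplicity (defaults to 1 when absent).  A directory
    is accepted too: each ``*.tsv`` file inside holds one gene's rows.

    Self-pairs are dropped with a warning; duplicate ranks within one gene
    are rejected.
    """
    path = Path(path)
    if path.is_dir():
        frames = [pd.read_csv(p, sep="\t", dtype=str) for p in sorted(path.glob("*.tsv"))]
        if not frames:
            raise ValueError(f"{path}: no .tsv files in database directory")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "partner", "rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    df["rank"] = pd.to_numeric(df["rank"], errors="raise").astype(int)
    if "count" in df.columns:
        df["count"] = pd.to_numeric(df["count"], errors="raise").astype(int)
    else:
        df["count"] = 1

    self_mask = df["gene"] == df["partner"]
    if self_mask.any():
        logger.warning("dropping %d self-pairs from %s", int(self_mask.sum()), path)
        df = df[~self_mask]

    partner_lists: dict[str, tuple[tuple[str, int], ...]] = {}
    for gene, grp in df.groupby("gene", sort=True):
        if grp["rank"].duplicated().any():
            dup_rank = int(grp.loc[grp["rank"].duplicated(), "rank"].iloc[0])
            raise ValueError(f"duplicate rank {dup_rank} for gene {gene!r}")
        top = grp.sort_values("rank").head(K)
        partner_lists[str(gene)] = tuple(
            (str(p), int(c)) for p, c in zip(top["partner"], top["count"])
        )
    return CoexpressionDatabase(K=K, partner_lists=partner_lists)


def write_partner_db(db: CoexpressionDatabase, path: str | Path) -> None:
    """Write the database in the TSV dialect :func:`load_partner_db` reads."""
    rows: list[dict[str, object]] = []
    for gene in sorted(db.partner_lists):
        for rank, (partner, count) in enumerate(db.partner_lists[gene], start=1):
            rows.append({"gene": gene, "partner": partner, "rank": rank, "count": count})
    pd.DataFrame(rows, columns=["gene", "partner", "rank", "count"]).to_csv(
        path, sep="\t", index=False
    )


def genes_in_db(db: CoexpressionDatabase) -> Iterable[str]:
    return db.partner_lists.keys()
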