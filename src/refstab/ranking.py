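"""Shared stability-ranking container and rank utilities.

Every stability method in this package reduces to a per-gene score with the
convention *lower = more stable*; genes are ranked ascending with average
(fractional) ranks at ties.  :class:`StabilityRanking` is the common
currency the aggregation step consumes, and it round-trips through a simple
TSV (columns ``method, gene, score, rank``) so externally produced rankings
can be aggregated identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd


@dataclass
class StabilityRanking:
    method: str
    table: pd.DataFrame  # columns: gene, score, rank; sorted by rank
    lower_is_more_stable: bool = True

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def rank_of(self, gene: str) -> float:
        return float(self.table.set_index("gene").loc[gene, "rank"])

    def score_of(self, gene: str) -> float:
        return float(self.table.set_index("gene").loc[gene, "score"])

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("gene")["score"]

    @property
    def ranks(self) -> pd.Series:
        return self.table.set_index("gene")["rank"]


def ranking_from_scores(method: str, scores: Mapping[str, float] | pd.Series,
                        ) -> StabilityRanking:
    """Rank genes by ascending score with average ranks at ties."""
    s = pd.Series(scores, dtype=float)
    ranks = s.rank(method="average")
    table = (pd.DataFrame({"gene": s.index, "score": s.to_numpy(),
                           "rank": ranks.to_numpy()})
             .sort_values(["rank", "gene"], kind="stable")
             .reset_index(drop=True))
    return StabilityRanking(method=method, table=table)


def top_set(ranking: StabilityRanking, n: int) -> tuple[set[str], bool]:
    """Genes occupying the *n* best rank positions; ties expand the set.

    Returns ``(genes, expanded)`` where *expanded* is True when a tie pushed
    the set past *n* members.
    """
    ranks = ranking.ranks.sort_values(kind="stable")
    if len(ranks) <= n:
        return set(ranks.index), False
    cutoff = ranks.iloc[n - 1]
    chosen = set(ranks.index[ranks <= cutoff])
    return chosen, len(chosen) > n


def bottom_set(ranking: StabilityRanking, n: int) -> tuple[set[str], bool]:
    """Genes occupying the *n* worst rank positions; ties expand the set."""
    ranks = ranking.ranks.sort_values(ascending=False, kind="stable")
    if len(ranks) <= n:
        return set(ranks.index), False
    cutoff = ranks.iloc[n - 1]
    all_ranks = ranking.ranks
    chosen = set(all_ranks.index[all_ranks >= cutoff])
    return chosen, len(chosen) > n


def ranking_to_tsv(ranking: StabilityRanking, path: str | Path) -> None:
    out = ranking.table.assign(method=ranking.method)
    out[["method", "gene", "score", "rank"]].to_csv(path, sep="\t", index=False)


def ranking_from_tsv(path: str | Path) -> StabilityRanking:
    df = pd.read_csv(path, sep="\t")
    method = str(df["method"].iloc[0])
    table = df[["gene", "score", "rank"]].copy()
    return StabilityRanking(method=method, table=table.reset_index(drop=True))
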