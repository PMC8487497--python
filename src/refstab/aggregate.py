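"""Rank aggregation: comprehensive (geometric-mean-of-ranks) and consensus.

Two aggregation styles are provided.

* :func:`reffinder_rank` — the RefFinder-style comprehensive ranking: a
  gene's score is the geometric mean of its ranks across the ingredient
  methods (conventionally BestKeeper, comparative dCq, geNorm and
  NormFinder); lower geometric mean = more stable.  Aggregation is strictly
  monotone: improving a gene's rank in one method can never worsen its
  comprehensive score.

* :func:`consensus_overall` — a counting consensus: each method nominates
  its *n* most stable and *n* least stable genes (fractional ties expand a
  nomination set past *n*, and that expansion is flagged); genes are then
  ordered by how many methods nominated them.  Equal counts form explicit
  tie groups — they are reported as sets, never broken arbitrarily.

Both consume rank lists rather than raw scores, so rankings produced by
external tools can be aggregated identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ranking import StabilityRanking, bottom_set, ranking_from_scores, top_set

log = logging.getLogger(__name__)

KNOWN_METHODS = ("bestkeeper", "deltacq", "genorm", "normfinder", "reffinder")


def _check_common_genes(rankings: Mapping[str, StabilityRanking],
                        min_methods: int = 2) -> list[str]:
    if len(rankings) < min_methods:
        raise ValueError(f"need >= {min_methods} method rankings to aggregate")
    items = list(rankings.items())
    ref_method, ref = items[0]
    ref_set = set(ref.genes)
    for method, r in items[1:]:
        diff = ref_set ^ set(r.genes)
        if diff:
            raise ValueError(
                f"gene sets differ between {ref_method!r} and {method!r}: "
                f"{sorted(diff)}")
    return ref.genes


def reffinder_rank(rankings: Mapping[str, StabilityRanking]) -> StabilityRanking:
    """Comprehensive ranking by geometric mean of per-method ranks."""
    genes = _check_common_genes(rankings)
    rank_mat = pd.DataFrame({m: r.ranks for m, r in rankings.items()})
    score = np.exp(np.log(rank_mat).mean(axis=1)).reindex(genes)
    return ranking_from_scores("reffinder", score)


@dataclass
class ConsensusTable:
    """Top-n / bottom-n membership counts and the derived overall ordering.

    ``most_stable`` / ``least_stable`` are ordered lists of tie groups
    (each group a sorted list of genes with equal count); only genes with a
    non-zero count appear.
    """

    counts: pd.DataFrame                 # index gene; top_count, bottom_count
    most_stable: list[list[str]]
    least_stable: list[list[str]]
    top_n: int
    expansions: dict[str, dict[str, bool]] = field(default_factory=dict)

    def top_count(self, gene: str) -> int:
        return int(self.counts.loc[gene, "top_count"])

    def bottom_count(self, gene: str) -> int:
        return int(self.counts.loc[gene, "bottom_count"])


def _tie_groups(counts: pd.Series) -> list[list[str]]:
    nonzero = counts[counts > 0]
    groups: list[list[str]] = []
    for value in sorted(nonzero.unique(), reverse=True):
        groups.append(sorted(nonzero.index[nonzero == value]))
    return groups


def consensus_from_extremes(top: Mapping[str, Sequence[str]],
                            bottom: Mapping[str, Sequence[str]],
                            top_n: int = 2,
                            genes: Sequence[str] | None = None,
                            ) -> ConsensusTable:
    """Count top/bottom nominations given explicit per-method gene lists.

    A single method is allowed (the consensus then simply reproduces that
    method's top/bottom sets); an empty method map is not.
    """
    if len(top) < 1:
        raise ValueError("need >= 1 method for a consensus")
    universe = list(genes) if genes is not None else sorted(
        {g for lst in list(top.values()) + list(bottom.values()) for g in lst})
    counts = pd.DataFrame(0, index=universe,
                          columns=["top_count", "bottom_count"])
    for lst in top.values():
        for g in lst:
            counts.loc[g, "top_count"] += 1
    for lst in bottom.values():
        for g in lst:
            counts.loc[g, "bottom_count"] += 1
    return ConsensusTable(counts=counts,
                          most_stable=_tie_groups(counts["top_count"]),
                          least_stable=_tie_groups(counts["bottom_count"]),
                          top_n=top_n)


def consensus_overall(rankings: Mapping[str, StabilityRanking],
                      top_n: int = 2) -> ConsensusTable:
    """Counting consensus over full method rankings (ties expand sets)."""
    genes = _check_common_genes(rankings, min_methods=1)
    tops, bottoms, expansions = {}, {}, {}
    for method, r in rankings.items():
        t, t_exp = top_set(r, top_n)
        b, b_exp = bottom_set(r, top_n)
        tops[method], bottoms[method] = sorted(t), sorted(b)
        expansions[method] = {"top": t_exp, "bottom": b_exp}
        if t_exp or b_exp:
            log.info("method %s: tie expanded a top/bottom-%d set", method, top_n)
    table = consensus_from_extremes(tops, bottoms, top_n=top_n, genes=genes)
    table.expansions = expansions
    return table


def per_tissue_overall(rankings_per_tissue: Mapping[str, Mapping[str, StabilityRanking]],
                       top_n: int = 2) -> dict[str, ConsensusTable]:
    """Independent counting consensus for each tissue's method rankings."""
    return {tissue: consensus_overall(methods, top_n=top_n)
            for tissue, methods in rankings_per_tissue.items()}
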