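"""Pairwise Cq-difference stability: comparative dCq and geNorm M-values.

The comparative dCq method scores a gene by the variability of its Cq
difference against every other candidate: for each ordered pair (a, b) the
per-sample differences Cq_a - Cq_b are summarized by their mean and sample
(n-1) SD, and a gene's stability score is the arithmetic mean of those SDs
over its partners; lower mean SD = more stable.

Because Cq is already a log2-scale quantity, a pairwise Cq difference *is*
a log expression ratio, so the geNorm M-value — the average pairwise
variation of a gene with all others — is numerically identical to the
comparative-dCq mean-SD score on a full panel.  Both are exposed (they are
reported by different tools and aggregated separately downstream), computed
through the same code path so the identity holds exactly.

geNorm's stepwise procedure is also provided: repeatedly drop the gene
with the highest M and recompute until two genes remain; the surviving
pair is tied at rank 1.5 (pairwise variation cannot separate two genes).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_data import CqDataset, CqValidationError
from .ranking import StabilityRanking, ranking_from_scores

log = logging.getLogger(__name__)


def pairwise_deltas(dataset: CqDataset, include_self: bool = False) -> pd.DataFrame:
    """All ordered gene pairs with mean and SD of per-sample Cq differences.

    Complete-case per pair: a pair uses exactly the samples where both genes
    were measured.  Pairs with fewer than two common samples are flagged
    (``ok = False``, NaN statistics) rather than fabricated.  Antisymmetry
    of the means and symmetry of the SDs hold exactly: the reversed pair is
    emitted by negating the forward mean.

    Returns a DataFrame with columns ``gene_a, gene_b, mean_dcq, sd_dcq, n, ok``.
    """
    grid = dataset.to_matrix()
    genes = list(grid.index)
    if len(genes) < 2 and not include_self:
        raise CqValidationError("need >= 2 genes for pairwise differences")
    rows = []
    pairs = itertools.combinations(genes, 2)
    if include_self:
        pairs = itertools.chain(pairs, ((g, g) for g in genes))
    for a, b in pairs:
        va, vb = grid.loc[a].to_numpy(float), grid.loc[b].to_numpy(float)
        both = ~np.isnan(va) & ~np.isnan(vb)
        n = int(both.sum())
        if n < 2:
            log.warning("pair (%s, %s): only %d common samples; flagged", a, b, n)
            rows.append((a, b, np.nan, np.nan, n, False))
            if a != b:
                rows.append((b, a, np.nan, np.nan, n, False))
            continue
        d = va[both] - vb[both]
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        rows.append((a, b, mean, sd, n, True))
        if a != b:
            rows.append((b, a, -mean, sd, n, True))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mean_dcq",
                                       "sd_dcq", "n", "ok"])


def _mean_partner_sd(dataset: CqDataset) -> dict[str, float]:
    deltas = pairwise_deltas(dataset)
    scores = {}
    for g in dataset.genes:
        block = deltas[(deltas["gene_a"] == g) & (deltas["gene_a"] != deltas["gene_b"])]
        usable = block[block["ok"]]
        if len(usable) < len(block):
            log.warning("%s: %d partner pair(s) dropped for lack of common "
                        "samples", g, len(block) - len(usable))
        if usable.empty:
            raise CqValidationError(f"gene {g}: no usable partner pairs")
        scores[g] = float(usable["sd_dcq"].mean())
    return scores


def delta_cq_stability(dataset: CqDataset) -> StabilityRanking:
    """Comparative-dCq ranking: mean partner SD, ascending (lower = stable)."""
    return ranking_from_scores("deltacq", _mean_partner_sd(dataset))


def genorm_m(dataset: CqDataset) -> StabilityRanking:
    """geNorm M-values over the full panel.

    Identical numbers to :func:`delta_cq_stability` by construction (same
    pairwise SDs, same averaging); kept as a distinct method label because
    the downstream aggregation treats the two as separate published tools.
    """
    if len(dataset.genes) < 3:
        raise CqValidationError("geNorm needs >= 3 genes")
    return ranking_from_scores("genorm", _mean_partner_sd(dataset))


@dataclass
class GenormExclusion:
    """Stepwise geNorm result: worst-to-best exclusion order and a ranking."""

    exclusion_order: list[str]     # first element = least stable, excluded first
    m_at_exclusion: list[float]    # M-value each gene carried when excluded
    ranking: StabilityRanking      # rank k for first excluded ... final pair 1.5


def genorm_iterative_ranking(dataset: CqDataset) -> GenormExclusion:
    """geNorm stepwise exclusion: drop the highest-M gene until two remain.

    Ties at the maximum M are broken deterministically by input (gene-list)
    order: the earliest-listed tied gene is excluded first.  The final two
    genes share rank 1.5 and carry the M of the final round.
    """
    genes = list(dataset.genes)
    if len(genes) < 3:
        raise CqValidationError("geNorm stepwise exclusion needs >= 3 genes")
    remaining = list(genes)
    grid_all = dataset.measurements
    order: list[str] = []
    m_out: list[float] = []
    while len(remaining) > 2:
        sub = CqDataset(grid_all[grid_all["gene_symbol"].isin(remaining)],
                        genes=remaining, validate=False)
        scores = _mean_partner_sd(sub)
        worst_m = max(scores.values())
        worst = next(g for g in remaining if scores[g] == worst_m)
        order.append(worst)
        m_out.append(worst_m)
        remaining.remove(worst)
    final = CqDataset(grid_all[grid_all["gene_symbol"].isin(remaining)],
                      genes=remaining, validate=False)
    final_sd = pairwise_deltas(final)
    final_m = float(final_sd.loc[final_sd["ok"], "sd_dcq"].iloc[0]) \
        if final_sd["ok"].any() else float("nan")
    order.extend(remaining)
    m_out.extend([final_m, final_m])

    k = len(genes)
    ranks = {g: float(k - i) for i, g in enumerate(order)}
    for g in remaining:
        ranks[g] = 1.5
    table = (pd.DataFrame({"gene": list(ranks), "score": [dict(zip(order, m_out))[g]
                                                          for g in ranks],
                           "rank": list(ranks.values())})
             .sort_values("rank", kind="stable").reset_index(drop=True))
    ranking = StabilityRanking(method="genorm", table=table)
    return GenormExclusion(exclusion_order=order, m_at_exclusion=m_out,
                           ranking=ranking)
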