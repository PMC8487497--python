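"""BestKeeper-style descriptive stability statistics for candidate genes.

BestKeeper judges a candidate reference gene by the marginal dispersion of
its Cq values: the geometric mean (GM) of Cq, the min/max, and a dispersion
SD[+-CP] expressed both in cycles and as a fold change ("x-fold",
2^|dCq| signed by the direction of the deviation; below-GM deviations mean
*higher* expression and carry a negative sign).  A gene is conventionally
deemed suitable for normalization when SD[+-CP] < 1.0 cycle.  The
BestKeeper *index* is the per-sample geometric mean of Cq over the whole
candidate panel; per-gene Pearson correlation with the index measures how
well each gene tracks the panel consensus.

Two dispersion modes are offered because published tables rarely say which
was used: ``mad`` (mean absolute deviation from the geometric mean — the
original BestKeeper definition, and the default) and ``sample_sd`` (the
usual n-1 standard deviation).  The mode is recorded in every result.

All statistics are carried at full precision; rounding to table precision
happens only at rendering time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cq_data import CqDataset, CqValidationError
from .ranking import StabilityRanking, ranking_from_scores

SD_MODES = ("mad", "sample_sd")


@dataclass(frozen=True)
class BestKeeperStats:
    """One gene's descriptive row: central value, range and dispersion."""

    gene_symbol: str
    gm: float          # geometric mean of Cq, cycles
    cv: float          # sd_cp / gm, dimensionless proportion
    min_cp: float
    max_cp: float
    sd_cp: float       # dispersion in cycles, per sd_mode
    xfold_min: float   # signed fold at the minimum Cq (negative: below GM)
    xfold_max: float   # signed fold at the maximum Cq
    xfold_sd: float    # 2**sd_cp
    n_samples: int
    sd_mode: str = "mad"


@dataclass(frozen=True)
class BestKeeperIndex:
    """Panel index (per-sample GM over genes) and per-gene correlations."""

    index: pd.Series               # per complete-case sample
    correlations: pd.DataFrame     # columns: gene, r, p (NaN when degenerate)
    n_complete: int
    n_dropped: int


def xfold(cp: float, gm: float) -> float:
    """Signed fold change of a Cq deviation from the geometric mean.

    ``sign(cp - gm) * 2**|cp - gm|``; +1 at no deviation.  One cycle of
    deviation is a two-fold expression difference.
    """
    d = cp - gm
    if d == 0:
        return 1.0
    return math.copysign(2.0 ** abs(d), d)


def descriptive_stats(cq_values, gene_symbol: str = "",
                      sd_mode: str = "mad") -> BestKeeperStats:
    """Compute the BestKeeper descriptive row for one gene's Cq vector."""
    if sd_mode not in SD_MODES:
        raise ValueError(f"sd_mode must be one of {SD_MODES}")
    v = np.asarray(cq_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise CqValidationError("need >= 2 Cq values")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise CqValidationError(
            "Cq values must be finite and > 0 (geometric mean undefined)")
    # exp-mean-log form; a constant vector short-circuits so the zero-
    # deviation limit (x-fold = +1 exactly) is not lost to roundoff
    gm = float(v[0]) if v.min() == v.max() else float(np.exp(np.mean(np.log(v))))
    if sd_mode == "mad":
        sd = float(np.mean(np.abs(v - gm)))
    else:
        sd = float(np.std(v, ddof=1))
    mn, mx = float(v.min()), float(v.max())
    return BestKeeperStats(
        gene_symbol=gene_symbol, gm=gm, cv=sd / gm, min_cp=mn, max_cp=mx,
        sd_cp=sd, xfold_min=xfold(mn, gm), xfold_max=xfold(mx, gm),
        xfold_sd=2.0 ** sd, n_samples=int(v.size), sd_mode=sd_mode)


def bestkeeper_stats(dataset: CqDataset,
                     sd_mode: str = "mad") -> list[BestKeeperStats]:
    """Per-gene descriptive rows over the dataset (complete cases per gene)."""
    grid = dataset.to_matrix()
    return [descriptive_stats(grid.loc[g].to_numpy(), gene_symbol=g,
                              sd_mode=sd_mode)
            for g in dataset.genes]


def sample_geometric_means(grid: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of Cq over genes (the panel index)."""
    return np.exp(np.log(grid).mean(axis=0))


def bestkeeper_index(dataset: CqDataset) -> BestKeeperIndex:
    """Panel index and per-gene Pearson correlation against it.

    Complete-case: only samples with the full gene panel enter the index.
    A gene (or index) with zero variance yields NaN r/p as the undefined
    marker rather than an arbitrary value.
    """
    grid = dataset.to_matrix()
    if grid.shape[0] < 3:
        raise CqValidationError("BestKeeper index needs >= 3 genes")
    complete = grid.dropna(axis=1)
    n_dropped = grid.shape[1] - complete.shape[1]
    if complete.shape[1] < 3:
        raise CqValidationError(
            f"only {complete.shape[1]} complete-case samples; need >= 3")
    index = sample_geometric_means(complete)
    rows = []
    for g in complete.index:
        x = complete.loc[g].to_numpy(dtype=float)
        y = index.to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = sps.pearsonr(x, y)
        rows.append((g, float(r), float(p)))
    corr = pd.DataFrame(rows, columns=["gene", "r", "p"])
    return BestKeeperIndex(index=index, correlations=corr,
                           n_complete=complete.shape[1], n_dropped=n_dropped)


def criterion_filter(stats: list[BestKeeperStats], threshold: float = 1.0,
                     ) -> tuple[list[BestKeeperStats], list[BestKeeperStats]]:
    """Partition genes into (suitable, unsuitable) by ``sd_cp < threshold``.

    The inequality is strict — a gene at exactly the threshold is deemed
    unsuitable.  Input order is preserved in both partitions.
    """
    suitable = [s for s in stats if s.sd_cp < threshold]
    unsuitable = [s for s in stats if not s.sd_cp < threshold]
    return suitable, unsuitable


def rank_genes_bestkeeper(dataset: CqDataset,
                          sd_mode: str = "mad") -> StabilityRanking:
    """Rank genes by ascending Cq dispersion (rank 1 = smallest SD)."""
    stats = bestkeeper_stats(dataset, sd_mode=sd_mode)
    scores = {s.gene_symbol: s.sd_cp for s in stats}
    return ranking_from_scores("bestkeeper", scores)
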