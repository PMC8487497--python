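"""Model-based stability estimation (NormFinder-style variance decomposition).

The model treats the gene-by-sample Cq grid within each experimental group
as an additive two-way layout: gene effect + sample effect + noise, with a
gene-specific noise variance.  A candidate reference gene is penalized for
two distinct failure modes:

* *intragroup variability* — its own noise variance sigma^2_{g,gamma},
  estimated from the two-way-centered residuals.  The naive per-gene
  residual mean square is biased (each gene contributes to the estimated
  sample effects), so a multiplicative small-panel correction of the
  k/(k-2) family is applied and negative estimates are clipped at zero;
* *intergroup bias* — a systematic expression difference between groups
  d_{g,gamma} (the gene's group mean, doubly centered so that per gene the
  group-size-weighted deviations sum to zero).  Because d is estimated with
  error, it is shrunk toward zero by an empirical-Bayes factor
  gamma^2 / (gamma^2 + var(d_hat)), where gamma^2 is the between-gene
  variance of the deviations in that group net of estimation noise.

The stability value is

    rho_g = mean over groups of ( |d_shrunk| + sqrt(sigma^2_hat / n_group) )

in cycles; lower = more stable.  At least three genes are required (with
two, the bias correction is undefined), and every group needs >= 2 samples.
An ungrouped variant ranks genes by bias-corrected residual variance alone
and serves single-condition scopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_data import CqDataset, CqValidationError
from .ranking import StabilityRanking, ranking_from_scores

log = logging.getLogger(__name__)


@dataclass
class GroupedCqData:
    """Complete-case gene-by-sample grid plus a group label per sample."""

    matrix: pd.DataFrame   # genes x samples, no missing values
    groups: pd.Series      # index = sample ids, values = group labels

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise CqValidationError("grouped analysis requires complete cases")
        if list(self.groups.index) != list(self.matrix.columns):
            self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            raise CqValidationError("every sample needs a group label")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise CqValidationError(f"groups with < 2 samples: {small}")
        if self.matrix.shape[0] < 3:
            raise CqValidationError(
                "model-based estimation needs >= 3 genes; for fewer genes "
                "use the variance-only ungrouped fallback")

    @property
    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))


def grouped_from_dataset(dataset: CqDataset, group_by: str = "condition",
                         exclude: tuple[str, ...] = ("C",)) -> GroupedCqData:
    """Build grouped data from a dataset, dropping incomplete samples.

    By default groups are the diet conditions with the untreated control
    group ``C`` excluded (stability is judged between the pair-fed and
    deficient groups); the count of dropped incomplete samples is logged.
    """
    grid = dataset.to_matrix()
    ann = dataset.samples.set_index("sample_id")
    keep = [s for s in grid.columns if ann.loc[s, group_by] not in exclude]
    grid = grid[keep]
    complete = grid.dropna(axis=1)
    if complete.shape[1] < grid.shape[1]:
        log.info("dropped %d incomplete samples for grouped analysis",
                 grid.shape[1] - complete.shape[1])
    groups = ann.loc[complete.columns, group_by]
    return GroupedCqData(matrix=complete, groups=groups)


@dataclass
class NormFinderResult:
    """Variance decomposition and stability values, lower = more stable."""

    stability: pd.Series            # rho per gene, cycles
    intragroup_var: pd.DataFrame    # genes x groups, cycles^2 (clipped >= 0)
    intergroup_dev: pd.DataFrame    # raw d, genes x groups, cycles
    intergroup_dev_shrunk: pd.DataFrame
    group_sizes: pd.Series

    @property
    def ranking(self) -> StabilityRanking:
        return ranking_from_scores("normfinder", self.stability)


def _two_way_residuals(y: np.ndarray) -> np.ndarray:
    """Residuals after removing gene (row) and sample (column) effects."""
    return (y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
            + y.mean())


def _bias_corrected_var(y: np.ndarray) -> np.ndarray:
    """Per-gene residual variance with the small-panel correction, clipped.

    For k genes and n samples the naive per-gene residual mean square
    s2_g = sum_j r_gj^2 / (n-1) has expectation
    (1 - 2/k) sigma^2_g + mean(sigma^2)/k, so
    sigma^2_hat_g = k/(k-2) * (s2_g - sum(s2)/(k(k-1))) is unbiased;
    negative estimates are set to zero.
    """
    k, n = y.shape
    if k < 3:
        raise CqValidationError("bias-corrected variance needs >= 3 genes")
    r = _two_way_residuals(y)
    s2 = (r ** 2).sum(axis=1) / (n - 1)
    var = k / (k - 2) * (s2 - s2.sum() / (k * (k - 1)))
    return np.clip(var, 0.0, None)


def normfinder_stability(data: GroupedCqData) -> NormFinderResult:
    """Estimate intra/intergroup components and the stability value rho."""
    genes = list(data.matrix.index)
    labels = data.group_labels
    y_all = data.matrix.to_numpy(dtype=float)
    k = len(genes)

    n_g, var_hat, group_gene_means = {}, {}, {}
    for g in labels:
        cols = (data.groups == g).to_numpy()
        y = y_all[:, cols]
        n_g[g] = y.shape[1]
        var_hat[g] = _bias_corrected_var(y)
        group_gene_means[g] = y.mean(axis=1)

    n = pd.Series(n_g)
    total = float(n.sum())
    m = pd.DataFrame(group_gene_means, index=genes)       # genes x groups
    overall_gene = (m * n).sum(axis=1) / total            # weighted over groups
    group_effect = m.mean(axis=0)                         # mean over genes
    grand = float((group_effect * n).sum() / total)
    d = m.sub(overall_gene, axis=0).sub(group_effect - grand, axis=1)

    var_df = pd.DataFrame(var_hat, index=genes)
    d_shrunk = pd.DataFrame(index=genes, columns=d.columns, dtype=float)
    for g in labels:
        sampling_var = var_df[g] / n_g[g]
        gamma2 = max(0.0, float((d[g] ** 2).sum() / (k - 1)
                                - sampling_var.mean()))
        denom = gamma2 + sampling_var
        with np.errstate(invalid="ignore"):
            factor = np.where(denom > 0, gamma2 / denom, 0.0)
        d_shrunk[g] = d[g] * factor

    per_group = d_shrunk.abs() + np.sqrt(var_df.div(n, axis=1))
    rho = per_group.mean(axis=1)
    return NormFinderResult(stability=rho, intragroup_var=var_df,
                            intergroup_dev=d, intergroup_dev_shrunk=d_shrunk,
                            group_sizes=n)


def normfinder_grouped(dataset: CqDataset, group_by: str = "condition",
                       exclude: tuple[str, ...] = ("C",)) -> NormFinderResult:
    """Convenience wrapper: dataset -> grouped data -> stability values."""
    return normfinder_stability(grouped_from_dataset(dataset, group_by, exclude))


def normfinder_ungrouped(grid: pd.DataFrame | CqDataset) -> StabilityRanking:
    """Variance-only stability for a single-group scope.

    Scores are the bias-corrected per-gene residual variances after two-way
    centering of the full grid (so a per-sample constant — e.g. a loading
    difference — cancels), ranked ascending.
    """
    if isinstance(grid, CqDataset):
        grid = grid.to_matrix().dropna(axis=1)
    if grid.isna().any().any():
        grid = grid.dropna(axis=1)
    var = _bias_corrected_var(grid.to_numpy(dtype=float))
    return ranking_from_scores("normfinder", pd.Series(var, index=grid.index))
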