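"""BestKeeper descriptive statistics, x-fold transform, index and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as rs
from refstab.bestkeeper import sample_geometric_means

from conftest import make_long_df

# published combined-condition dispersion rows used as criterion inputs
SD_ROW_ID = [0.64, 0.89, 0.91, 0.93, 0.94, 1.01, 1.06, 1.08, 1.14, 1.48]
SD_ROW_PF = [0.51, 1.06, 1.08, 1.11, 1.13, 1.14, 1.17, 1.22, 1.24, 1.37]


def brute_force_stats(v, sd_mode):
    """Elementwise recomputation, independent of the implementation."""
    n = len(v)
    gm = 1.0
    for x in v:
        gm *= x
    gm = gm ** (1.0 / n)
    if sd_mode == "mad":
        sd = sum(abs(x - gm) for x in v) / n
    else:
        mean = sum(v) / n
        sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    return gm, sd, min(v), max(v)


@pytest.mark.parametrize("sd_mode", ["mad", "sample_sd"])
def test_descriptive_stats_match_brute_force(sd_mode):
    rng = np.random.default_rng(2024)
    for _ in range(500):
        v = rng.uniform(10, 35, size=rng.integers(2, 12)).tolist()
        s = rs.descriptive_stats(v, sd_mode=sd_mode)
        gm, sd, mn, mx = brute_force_stats(v, sd_mode)
        assert s.gm == pytest.approx(gm, abs=1e-12)
        assert s.sd_cp == pytest.approx(sd, abs=1e-12)
        assert (s.min_cp, s.max_cp) == (mn, mx)
        assert s.cv * s.gm == pytest.approx(s.sd_cp, abs=1e-12)
        assert s.xfold_sd == pytest.approx(2 ** sd, rel=1e-12)
        assert abs(s.xfold_min) >= 1 and abs(s.xfold_max) >= 1


def test_constant_vector_zero_variance_limit():
    s = rs.descriptive_stats([22.0] * 8)
    assert s.gm == 22.0 and s.sd_cp == 0.0 and s.cv == 0.0
    assert s.xfold_min == 1.0 and s.xfold_max == 1.0 and s.xfold_sd == 1.0


def test_descriptive_stats_input_validation():
    with pytest.raises(rs.CqValidationError):
        rs.descriptive_stats([20.0])
    with pytest.raises(rs.CqValidationError):
        rs.descriptive_stats([20.0, -1.0])
    with pytest.raises(ValueError):
        rs.descriptive_stats([20.0, 21.0], sd_mode="median")


def test_xfold_published_cells():
    # below-GM deviation carries a negative sign (higher expression)
    assert round(rs.xfold(21.28, 22.68), 2) == -2.64
    # strongest over-dispersion cell rounds to the printed 10.4
    assert round(rs.xfold(25.85, 22.47), 1) == 10.4
    assert rs.xfold(22.47, 22.47) == 1.0


@given(st.floats(10, 35), st.floats(0, 5))
@settings(max_examples=200, derandomize=True)
def test_xfold_magnitude_antisymmetry(gm, d):
    assert abs(rs.xfold(gm + d, gm)) == pytest.approx(abs(rs.xfold(gm - d, gm)))


def _stats_from_sd_row(row):
    return [rs.BestKeeperStats(gene_symbol=f"g{i}", gm=20.0, cv=sd / 20.0,
                               min_cp=18.0, max_cp=22.0, sd_cp=sd,
                               xfold_min=-1.0, xfold_max=1.0,
                               xfold_sd=2 ** sd, n_samples=96)
            for i, sd in enumerate(row)]


def test_criterion_filter_counts_and_strictness():
    suitable, unsuitable = rs.criterion_filter(_stats_from_sd_row(SD_ROW_ID))
    assert len(suitable) == 5 and len(unsuitable) == 5
    suitable, _ = rs.criterion_filter(_stats_from_sd_row(SD_ROW_PF))
    assert len(suitable) == 1
    at_threshold, _ = rs.criterion_filter(_stats_from_sd_row([1.0]))
    assert at_threshold == []  # strict inequality at the boundary


def test_rank_genes_orders_by_dispersion():
    rows = []
    for gene, sd in [("Hprt", 0.1), ("Tbp", 0.5), ("Rpl19", 1.0)]:
        for j, eps in enumerate([-sd, sd, -sd, sd]):
            rows.append((f"s{j}", f"a{j}", "PF", "liver", gene, 22.0 + eps))
    ranking = rs.rank_genes_bestkeeper(rs.CqDataset(make_long_df(rows)))
    assert ranking.genes == ["Hprt", "Tbp", "Rpl19"]
    assert ranking.ranks.tolist() == [1.0, 2.0, 3.0]


def test_rank_ties_get_average_rank():
    rows = []
    for gene in ("a", "b"):
        for j, eps in enumerate([-0.5, 0.5]):
            rows.append((f"s{j}", f"x{j}", "PF", "liver", gene, 20.0 + eps))
    ranking = rs.rank_genes_bestkeeper(rs.CqDataset(make_long_df(rows)))
    assert ranking.ranks.tolist() == [1.5, 1.5]


def test_ranking_matches_sort_oracle_and_gene_permutation():
    rng = np.random.default_rng(5)
    rows = []
    genes = [f"g{i}" for i in range(6)]
    for j in range(10):
        for g in genes:
            rows.append((f"s{j}", f"a{j}", "PF", "liver", g, rng.uniform(15, 30)))
    df = make_long_df(rows)
    ds = rs.CqDataset(df, genes=genes)
    ranking = rs.rank_genes_bestkeeper(ds)
    sds = {s.gene_symbol: s.sd_cp for s in rs.bestkeeper_stats(ds)}
    oracle = sorted(genes, key=lambda g: sds[g])
    assert ranking.genes == oracle
    permuted = rs.CqDataset(df, genes=genes[::-1])
    assert rs.rank_genes_bestkeeper(permuted).genes == oracle


def test_index_identical_genes_perfect_correlation():
    rows = []
    for j, cq in enumerate([20.0, 21.0, 23.0]):
        for g in ("a", "b", "c"):
            rows.append((f"s{j}", f"x{j}", "PF", "liver", g, cq))
    idx = rs.bestkeeper_index(rs.CqDataset(make_long_df(rows)))
    assert idx.index.tolist() == pytest.approx([20.0, 21.0, 23.0])
    assert idx.correlations["r"].tolist() == pytest.approx([1.0, 1.0, 1.0])


def test_index_constant_gene_reported_undefined():
    rows = []
    for j, cq in enumerate([20.0, 21.0, 23.0]):
        rows += [(f"s{j}", f"x{j}", "PF", "liver", "a", cq),
                 (f"s{j}", f"x{j}", "PF", "liver", "b", cq),
                 (f"s{j}", f"x{j}", "PF", "liver", "flat", 22.0)]
    idx = rs.bestkeeper_index(rs.CqDataset(make_long_df(rows)))
    flat = idx.correlations.set_index("gene").loc["flat"]
    assert np.isnan(flat["r"]) and np.isnan(flat["p"])


def test_two_gene_index_hand_computed():
    grid = pd.DataFrame([[16.0, 25.0, 18.0], [25.0, 16.0, 32.0]],
                        index=["g1", "g2"], columns=["s1", "s2", "s3"])
    idx = sample_geometric_means(grid)
    assert idx.tolist() == pytest.approx([20.0, 20.0, 24.0])


def test_index_needs_enough_genes_and_samples(tiny_dataset):
    with pytest.raises(rs.CqValidationError):
        rs.bestkeeper_index(tiny_dataset)  # 2 genes


def test_noise_gene_decorrelates_from_index():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        base = rng.uniform(18, 26, size=48)  # shared panel signal
        rows = []
        for j in range(48):
            for i in range(4):
                rows.append((f"s{j}", f"a{j}", "PF", "liver", f"g{i}",
                             base[j] + rng.normal(0, 0.2)))
            rows.append((f"s{j}", f"a{j}", "PF", "liver", "noise",
                         rng.uniform(18, 26)))
        idx = rs.bestkeeper_index(rs.CqDataset(make_long_df(rows)))
        r = idx.correlations.set_index("gene").loc["noise", "r"]
        hits += abs(r) < 0.5
    assert hits >= 95
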