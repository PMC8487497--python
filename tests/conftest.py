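import numpy as np
import pandas as pd
import pytest

import refstab as rs

RG_PANEL = ["Hprt", "Rpl19", "Rps29", "Tbp", "Rpl27", "Rplp0", "Ppia",
            "Rpl22", "Actb", "Gapdh"]


def make_long_df(records):
    """records: iterable of (sample, animal, condition, tissue, gene, cq)."""
    return pd.DataFrame(records, columns=["sample_id", "animal_id", "condition",
                                          "tissue", "gene_symbol", "cq"])


def random_dataset(rng, n_genes=4, n_samples=6, missing_frac=0.0):
    """A small random dataset; optionally drop a fraction of cells."""
    genes = [f"g{i}" for i in range(n_genes)]
    rows = []
    for j in range(n_samples):
        cond = "PF" if j % 2 == 0 else "ID"
        for g in genes:
            if missing_frac and rng.random() < missing_frac:
                continue
            rows.append((f"s{j}", f"a{j}", cond, "liver", g,
                         rng.uniform(15, 30)))
    return rs.CqDataset(make_long_df(rows), genes=genes)


@pytest.fixture
def tiny_dataset():
    return rs.CqDataset(make_long_df([
        ("s1", "a1", "PF", "liver", "Actb", 20.0),
        ("s1", "a1", "PF", "liver", "Gapdh", 21.0),
        ("s2", "a2", "ID", "liver", "Actb", 22.0),
        ("s2", "a2", "ID", "liver", "Gapdh", 23.0),
    ]))


@pytest.fixture(scope="session")
def sim_full():
    """Default study simulation, all 11 genes, fixed seed."""
    return rs.generate(rs.StudyDesign(seed=11), rs.default_study_profiles())


@pytest.fixture(scope="session")
def sim_panel(sim_full):
    """The 10-gene candidate panel only (target gene excluded)."""
    return sim_full.select_genes(RG_PANEL)
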