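"""Relative quantification by the comparative ddCq (2^-ddCq) method.

For each sample, dCq = Cq_target - Cq_reference (with several reference
genes, Cq_reference is their arithmetic mean, i.e. the geometric mean on
the expression scale).  ddCq subtracts the control-group mean dCq (the
calibrator), and the relative quantity is 2^-ddCq, so the control group's
*geometric* mean relative quantity is exactly 1 by construction.
Amplification efficiency is taken as ideal doubling (base 2) throughout.

Group comparison uses a pooled-variance two-sided Student t test on the
per-sample dCq values — the statistically natural scale, since dCq is
approximately normal while folds are log-normal; fold-scale means +- SEM
are also reported for presentation.  The sensitivity report re-runs the
quantification under each candidate reference gene: a reference gene whose
own expression shifts by c cycles under treatment rescales the measured
fold by 2^c, which is exactly the hazard reference-gene validation guards
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cq_data import CqDataset, CqValidationError


@dataclass
class FoldChangeResult:
    target: str
    references: tuple[str, ...]
    control: str
    treatment: str
    per_sample: pd.DataFrame     # sample_id, condition, dcq, ddcq, rel_quantity
    group_stats: pd.DataFrame    # per condition: n, mean_fold, sem_fold, geo_fold
    t_stat: float
    p_value: float

    @property
    def treatment_fold(self) -> float:
        """Geometric-mean fold of the treatment group (2^-mean ddCq)."""
        return float(self.group_stats.loc[self.treatment, "geo_fold"])


def student_t(group_a: Sequence[float], group_b: Sequence[float],
              ) -> tuple[float, float]:
    """Pooled-variance two-sample t with two-sided p.

    Degenerate inputs follow the natural limits: zero pooled variance with
    equal means gives (0, 1); zero pooled variance with unequal means gives
    (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CqValidationError("each group needs >= 2 values")
    na, nb = a.size, b.size
    pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    diff = float(a.mean() - b.mean())
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def ddcq_fold_change(dataset: CqDataset, target: str,
                     references: str | Sequence[str],
                     control: str = "PF", treatment: str = "ID",
                     ) -> FoldChangeResult:
    """Quantify *target* relative to *references*, calibrated on *control*."""
    if isinstance(references, str):
        references = (references,)
    references = tuple(references)
    if target in references:
        raise CqValidationError("reference gene cannot equal the target")
    genes = set(dataset.genes)
    missing = [g for g in (target, *references) if g not in genes]
    if missing:
        raise CqValidationError(f"genes absent from dataset: {missing}")

    grid = dataset.to_matrix()
    ann = dataset.samples.set_index("sample_id")
    needed = grid.loc[[target, *references]]
    complete = needed.dropna(axis=1)
    cond = ann.loc[complete.columns, "condition"]

    rows = {}
    for label in (control, treatment):
        cols = cond.index[cond == label]
        if len(cols) < 2:
            raise CqValidationError(
                f"group {label!r} has {len(cols)} complete samples; need >= 2")
        rows[label] = cols

    ref_cq = complete.loc[list(references)].mean(axis=0)
    dcq = complete.loc[target] - ref_cq
    calibrator = float(dcq[rows[control]].mean())
    keep = rows[control].append(rows[treatment])
    per_sample = pd.DataFrame({
        "sample_id": keep,
        "condition": cond[keep].to_numpy(),
        "dcq": dcq[keep].to_numpy(),
    })
    per_sample["ddcq"] = per_sample["dcq"] - calibrator
    per_sample["rel_quantity"] = 2.0 ** (-per_sample["ddcq"])

    stats_rows = {}
    for label in (control, treatment):
        q = per_sample.loc[per_sample["condition"] == label, "rel_quantity"]
        dd = per_sample.loc[per_sample["condition"] == label, "ddcq"]
        n = len(q)
        stats_rows[label] = {
            "n": n,
            "mean_fold": float(q.mean()),
            "sem_fold": float(q.std(ddof=1) / math.sqrt(n)),
            "geo_fold": float(2.0 ** (-dd.mean())),
        }
    group_stats = pd.DataFrame(stats_rows).T

    t, p = student_t(per_sample.loc[per_sample["condition"] == treatment, "dcq"],
                     per_sample.loc[per_sample["condition"] == control, "dcq"])
    return FoldChangeResult(target=target, references=references,
                            control=control, treatment=treatment,
                            per_sample=per_sample, group_stats=group_stats,
                            t_stat=t, p_value=p)


def rg_sensitivity_report(dataset: CqDataset, target: str,
                          rg_list: Sequence[str], control: str = "PF",
                          treatment: str = "ID") -> pd.DataFrame:
    """Fold change of *target* under each candidate reference gene.

    One row per reference gene with the treatment-group fold (geometric and
    arithmetic mean +- SEM) and the t-test p-value; the ``spread``
    column (identical in every row) is max fold / min fold across reference
    genes — how much the choice of reference gene alone rescales the result.
    """
    rows = []
    for rg in rg_list:
        res = ddcq_fold_change(dataset, target, rg, control, treatment)
        ts = res.group_stats.loc[treatment]
        rows.append({"reference": rg, "fold": res.treatment_fold,
                     "mean_fold": ts["mean_fold"], "sem_fold": ts["sem_fold"],
                     "t_stat": res.t_stat, "p_value": res.p_value,
                     "n_control": int(res.group_stats.loc[control, "n"]),
                     "n_treatment": int(ts["n"])})
    out = pd.DataFrame(rows)
    out["spread"] = out["fold"].max() / out["fold"].min()
    return out
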