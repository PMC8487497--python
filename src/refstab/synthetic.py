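"""Synthetic Cq-data generator for a two-condition, multi-tissue animal study.

The generator emulates the measurement structure reference-gene stability
methods assume: a panel of candidate reference genes measured across several
tissues in two diet conditions — an iron-deficient group (ID) and a
pair-fed iron-replete control group (PF) — with n animals per condition and
each animal contributing one sample per tissue.

The model, on the Cq (log2-expression) scale, is additive Gaussian:

    Cq(a, t, c, g) = mu_g + tau_{g,t} + delta_g * 1[c = shifted] + alpha_a + eps

* ``mu_g`` — the gene's baseline Cq (cycles);
* ``tau_{g,t}`` — a fixed tissue offset (cycles), zero by default;
* ``delta_g`` — a condition-dependent shift (cycles): the gene's
  *instability*; 0 for an ideal reference gene, negative for a gene induced
  by the shifted condition (lower Cq = more transcript);
* ``alpha_a ~ N(0, sigma_a^2)`` — drawn once per animal and shared across
  that animal's tissues, inducing within-animal correlation;
* ``eps ~ N(0, (sigma_g * scale_{g,t})^2)`` — i.i.d. technical noise.

Normal noise on the Cq scale is the standard qPCR error model (Cq is
already a log2 quantity).  Randomness comes from :class:`numpy.random
.Generator` seeded with ``PCG64`` — a named, versioned algorithm — so a
seed fully determines the dataset, bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cq_data import CqDataset, CqValidationError

DEFAULT_TISSUES = ("gastrocnemius", "heart", "kidney", "liver", "lung", "spleen")

#: per-gene baseline Cq (cycles), combined-tissues geometric means of the
#: emulated study's candidate panel
BASELINE_CQ: Mapping[str, float] = {
    "Hprt": 22.62, "Rpl19": 17.58, "Rps29": 17.69, "Tbp": 24.24,
    "Rpl27": 18.94, "Rplp0": 19.55, "Ppia": 17.76, "Rpl22": 18.15,
    "Actb": 16.89, "Gapdh": 22.60,
}

#: per-gene technical SD defaults (cycles), matched to the combined-tissues
#: Cq dispersions of the emulated study (0.5-1.5 cycle range)
TECHNICAL_SD: Mapping[str, float] = {
    "Hprt": 0.58, "Rpl19": 0.99, "Rps29": 1.00, "Tbp": 1.01,
    "Rpl27": 1.06, "Rplp0": 1.10, "Ppia": 1.10, "Rpl22": 1.11,
    "Actb": 1.18, "Gapdh": 1.43,
}

#: condition shifts (cycles under ID) used by the "realistic" preset for the
#: reference genes repeatedly flagged as condition-responsive
REALISTIC_CONDITION_SHIFTS: Mapping[str, float] = {
    "Actb": 0.40, "Gapdh": 0.60, "Ppia": 0.30,
}

#: tissue offsets (cycles) for the "realistic" preset; scaled per gene below
REALISTIC_TISSUE_BASE: Mapping[str, float] = {
    "gastrocnemius": 0.0, "heart": -0.6, "kidney": 0.5,
    "liver": -1.2, "lung": 1.0, "spleen": 2.0,
}
_REALISTIC_GENE_SCALE = (1.0, 0.7, 1.3, 0.9, 1.1, 0.8, 1.2, 0.6, 1.4, 1.0)

TARGET_GENE = "Tfrc"
#: shift of the Tfrc-like target under ID: -3.32 cycles = 2^3.32 ~ 10-fold induction
TARGET_CONDITION_SHIFT = -3.32
TARGET_BASELINE_CQ = 21.0
TARGET_TECHNICAL_SD = 0.30


@dataclass(frozen=True)
class GeneProfile:
    """Generative parameters for one gene; see the module model equation."""

    gene_symbol: str
    baseline_cq: float
    condition_shift: float = 0.0
    technical_sd: float = 0.0
    tissue_offsets: Mapping[str, float] = field(default_factory=dict)
    tissue_sd_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technical_sd < 0:
            raise CqValidationError(
                f"{self.gene_symbol}: technical_sd must be >= 0")
        if any(s < 0 for s in self.tissue_sd_scale.values()):
            raise CqValidationError(
                f"{self.gene_symbol}: tissue_sd_scale factors must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Animals-per-group, tissue and condition layout of a simulated study."""

    n_per_group: int = 8
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    conditions: tuple[str, ...] = ("PF", "ID")
    shifted_condition: str = "ID"
    animal_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise CqValidationError("n_per_group must be >= 2")
        if not self.tissues or not self.conditions:
            raise CqValidationError("need >= 1 tissue and >= 1 condition")
        if self.animal_sd < 0:
            raise CqValidationError("animal_sd must be >= 0")


def generate(design: StudyDesign, profiles: Sequence[GeneProfile]) -> CqDataset:
    """Draw a Cq dataset from the additive model; same seed, same bits.

    Each animal gets an id ``<condition><index>`` and contributes one sample
    per tissue (``sample_id = <animal>_<tissue>``).
    """
    if not profiles:
        raise CqValidationError("profiles must be non-empty")
    rng = np.random.default_rng(design.seed)

    animals = [f"{c}{i + 1:02d}" for c in design.conditions
               for i in range(design.n_per_group)]
    alpha = dict(zip(animals, rng.normal(0.0, design.animal_sd, len(animals))))

    rows = []
    for c in design.conditions:
        shifted = c == design.shifted_condition
        for i in range(design.n_per_group):
            animal = f"{c}{i + 1:02d}"
            for t in design.tissues:
                sample = f"{animal}_{t}"
                for p in profiles:
                    sd = p.technical_sd * p.tissue_sd_scale.get(t, 1.0)
                    cq = (p.baseline_cq
                          + p.tissue_offsets.get(t, 0.0)
                          + (p.condition_shift if shifted else 0.0)
                          + alpha[animal]
                          + rng.normal(0.0, sd))
                    rows.append((sample, animal, c, t, p.gene_symbol, cq))
    df = pd.DataFrame(rows, columns=["sample_id", "animal_id", "condition",
                                     "tissue", "gene_symbol", "cq"])
    return CqDataset(df, genes=[p.gene_symbol for p in profiles])


def inject_instability(profiles: Sequence[GeneProfile], gene_symbol: str,
                       delta: float) -> list[GeneProfile]:
    """Return profiles with *gene_symbol*'s condition shift set to *delta*."""
    if gene_symbol not in {p.gene_symbol for p in profiles}:
        raise KeyError(f"gene {gene_symbol!r} not in profile set")
    return [dataclasses.replace(p, condition_shift=delta)
            if p.gene_symbol == gene_symbol else p for p in profiles]


def default_study_profiles(preset: str = "flat") -> list[GeneProfile]:
    """The emulated study panel: 10 candidate reference genes + 1 target.

    ``preset="flat"`` (default): baselines and technical SDs from the module
    tables, zero tissue offsets, zero condition shift for every reference
    gene, and a strongly condition-responsive Tfrc-like target
    (delta = -3.32 cycles, a ~10-fold induction under ID).

    ``preset="realistic"`` additionally applies fixed tissue offsets up to
    +/-2 cycles (inflating combined-tissue Cq ranges the way real multi-
    tissue panels do) and small positive shifts for the classically
    condition-responsive genes Actb, Gapdh and Ppia.
    """
    if preset not in {"flat", "realistic"}:
        raise ValueError(f"unknown preset {preset!r}")
    profiles = []
    for i, (gene, mu) in enumerate(BASELINE_CQ.items()):
        offsets: dict[str, float] = {}
        delta = 0.0
        if preset == "realistic":
            scale = _REALISTIC_GENE_SCALE[i % len(_REALISTIC_GENE_SCALE)]
            offsets = {t: v * scale for t, v in REALISTIC_TISSUE_BASE.items()}
            delta = REALISTIC_CONDITION_SHIFTS.get(gene, 0.0)
        profiles.append(GeneProfile(gene, mu, condition_shift=delta,
                                    technical_sd=TECHNICAL_SD[gene],
                                    tissue_offsets=offsets))
    profiles.append(GeneProfile(TARGET_GENE, TARGET_BASELINE_CQ,
                                condition_shift=TARGET_CONDITION_SHIFT,
                                technical_sd=TARGET_TECHNICAL_SD))
    return profiles


# -- profile (de)serialization ---------------------------------------------

def profiles_to_yaml(profiles: Sequence[GeneProfile], path: str | Path) -> None:
    doc = [{"gene": p.gene_symbol, "mu": float(p.baseline_cq),
            "delta": float(p.condition_shift), "sigma": float(p.technical_sd),
            "tissue_offsets": {k: float(v) for k, v in p.tissue_offsets.items()},
            "tissue_sd_scale": {k: float(v) for k, v in p.tissue_sd_scale.items()}}
           for p in profiles]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def profiles_from_yaml(path: str | Path) -> list[GeneProfile]:
    doc = yaml.safe_load(Path(path).read_text())
    return [GeneProfile(d["gene"], float(d["mu"]),
                        condition_shift=float(d.get("delta", 0.0)),
                        technical_sd=float(d.get("sigma", 0.0)),
                        tissue_offsets=dict(d.get("tissue_offsets") or {}),
                        tissue_sd_scale=dict(d.get("tissue_sd_scale") or {}))
            for d in doc]
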