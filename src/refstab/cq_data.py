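"""Data model, validation and file I/O for Cq (quantification-cycle) tables.

A qPCR run yields one quantification cycle (Cq, also written CP or Ct) per
(sample, gene) combination; one cycle corresponds to roughly a two-fold
difference in template, with lower Cq meaning more template.  The containers
here carry those values together with the sample annotations every stability
method downstream needs — animal, tissue and diet condition — and enforce
the invariants those methods rely on: unique (sample, gene) keys, finite
positive Cq, and declared gene/sample orderings.

Two on-disk layouts are supported:

* ``long`` — one measurement per row with header
  ``sample_id,animal_id,condition,tissue,gene_symbol,cq``;
* ``wide`` — one sample per row, the four annotation columns first, then
  one column per gene.

Comment lines starting with ``#`` are ignored.  Delimiter is inferred from
the extension (``.tsv``/``.tab`` → tab, otherwise comma) and can be
overridden.  Gene symbols are case-preserved but matched case-insensitively,
and ``36b4`` is registered as an alias of ``Rplp0`` (both names circulate
for the same ribosomal-protein gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LONG_COLUMNS = ["sample_id", "animal_id", "condition", "tissue", "gene_symbol", "cq"]
ANNOTATION_COLUMNS = ["sample_id", "animal_id", "condition", "tissue"]

#: alternative symbols seen in the literature, matched case-insensitively
GENE_ALIASES: Mapping[str, str] = {"36b4": "Rplp0"}


class CqValidationError(ValueError):
    """An input table violates a dataset invariant."""


class CqFormatError(ValueError):
    """A file cannot be interpreted as a Cq table."""


def canonical_gene_symbol(symbol: str, registry: dict[str, str] | None = None) -> str:
    """Resolve aliases and case-fold a gene symbol against *registry*.

    *registry* maps lower-case keys to the canonical (first-seen) spelling
    and is updated in place; pass ``None`` for one-off resolution.
    """
    symbol = str(symbol).strip()
    for alias, target in GENE_ALIASES.items():
        if symbol.lower() == alias.lower():
            symbol = target
            break
    if registry is None:
        return symbol
    return registry.setdefault(symbol.lower(), symbol)


@dataclass(frozen=True)
class AnalysisScope:
    """A tissue/condition selection for an analysis.

    ``None`` means "all" for either axis.  The qPCR stability literature
    distinguishes per-tissue scopes from an all-tissues-combined scope, and
    per-condition scopes from a combined two-condition scope; this type
    expresses any of those.
    """

    tissues: tuple[str, ...] | None = None
    conditions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name, sel in (("tissues", self.tissues), ("conditions", self.conditions)):
            if sel is not None and len(sel) == 0:
                raise CqValidationError(f"scope selection for {name} must be non-empty")

    @staticmethod
    def of(tissues: Iterable[str] | str | None = None,
           conditions: Iterable[str] | str | None = None) -> "AnalysisScope":
        def _tup(x):
            if x is None:
                return None
            if isinstance(x, str):
                return (x,)
            return tuple(x)
        return AnalysisScope(_tup(tissues), _tup(conditions))


class CqDataset:
    """An annotated collection of Cq measurements.

    Internally a long-format :class:`pandas.DataFrame` with columns
    ``sample_id, animal_id, condition, tissue, gene_symbol, cq`` plus an
    ordered gene list and an ordered, annotated sample list.
    """

    def __init__(self, measurements: pd.DataFrame,
                 genes: Sequence[str] | None = None,
                 validate: bool = True) -> None:
        missing = [c for c in LONG_COLUMNS if c not in measurements.columns]
        if missing:
            raise CqFormatError(f"measurement table lacks columns: {missing}")
        df = measurements.loc[:, LONG_COLUMNS].copy().reset_index(drop=True)

        registry: dict[str, str] = {}
        if genes is not None:
            genes = [canonical_gene_symbol(g, registry) for g in genes]
        df["gene_symbol"] = [canonical_gene_symbol(g, registry) for g in df["gene_symbol"]]
        for col in ("sample_id", "animal_id", "condition", "tissue"):
            df[col] = df[col].astype(str)
        df["cq"] = pd.to_numeric(df["cq"])

        if validate:
            self._validate(df)

        self._df = df
        seen = list(dict.fromkeys(df["gene_symbol"]))
        if genes is None:
            self._genes = seen
        else:
            extra = [g for g in seen if g not in genes]
            self._genes = list(genes) + extra
        self._samples = (df[ANNOTATION_COLUMNS]
                         .drop_duplicates(subset="sample_id")
                         .reset_index(drop=True))

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        cq = df["cq"].to_numpy(dtype=float)
        bad = ~np.isfinite(cq) | (cq <= 0)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise CqValidationError(
                f"cq must be finite and > 0; offending rows (0-based): {rows}")
        dup = df.duplicated(subset=["sample_id", "gene_symbol"], keep=False)
        if dup.any():
            keys = (df.loc[dup, ["sample_id", "gene_symbol"]]
                    .drop_duplicates().itertuples(index=False, name=None))
            raise CqValidationError(
                "duplicate (sample, gene) measurements: " +
                ", ".join(map(str, list(keys)[:10])))
        ann = df[ANNOTATION_COLUMNS].drop_duplicates()
        conflicts = ann["sample_id"][ann["sample_id"].duplicated()].unique()
        if len(conflicts):
            raise CqValidationError(
                f"samples with conflicting annotations: {list(conflicts)}")

    # -- basic accessors ---------------------------------------------------

    @property
    def measurements(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    @property
    def samples(self) -> pd.DataFrame:
        """Ordered sample annotations (one row per sample)."""
        return self._samples.copy()

    @property
    def sample_ids(self) -> list[str]:
        return self._samples["sample_id"].tolist()

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self._samples["tissue"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self._samples["condition"]))

    def __len__(self) -> int:
        return len(self._df)

    def equals(self, other: "CqDataset") -> bool:
        """Field-for-field equality, independent of row order."""
        if self.genes != other.genes:
            return False
        key = ["sample_id", "gene_symbol"]
        a = self._df.sort_values(key).reset_index(drop=True)
        b = other._df.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    # -- operations --------------------------------------------------------

    def subset(self, scope: AnalysisScope) -> "CqDataset":
        """Restrict to the samples matching *scope*; the gene list is kept.

        Scope terms absent from the dataset's vocabulary are logged as
        warnings, not errors; an empty result is legal but flagged.
        """
        df = self._df
        if scope.tissues is not None:
            unknown = set(scope.tissues) - set(self.tissues)
            if unknown:
                log.warning("scope tissues not in dataset: %s", sorted(unknown))
            df = df[df["tissue"].isin(scope.tissues)]
        if scope.conditions is not None:
            unknown = set(scope.conditions) - set(self.conditions)
            if unknown:
                log.warning("scope conditions not in dataset: %s", sorted(unknown))
            df = df[df["condition"].isin(scope.conditions)]
        if df.empty:
            log.warning("scope %s selects no measurements", scope)
        return CqDataset(df, genes=self._genes, validate=False)

    def select_genes(self, genes: Sequence[str]) -> "CqDataset":
        """Restrict to a gene subset (e.g. the candidate panel without the
        target gene), preserving the requested order."""
        registry: dict[str, str] = {g.lower(): g for g in self._genes}
        wanted = [canonical_gene_symbol(g, registry) for g in genes]
        unknown = [g for g in wanted if g not in self._genes]
        if unknown:
            raise CqValidationError(f"genes absent from dataset: {unknown}")
        df = self._df[self._df["gene_symbol"].isin(wanted)]
        return CqDataset(df, genes=wanted, validate=False)

    def to_matrix(self) -> pd.DataFrame:
        """Gene-by-sample Cq grid; absent (sample, gene) cells are NaN."""
        grid = self._df.pivot(index="gene_symbol", columns="sample_id", values="cq")
        return grid.reindex(index=self._genes, columns=self.sample_ids)

    def completeness(self) -> dict:
        """Report whether every gene was measured in every sample."""
        grid = self.to_matrix()
        miss = grid.isna()
        missing = [(s, g) for g in grid.index for s in grid.columns if miss.loc[g, s]]
        return {
            "n_genes": len(self._genes),
            "n_samples": len(self._samples),
            "n_expected": grid.size,
            "n_observed": int(grid.notna().to_numpy().sum()),
            "n_missing": len(missing),
            "complete": not missing,
            "missing": missing,
        }


# -- file I/O ---------------------------------------------------------------

def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _detect_layout(columns: Sequence[str]) -> str:
    cols = [c.strip() for c in columns]
    if set(LONG_COLUMNS) <= set(cols):
        return "long"
    if cols[:4] == ANNOTATION_COLUMNS and len(cols) > 4:
        return "wide"
    raise CqFormatError(
        f"cannot interpret header {list(columns)!r} as a long or wide Cq table")


def read_cq_table(path: str | Path, layout: str | None = None,
                  delimiter: str | None = None) -> CqDataset:
    """Read a long- or wide-format Cq table into a validated dataset.

    ``layout`` is auto-detected from the header when not given.  Numbers are
    parsed with '.' as decimal separator regardless of locale (pandas'
    C parser).  Empty Cq cells denote missing measurements and are dropped
    with a log entry; non-numeric or non-positive Cq raises
    :class:`CqValidationError` naming the offending rows.  A ``replicate``
    column, if present, is collapsed by arithmetic mean before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                      skip_blank_lines=True)
    raw.columns = [str(c).strip() for c in raw.columns]
    if layout is None:
        layout = _detect_layout(raw.columns)
    elif layout not in {"long", "wide"}:
        raise CqFormatError(f"unknown layout {layout!r}")

    if layout == "wide":
        gene_cols = [c for c in raw.columns if c not in ANNOTATION_COLUMNS]
        if not gene_cols:
            raise CqFormatError("wide table has no gene columns")
        long_df = raw.melt(id_vars=ANNOTATION_COLUMNS, value_vars=gene_cols,
                           var_name="gene_symbol", value_name="cq")
    else:
        required = LONG_COLUMNS + (["replicate"] if "replicate" in raw.columns else [])
        missing = [c for c in LONG_COLUMNS if c not in raw.columns]
        if missing:
            raise CqFormatError(f"long table lacks columns: {missing}")
        long_df = raw.loc[:, required]

    blank = long_df["cq"].isna() | (long_df["cq"].astype(str).str.strip() == "")
    if blank.any():
        log.info("%d empty Cq cells treated as missing measurements", int(blank.sum()))
        long_df = long_df[~blank]
    bad = pd.to_numeric(long_df["cq"], errors="coerce").isna()
    if bad.any():
        raise CqValidationError(
            f"non-numeric cq values at rows (0-based, post-comment): "
            f"{long_df.index[bad].tolist()[:10]}")
    # astype goes through correctly-rounded float() so text round-trips exactly
    long_df = long_df.assign(cq=long_df["cq"].astype(float))

    if "replicate" in long_df.columns:
        n_before = len(long_df)
        long_df = (long_df
                   .groupby(ANNOTATION_COLUMNS + ["gene_symbol"], sort=False,
                            as_index=False)["cq"].mean())
        log.info("collapsed %d replicate wells to %d measurements by mean",
                 n_before, len(long_df))

    return CqDataset(long_df)


def write_cq_table(dataset: CqDataset, path: str | Path, layout: str = "long",
                   delimiter: str | None = None) -> None:
    """Write a dataset as a long or wide delimited text table."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    if layout == "long":
        dataset.measurements.to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        grid = dataset.to_matrix().T  # samples as rows
        wide = dataset.samples.merge(
            grid, left_on="sample_id", right_index=True, how="left")
        wide.to_csv(path, sep=sep, index=False)
    else:
        raise CqFormatError(f"unknown layout {layout!r}")
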