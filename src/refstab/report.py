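"""Pipeline orchestration and paper-style table rendering.

``run_evaluate`` executes every requested stability method over every
requested scope (the all-tissues-combined scope plus each individual
tissue), derives the comprehensive (geometric-mean-of-ranks) ranking and
the counting consensus, and packages everything with a provenance block
(config, package version, input checksum, dropped-sample counts) that
suffices to reproduce the run bit-identically.

Rendered tables round to the configured precision (default 2 decimals);
the stored results keep full precision, and rendering never mutates them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .aggregate import ConsensusTable, consensus_overall, reffinder_rank
from .bestkeeper import BestKeeperStats, bestkeeper_stats, rank_genes_bestkeeper
from .cq_data import AnalysisScope, CqDataset, CqValidationError, read_cq_table
from .normfinder import normfinder_grouped, normfinder_ungrouped
from .pairwise import delta_cq_stability, genorm_iterative_ranking
from .ranking import StabilityRanking

log = logging.getLogger(__name__)

EVALUATE_METHODS = ("bestkeeper", "deltacq", "genorm", "normfinder")
#: ingredient rankings counted by the overall consensus (geNorm enters
#: through the comprehensive ranking, not as a separate vote)
CONSENSUS_METHODS = ("bestkeeper", "deltacq", "normfinder", "reffinder")

EXIT_OK, EXIT_VALIDATION, EXIT_PARTIAL = 0, 2, 3


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    input: str | Path | None = None
    methods: tuple[str, ...] = EVALUATE_METHODS
    conditions: tuple[str, ...] = ("PF", "ID")
    per_tissue: bool = True
    sd_mode: str = "mad"
    top_n: int = 2
    seed: int | None = None
    outdir: str | Path | None = None
    precision: int = 2

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("methods must be non-empty")
        unknown = [m for m in self.methods if m not in EVALUATE_METHODS]
        if unknown:
            raise ConfigError(f"unknown methods: {unknown}")
        if self.precision < 0:
            raise ConfigError("precision must be >= 0")
        if self.sd_mode not in ("mad", "sample_sd"):
            raise ConfigError(f"unknown sd_mode {self.sd_mode!r}")


@dataclass
class EvaluationReport:
    config: RunConfig
    rankings: dict[str, dict[str, StabilityRanking]]   # scope -> method -> ranking
    bestkeeper_tables: dict[str, list[BestKeeperStats]]
    consensus: ConsensusTable | None
    per_tissue_consensus: dict[str, ConsensusTable]
    provenance: dict
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def exit_status(self) -> int:
        return EXIT_PARTIAL if self.failures else EXIT_OK


def _run_methods(dataset: CqDataset, methods, sd_mode: str,
                 grouped: bool) -> dict[str, StabilityRanking]:
    out: dict[str, StabilityRanking] = {}
    for m in methods:
        if m == "bestkeeper":
            out[m] = rank_genes_bestkeeper(dataset, sd_mode=sd_mode)
        elif m == "deltacq":
            out[m] = delta_cq_stability(dataset)
        elif m == "genorm":
            out[m] = genorm_iterative_ranking(dataset).ranking
        elif m == "normfinder":
            if grouped:
                out[m] = normfinder_grouped(dataset).ranking
            else:
                out[m] = normfinder_ungrouped(dataset)
    return out


def run_evaluate(config: RunConfig,
                 dataset: CqDataset | None = None) -> EvaluationReport:
    """Execute every configured method per scope, then aggregate.

    Module errors are captured per scope without aborting the other scopes;
    the report's ``exit_status`` reflects partial failure.
    """
    checksum = None
    if dataset is None:
        if config.input is None:
            raise ConfigError("either a dataset or an input path is required")
        checksum = hashlib.sha256(Path(config.input).read_bytes()).hexdigest()
        dataset = read_cq_table(config.input)
    base = dataset.subset(AnalysisScope.of(conditions=config.conditions))
    grouped = len(config.conditions) >= 2

    scopes: dict[str, CqDataset] = {"all-tissues": base}
    if config.per_tissue:
        for t in base.tissues:
            scopes[t] = base.subset(AnalysisScope.of(tissues=t))

    rankings: dict[str, dict[str, StabilityRanking]] = {}
    bk_tables: dict[str, list[BestKeeperStats]] = {}
    failures: dict[str, str] = {}
    for name, sub in scopes.items():
        try:
            methods = _run_methods(sub, config.methods, config.sd_mode, grouped)
            if len(methods) >= 2:
                methods["reffinder"] = reffinder_rank(methods)
            rankings[name] = methods
            if "bestkeeper" in config.methods:
                bk_tables[name] = bestkeeper_stats(sub, sd_mode=config.sd_mode)
        except (CqValidationError, ValueError) as exc:
            log.error("scope %s failed: %s", name, exc)
            failures[name] = str(exc)

    def _consensus_inputs(methods: Mapping[str, StabilityRanking]):
        return {m: r for m, r in methods.items() if m in CONSENSUS_METHODS}

    consensus = None
    if "all-tissues" in rankings and len(_consensus_inputs(rankings["all-tissues"])) >= 2:
        consensus = consensus_overall(_consensus_inputs(rankings["all-tissues"]),
                                      top_n=config.top_n)
    per_tissue_consensus = {
        name: consensus_overall(_consensus_inputs(methods), top_n=config.top_n)
        for name, methods in rankings.items()
        if name != "all-tissues" and len(_consensus_inputs(methods)) >= 2}

    provenance = {
        "package": "refstab",
        "version": __version__,
        "config": _config_dict(config),
        "input_sha256": checksum,
        "n_samples": len(base.samples),
        "n_genes": len(base.genes),
        "completeness": {k: v for k, v in base.completeness().items()
                         if k != "missing"},
    }
    return EvaluationReport(config=config, rankings=rankings,
                            bestkeeper_tables=bk_tables, consensus=consensus,
                            per_tissue_consensus=per_tissue_consensus,
                            provenance=provenance, failures=failures)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("input", "outdir"):
        if d[key] is not None:
            d[key] = str(d[key])
    d["methods"] = list(d["methods"])
    d["conditions"] = list(d["conditions"])
    return d


# -- rendering --------------------------------------------------------------

_BK_ROWS = [("Geo mean [CP]", "gm"), ("CV", "cv"), ("Min [CP]", "min_cp"),
            ("Max [CP]", "max_cp"), ("Std dev [+- CP]", "sd_cp"),
            ("Min [x-fold]", "xfold_min"), ("Max [x-fold]", "xfold_max"),
            ("Std dev [+- x-fold]", "xfold_sd")]


def render_bestkeeper_table(stats: list[BestKeeperStats],
                            precision: int = 2) -> str:
    """Genes as columns ordered by ascending dispersion; classic row layout."""
    if not stats:
        raise ValueError("no statistics to render")
    ordered = sorted(stats, key=lambda s: s.sd_cp)
    lines = ["statistic\t" + "\t".join(s.gene_symbol for s in ordered)]
    for label, attr in _BK_ROWS:
        cells = [f"{getattr(s, attr):.{precision}f}" for s in ordered]
        lines.append(label + "\t" + "\t".join(cells))
    ranks = pd.Series([s.sd_cp for s in ordered]).rank(method="average")
    lines.append("Ranking\t" + "\t".join(
        f"{r:g}" for r in ranks))
    return "\n".join(lines) + "\n"


def parse_bestkeeper_table(text: str) -> pd.DataFrame:
    """Parse a rendered BestKeeper table back into statistic x gene values."""
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    return df


def render_overall_table(consensus: ConsensusTable) -> str:
    """Most/least-stable blocks; tie groups joined by '/' in a single cell."""
    lines = ["block\tposition\tgenes\tcount"]
    for block, groups in (("most stable", consensus.most_stable),
                          ("least stable", consensus.least_stable)):
        pos = 1
        for group in groups:
            count = (consensus.top_count(group[0]) if block == "most stable"
                     else consensus.bottom_count(group[0]))
            lines.append(f"{block}\t{pos}\t{'/'.join(group)}\t{count}")
            pos += len(group)
    return "\n".join(lines) + "\n"


def report_to_json(report: EvaluationReport) -> str:
    """Machine-readable summary; keys sorted so reruns are byte-identical."""
    doc: dict = {"provenance": report.provenance, "failures": report.failures,
                 "rankings": {}, "consensus": None, "per_tissue_consensus": {}}
    for scope, methods in report.rankings.items():
        doc["rankings"][scope] = {
            m: [{"gene": g, "score": float(s), "rank": float(r)}
                for g, s, r in r_.table.itertuples(index=False)]
            for m, r_ in methods.items()}

    def _cons(c: ConsensusTable) -> dict:
        return {"top_n": c.top_n,
                "counts": {g: {"top": int(row["top_count"]),
                               "bottom": int(row["bottom_count"])}
                           for g, row in c.counts.iterrows()},
                "most_stable": c.most_stable,
                "least_stable": c.least_stable}

    if report.consensus is not None:
        doc["consensus"] = _cons(report.consensus)
    doc["per_tissue_consensus"] = {t: _cons(c)
                                   for t, c in report.per_tissue_consensus.items()}
    return json.dumps(doc, sort_keys=True, indent=1)


def write_report(report: EvaluationReport, outdir: str | Path) -> Path:
    """Write TSV tables and the JSON summary; returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .ranking import ranking_to_tsv
    for scope, methods in report.rankings.items():
        for m, r in methods.items():
            ranking_to_tsv(r, outdir / f"ranking_{scope}_{m}.tsv")
    for scope, stats in report.bestkeeper_tables.items():
        (outdir / f"bestkeeper_{scope}.tsv").write_text(
            render_bestkeeper_table(stats, precision=report.config.precision))
    if report.consensus is not None:
        (outdir / "overall_consensus.tsv").write_text(
            render_overall_table(report.consensus))
    summary = outdir / "summary.json"
    summary.write_text(report_to_json(report))
    return summary


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (keys = field names)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("methods", "conditions"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return RunConfig(**doc)
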