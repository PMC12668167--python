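"""End-to-end pipeline driver.

Stages run in a fixed order -- select -> convert -> per-group meta ->
meta-meta -> bias -> gene-list refinement -> connectivity -> networks ->
enrichment -> pgx -- each optional (a stage is skipped when its inputs
are absent or it is not requested).  Every stage appends a record-count
entry to the run report (input = output + sum of exclusions) and every
exclusion decision is written to a JSON-lines log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd

from . import __version__
from .bias_diagnostics import bias_battery, funnel_data
from .effects import (
    GENOME_WIDE_THRESHOLD,
    effect_from_study,
    select_study_inputs,
)
from .enrichment import pgx_screen
from .errors import ValidationError
from .genelist import build_prepgl, connectivity_filter, merge_panel, refine_to_pgl
from .io import (
    read_associations,
    read_edges,
    read_gmt,
    read_panel,
    read_pgx,
    read_scored_edges,
    write_gene_list,
    write_meta_result,
)
from .meta_engine import GroupSummary, forest_data, meta_meta, pool_random_dl
from .network_stats import build_network, node_statistics, stats_frame

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "select",
    "meta",
    "metameta",
    "bias",
    "refine",
    "network",
    "enrich",
    "pgx",
)


@dataclass
class StageCount:
    stage: str
    n_input: int
    exclusions: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    @property
    def conserved(self) -> bool:
        return self.n_input == self.n_output + sum(self.exclusions.values())


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    stages: list[StageCount] = field(default_factory=list)
    timing_s: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "timing_s": self.timing_s,
            "stages": [
                {
                    "stage": s.stage,
                    "n_input": s.n_input,
                    "exclusions": s.exclusions,
                    "n_output": s.n_output,
                }
                for s in self.stages
            ],
        }


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run (typically loaded from YAML)."""

    trait_groups: dict[str, str] = field(default_factory=dict)  # label -> association TSV
    out_dir: str = "metameta_out"
    significance_threshold: float = GENOME_WIDE_THRESHOLD
    ci_level: float = 0.95
    score_min: float = 0.4
    connectivity_steps: int = 2
    universe_N: int = 20_000
    metameta_mode: str = "pseudo_study"
    conversion: str = "normal"
    trimfill_side: str = "right"
    trimfill_estimator: str = "L0"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    column_map: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None   # symbol -> biotype TSV
    panel_path: str | None = None
    ppi_edges_path: str | None = None
    network_edges_path: str | None = None
    role_map_path: str | None = None
    gmt_paths: tuple[str, ...] = ()
    pgx_path: str | None = None

    def __post_init__(self):
        if not (0 < self.ci_level < 1):
            raise ValidationError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if not (0 < self.significance_threshold <= 1):
            raise ValidationError("significance_threshold must lie in (0, 1]")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValidationError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "gmt_paths" in raw:
            raw["gmt_paths"] = tuple(raw["gmt_paths"])
        return cls(**raw)


class _ExclusionLog:
    def __init__(self, path: Path):
        self._fh = open(path, "w", encoding="utf-8")

    def event(self, stage: str, criterion: str, detail) -> None:
        self._fh.write(json.dumps({"stage": stage, "criterion": criterion, "detail": detail}) + "\n")

    def close(self):
        self._fh.close()


def _read_annotation(path: str | None) -> dict[str, str]:
    if not path:
        return {}
    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the requested stages; write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: str(v) for k, v in config.__dict__.items()})
    log = _ExclusionLog(out / "exclusions.jsonl")
    stage_state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            try:
                _STAGE_FNS[stage](config, stage_state, report, log, out)
            except Exception:
                logger.error("pipeline aborted in stage %r", stage)
                (out / "FAILED_STAGE").write_text(stage + "\n")
                raise
            report.timing_s[stage] = round(time.perf_counter() - t0, 4)
    finally:
        log.close()
        (out / "run_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
    return report


def _stage_select(config, state, report, log, out):
    groups = {}
    for label, path in config.trait_groups.items():
        records, rejects = read_associations(path, config.column_map)
        for line_no, reason in rejects.rows:
            log.event("select", "malformed_row", {"group": label, "line": line_no, "reason": reason})
        inputs = select_study_inputs(records, threshold=config.significance_threshold)
        kept_ids = {s.source_id for s in inputs}
        n_nonsig = sum(
            1 for r in records
            if r.p_value is None or r.sample_size is None or not (r.p_value < config.significance_threshold)
        )
        n_dedup = len(records) - n_nonsig - len(inputs)
        for r in records:
            if r.p_value is None or r.sample_size is None or not (r.p_value < config.significance_threshold):
                log.event("select", "p_above_threshold_or_missing", {"group": label, "study": r.study_id, "rsid": r.rsid})
            elif r.study_id not in kept_ids:
                log.event("select", "duplicate_study", {"group": label, "study": r.study_id, "rsid": r.rsid})
        report.stages.append(
            StageCount(
                stage=f"select:{label}",
                n_input=len(records) + len(rejects),
                exclusions={
                    "malformed": len(rejects),
                    "not_genome_wide_or_missing": n_nonsig,
                    "duplicate_snp_in_study": n_dedup,
                },
                n_output=len(inputs),
            )
        )
        groups[label] = {"records": records, "inputs": inputs}
    state["groups"] = groups


def _stage_meta(config, state, report, log, out):
    groups = state.get("groups", {})
    metas = {}
    for label, g in groups.items():
        if not g["inputs"]:
            log.event("meta", "empty_group", {"group": label})
            continue
        estimates = [effect_from_study(s, method=config.conversion) for s in g["inputs"]]
        result = pool_random_dl(estimates, level=config.ci_level)
        metas[label] = {"result": result, "estimates": estimates}
        write_meta_result(result, out / f"meta_{label}.json")
        forest_data(result, estimates).to_csv(out / f"forest_{label}.csv", index=False)
        report.stages.append(
            StageCount(stage=f"meta:{label}", n_input=len(estimates), n_output=len(estimates))
        )
    state["metas"] = metas


def _stage_metameta(config, state, report, log, out):
    metas = state.get("metas", {})
    if not metas:
        return
    groups = [
        GroupSummary.from_meta_result(m["result"], label=label)
        for label, m in sorted(metas.items())
    ]
    result = meta_meta(groups, mode=config.metameta_mode, level=config.ci_level)
    state["metameta"] = result
    from .effects import effect_from_p_n

    if config.metameta_mode == "pseudo_study":
        units = [effect_from_p_n(g.p_value, g.total_n, source_id=g.label) for g in groups]
    else:
        units = [m["result"].as_effect(label) for label, m in sorted(metas.items())]
    state["metameta_units"] = units
    write_meta_result(result, out / "metameta.json")
    forest_data(result, units).to_csv(out / "forest_metameta.csv", index=False)
    report.stages.append(StageCount(stage="metameta", n_input=len(groups), n_output=len(groups)))


def _stage_bias(config, state, report, log, out):
    units = state.get("metameta_units")
    if not units:
        return
    battery = bias_battery(
        units,
        side=config.trimfill_side,
        estimator=config.trimfill_estimator,
        level=config.ci_level,
    )
    (out / "bias_report.json").write_text(
        json.dumps(battery.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    funnel_data(units).to_csv(out / "funnel.csv", index=False)
    report.stages.append(StageCount(stage="bias", n_input=len(units), n_output=len(units)))


def _stage_refine(config, state, report, log, out):
    groups = state.get("groups", {})
    records = [r for g in groups.values() for r in g["records"]]
    if not records:
        return
    annotation = _read_annotation(config.annotation_path)
    prepgl = build_prepgl(records, annotation, threshold=config.significance_threshold)
    pgl_coding = refine_to_pgl(prepgl, annotation)
    n_noncoding = len(prepgl) - len(pgl_coding)
    for g in prepgl:
        if g not in pgl_coding and all(p.symbol != g.symbol for p in pgl_coding):
            log.event("refine", "noncoding_biotype", {"symbol": g.symbol, "biotype": g.biotype})
    if config.panel_path:
        panel = read_panel(config.panel_path, name="panel")
    else:
        from .io import gars_panel

        panel = gars_panel()
    pgl = merge_panel(pgl_coding, panel)
    write_gene_list(prepgl, out / "prepgl.tsv")
    write_gene_list(pgl, out / "pgl.tsv")
    report.stages.append(
        StageCount(
            stage="refine",
            n_input=len(prepgl) + len(panel.symbols),
            exclusions={
                "noncoding_biotype": n_noncoding,
                "panel_overlap": len(pgl_coding) + len(panel.symbols) - len(pgl),
            },
            n_output=len(pgl),
        )
    )
    state["pgl"] = pgl
    if config.ppi_edges_path:
        edges = read_scored_edges(config.ppi_edges_path)
        sgl = connectivity_filter(pgl, edges, score_min=config.score_min, steps=config.connectivity_steps)
        for g in pgl:
            if g not in sgl:
                log.event("refine", "unconnected", {"symbol": g.symbol})
        write_gene_list(sgl, out / "sgl.tsv")
        report.stages.append(
            StageCount(
                stage="connectivity",
                n_input=len(pgl),
                exclusions={"unconnected": len(pgl) - len(sgl)},
                n_output=len(sgl),
            )
        )
        state["sgl"] = sgl


def _stage_network(config, state, report, log, out):
    if not config.network_edges_path or not config.role_map_path:
        return
    edges = read_edges(config.network_edges_path)
    roles = pd.read_csv(config.role_map_path, sep="\t", dtype=str)
    role_map = dict(zip(roles.iloc[:, 0], roles.iloc[:, 1]))
    graph = build_network(edges, role_map)
    stats = node_statistics(graph)
    stats_frame(stats).to_csv(out / "node_stats.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(graph, out / "network.graphml")
    report.stages.append(
        StageCount(stage="network", n_input=len(edges), n_output=graph.number_of_edges())
    )
    state["graph"] = graph


def _stage_enrich(config, state, report, log, out):
    sgl = state.get("sgl") or state.get("pgl")
    if not sgl or not config.gmt_paths:
        return
    from .enrichment import enrich_library

    query = [g.symbol for g in sgl]
    for path in config.gmt_paths:
        library = read_gmt(path)
        results = enrich_library(query, library, universe_N=config.universe_N)
        pd.DataFrame([r.to_dict() for r in results]).to_csv(
            out / f"enrichment_{Path(path).stem}.tsv", sep="\t", index=False
        )
        report.stages.append(
            StageCount(stage=f"enrich:{Path(path).stem}", n_input=len(library), n_output=len(results))
        )


def _stage_pgx(config, state, report, log, out):
    sgl = state.get("sgl") or state.get("pgl")
    if not sgl:
        return
    if config.pgx_path:
        table = read_pgx(config.pgx_path)
    else:
        from .io import pgx_annotations

        table = pgx_annotations()
    filtered, counts, total = pgx_screen([g.symbol for g in sgl], table)
    filtered.to_csv(out / "pgx_screen.tsv", sep="\t", index=False)
    counts.rename("n_annotations").to_csv(out / "pgx_counts.tsv", sep="\t")
    report.stages.append(
        StageCount(
            stage="pgx",
            n_input=len(table),
            exclusions={"gene_not_in_list": len(table) - total},
            n_output=total,
        )
    )


_STAGE_FNS = {
    "select": _stage_select,
    "meta": _stage_meta,
    "metameta": _stage_metameta,
    "bias": _stage_bias,
    "refine": _stage_refine,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "pgx": _stage_pgx,
}
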