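"""End-to-end orchestration: enumerate -> quantify -> both arms -> consensus
-> enrichment, with a JSON run summary and schema validation helpers.

All thresholds default to the values the analysis is calibrated around:
count-arm FDR < 0.05; graph-arm posterior probability > 0.8 with
|delta PSI| >= 0.1; >= 3 same-sign studies in one arm plus >= 1 confirming
study in the other; UpSet observation threshold 5; enrichment p < 0.01 with
FDR < 0.2.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import count_test, graph_test, io as smio, psi as psi_mod
from .enrichment import GeneSetCollection, enrich
from .events import enumerate_se_events

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_stages", "run_pipeline", "validate_tables"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode for one pipeline run."""

    annotation: str | None = None
    counts: str | None = None
    events: str | None = None  # precomputed event table (alternative to annotation)
    gene_sets: str | None = None
    output_dir: str = "splicemeta_out"

    alpha: float = 0.05
    prob_min: float = 0.8
    dpsi_min: float = 0.1
    min_studies: int = 3
    min_other: int = 1
    observation_threshold: int = 5
    enrich_p: float = 0.01
    enrich_fdr: float = 0.2

    mode: str = "JC"
    overdispersion: float = 0.0
    posterior_samples: int = graph_test.DEFAULT_SAMPLES
    seed: int = graph_test.DEFAULT_SEED

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("prob_min", 0.0, 1.0),
            ("dpsi_min", 0.0, 1.0),
            ("enrich_p", 0.0, 1.0),
            ("enrich_fdr", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")
        if self.min_studies < 1 or self.min_other < 0 or self.observation_threshold < 0:
            raise ValueError("study/support thresholds out of range")
        if self.mode not in ("JC", "JCEC"):
            raise ValueError(f"mode must be 'JC' or 'JCEC', got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory results of one run."""

    events: pd.DataFrame
    psi: pd.DataFrame
    deltas: pd.DataFrame
    calls_count: pd.DataFrame
    calls_graph: pd.DataFrame
    stable: list
    stable_table: pd.DataFrame
    intersections: dict[str, list[dict]]
    enrichment: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def run_stages(
    events: pd.DataFrame, counts: pd.DataFrame, config: PipelineConfig,
    gene_sets: GeneSetCollection | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory tables."""
    study_ids = sorted(counts["study_id"].unique())
    gene_of = dict(zip(events["event_id"], events["gene_id"]))

    annotated = psi_mod.psi_table(counts, events=events, mode=config.mode)
    deltas = psi_mod.group_delta_table(annotated)

    calls_count = count_test.count_arm(
        annotated, alpha=config.alpha, overdispersion=config.overdispersion
    )
    calls_graph = graph_test.graph_arm(
        counts,
        prob_min=config.prob_min,
        dpsi_min=config.dpsi_min,
        n_samples=config.posterior_samples,
        seed=config.seed,
    )
    for calls in (calls_count, calls_graph):
        calls["gene_id"] = calls["event_id"].map(gene_of)

    stable = consensus_mod.cross_arm_stable(
        calls_count,
        calls_graph,
        min_studies=config.min_studies,
        min_other=config.min_other,
    )
    stable_table = smio.stable_records_to_table(stable, study_ids)
    intersections = {
        arm: consensus_mod.intersection_counts(
            calls, observation_threshold=config.observation_threshold
        )
        for arm, calls in (("count", calls_count), ("graph", calls_graph))
    }

    enrichment_table = None
    if gene_sets is not None and stable:
        stable_genes = sorted({rec.gene_id for rec in stable if rec.gene_id})
        if stable_genes:
            enrichment_table = enrich(
                stable_genes, gene_sets, p_max=config.enrich_p, fdr_max=config.enrich_fdr
            )

    summary = {
        "n_studies": len(study_ids),
        "n_events": int(events["event_id"].nunique()),
        "n_events_tested_count": int(calls_count["event_id"].nunique()),
        "n_events_tested_graph": int(calls_graph["event_id"].nunique()),
        "n_significant_count": int(
            calls_count.loc[calls_count["significant"], "event_id"].nunique()
        ),
        "n_significant_graph": int(
            calls_graph.loc[calls_graph["significant"], "event_id"].nunique()
        ),
        "n_stable": len(stable),
        "n_stable_genes": len({rec.gene_id for rec in stable}),
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "alpha",
                "prob_min",
                "dpsi_min",
                "min_studies",
                "min_other",
                "observation_threshold",
                "enrich_p",
                "enrich_fdr",
            )
        },
        "mode": config.mode,
        "seed": config.seed,
    }
    return PipelineResult(
        events=events,
        psi=annotated[smio.PSI_COLUMNS],
        deltas=deltas,
        calls_count=calls_count,
        calls_graph=calls_graph,
        stable=stable,
        stable_table=stable_table,
        intersections=intersections,
        enrichment=enrichment_table,
        summary=summary,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based run: read inputs, execute all stages, write every output.

    Returns the run summary (also written as ``summary.json``).  Missing
    inputs raise FileNotFoundError naming the path; a failure in a later
    stage keeps the outputs already written and marks the stage in the
    summary.
    """
    t0 = time.time()
    os.makedirs(config.output_dir, exist_ok=True)
    summary: dict = {"failed_stage": None}

    def _out(name: str) -> str:
        return os.path.join(config.output_dir, name)

    stage = "inputs"
    try:
        for label, path in (("annotation", config.annotation), ("counts", config.counts),
                            ("events", config.events), ("gene_sets", config.gene_sets)):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label} file not found: {path}")
        if config.counts is None:
            raise ValueError("a count table is required")
        counts = smio.read_count_table(config.counts)

        stage = "enumerate"
        if config.events is not None:
            events = smio.read_event_table(config.events)
        elif config.annotation is not None:
            events = smio.events_to_table(enumerate_se_events(config.annotation))
        else:
            raise ValueError("either an annotation GTF or an event table is required")
        smio.write_table(events, _out("events.tsv"))

        known = set(events["event_id"])
        unknown = set(counts["event_id"]) - known
        if unknown:
            raise ValueError(
                f"{len(unknown)} count-table events absent from the event table, "
                f"e.g. {sorted(unknown)[0]!r}"
            )

        stage = "analysis"
        gene_sets = (
            smio.read_gmt(config.gene_sets) if config.gene_sets is not None else None
        )
        result = run_stages(events, counts, config, gene_sets=gene_sets)

        stage = "outputs"
        smio.write_table(result.psi, _out("psi.tsv"))
        smio.write_table(result.deltas, _out("delta_psi.tsv"))
        smio.write_calls_table(result.calls_count, _out("calls_count.tsv"))
        smio.write_calls_table(result.calls_graph, _out("calls_graph.tsv"))
        smio.write_table(result.stable_table, _out("stable_das.tsv"))
        smio.write_bed6(result.stable, _out("stable_das.bed"))
        for arm, records in result.intersections.items():
            smio.write_intersections(records, _out(f"intersections_{arm}.json"))
        if result.enrichment is not None:
            smio.write_table(result.enrichment, _out("enrichment.tsv"))
        summary.update(result.summary)
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        with open(_out("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise
    summary["runtime_seconds"] = round(time.time() - t0, 3)
    summary["config"] = asdict(config)
    with open(_out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("pipeline finished: %d stable events", summary["n_stable"])
    return summary


def validate_tables(
    counts_path=None, events_path=None
) -> list[dict]:
    """Schema and invariant checks; returns violations with line numbers.

    Line numbers refer to the TSV data rows (header = line 1).
    """
    violations: list[dict] = []

    def _add(table, line, message):
        violations.append({"table": table, "line": line, "message": message})

    if events_path is not None:
        try:
            events = smio.read_event_table(events_path)
        except ValueError as exc:
            _add("events", None, str(exc))
            events = None
        if events is not None:
            for idx, row in events.iterrows():
                line = idx + 2
                if row["event_class"] not in ("SE", "MXE", "A5SS", "A3SS", "RI"):
                    _add("events", line, f"unknown event class {row['event_class']!r}")
                if row["strand"] not in ("+", "-"):
                    _add("events", line, f"bad strand {row['strand']!r}")
                if row["target_end"] <= row["target_start"]:
                    _add("events", line, "target end must exceed target start")
                elif not (
                    row["upstream_flank_end"] <= row["target_start"]
                    and row["target_end"] <= row["downstream_flank_start"]
                ):
                    _add("events", line, "flanks overlap the target")
            dup = events["event_id"].duplicated()
            for idx in events.index[dup]:
                _add("events", idx + 2, f"duplicate event_id {events.at[idx, 'event_id']!r}")

    if counts_path is not None:
        try:
            counts = smio.read_count_table(counts_path)
        except ValueError as exc:
            _add("counts", None, str(exc))
            counts = None
        if counts is not None:
            for idx, row in counts.iterrows():
                line = idx + 2
                if row["group"] not in ("fat", "thin"):
                    _add("counts", line, f"unknown group {row['group']!r}")
                if row["inclusion_count"] < 0 or row["skipping_count"] < 0:
                    _add("counts", line, "negative read count")
                if row["read_length"] < 2:
                    _add("counts", line, "read_length must be >= 2")
            dup = counts.duplicated(subset=["event_id", "study_id", "replicate_id"])
            for idx in counts.index[dup]:
                _add("counts", idx + 2, "duplicate (event, study, replicate) row")
    return violations
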