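"""Table and format round-tripping: TSV schemas, GTF/GMT readers, BED writer.

Every pipeline artefact is a plain-text table with a fixed schema so each
stage can be run, inspected and re-fed independently.
"""

from __future__ import annotations

import json

import pandas as pd

from .consensus import ConsensusRecord
from .enrichment import GeneSetCollection
from .events import SpliceEvent, canonical_key, event_id

EVENT_COLUMNS = [
    "event_id",
    "event_class",
    "chrom",
    "strand",
    "target_start",
    "target_end",
    "upstream_flank_end",
    "downstream_flank_start",
    "gene_id",
]
COUNT_COLUMNS = [
    "event_id",
    "study_id",
    "replicate_id",
    "group",
    "inclusion_count",
    "skipping_count",
    "read_length",
]
PSI_COLUMNS = ["event_id", "study_id", "replicate_id", "group", "psi"]
CALL_COLUMNS = [
    "event_id",
    "gene_id",
    "study_id",
    "arm",
    "delta_psi",
    "stat",
    "p_value",
    "fdr",
    "significant",
]

__all__ = [
    "EVENT_COLUMNS",
    "COUNT_COLUMNS",
    "PSI_COLUMNS",
    "CALL_COLUMNS",
    "events_to_table",
    "read_event_table",
    "read_count_table",
    "write_table",
    "read_calls_table",
    "write_calls_table",
    "stable_records_to_table",
    "write_bed6",
    "read_gmt",
    "write_intersections",
    "read_intersections",
]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def events_to_table(events: list[SpliceEvent]) -> pd.DataFrame:
    """Event-table frame for a list of enumerated events."""
    rows = []
    for ev in events:
        key = canonical_key(ev)
        rows.append(
            {
                "event_id": event_id(key),
                "event_class": key.event_class,
                "chrom": key.chrom,
                "strand": key.strand,
                "target_start": key.target_start,
                "target_end": key.target_end,
                "upstream_flank_end": key.upstream_end,
                "downstream_flank_start": key.downstream_start,
                "gene_id": ev.gene_id,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, EVENT_COLUMNS, f"event table {path}")
    return df


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "replicate_id": str})
    _require(df, COUNT_COLUMNS, f"count table {path}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_calls_table(calls: pd.DataFrame, path) -> None:
    """Write one arm's calls with the shared schema.

    The count arm fills p_value/fdr and puts the LRT statistic in ``stat``;
    the graph arm puts the posterior probability in ``stat`` and leaves
    p_value/fdr empty.
    """
    out = calls.copy()
    for col in CALL_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str})
    _require(df, CALL_COLUMNS, f"calls table {path}")
    df["significant"] = df["significant"].astype(bool)
    return df


def stable_records_to_table(
    records: list[ConsensusRecord], study_ids: list[str]
) -> pd.DataFrame:
    """Stable-set frame: one row per stable event, per-arm per-study deltas."""
    rows = []
    for rec in records:
        row = {
            "event_id": rec.event_id,
            "gene_id": rec.gene_id,
            "sign": rec.consensus_sign,
            "primary_arm": rec.primary_arm,
            "n_support_primary": rec.n_support_primary,
            "n_support_other": rec.n_support_other,
            "mean_delta_psi": rec.mean_delta_psi,
        }
        for arm in ("count", "graph"):
            for study in study_ids:
                row[f"dpsi_{arm}_{study}"] = rec.support.get(arm, {}).get(study)
        rows.append(row)
    base = [
        "event_id",
        "gene_id",
        "sign",
        "primary_arm",
        "n_support_primary",
        "n_support_other",
        "mean_delta_psi",
    ]
    extra = [f"dpsi_{arm}_{s}" for arm in ("count", "graph") for s in study_ids]
    return pd.DataFrame(rows, columns=base + extra)


def write_bed6(records: list[ConsensusRecord], path) -> None:
    """BED6 for stable events: name = gene|event, score = 1000 |mean dPSI|."""
    from .events import key_from_event_id

    with open(path, "w") as fh:
        for rec in records:
            key = key_from_event_id(rec.event_id)
            score = int(round(min(1.0, abs(rec.mean_delta_psi)) * 1000))
            name = f"{rec.gene_id}|{rec.event_id}"
            fh.write(
                f"{key.chrom}\t{key.target_start}\t{key.target_end}"
                f"\t{name}\t{score}\t{key.strand}\n"
            )


def read_gmt(path, background_size: int | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, members...).

    Without an explicit background size, the union of all member genes is
    used as the background universe.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, genes")
            term, _description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {term!r} is empty")
            sets[term] = set(genes)
    universe = set().union(*sets.values()) if sets else set()
    if background_size is None:
        return GeneSetCollection(
            sets=sets, background_size=len(universe), background_genes=universe
        )
    return GeneSetCollection(sets=sets, background_size=background_size)


def write_intersections(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")


def read_intersections(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
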