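"""Splicing-event domain objects and skipped-exon enumeration from annotation.

All internal coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted on read.  An event's identity across tools and studies is its
:class:`EventKey`, a canonical coordinate tuple that is independent of which
arm produced the call.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import gffutils

EVENT_CLASSES = ("SE", "MXE", "A5SS", "A3SS", "RI")

__all__ = [
    "EVENT_CLASSES",
    "GenomicInterval",
    "SpliceEvent",
    "EventKey",
    "GTFParseError",
    "canonical_key",
    "event_id",
    "key_from_event_id",
    "enumerate_se_events",
    "match_events",
]


class GTFParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    ``target`` is the skipped exon for SE, the retained intron for RI; MXE
    carries the second alternative exon in ``target_alt``.  Flanks are ordered
    on the genome axis (``flank_upstream`` is genomically left), so the
    invariant ``flank_upstream.end <= target.start <= target.end <=
    flank_downstream.start`` holds regardless of strand.
    """

    event_class: str
    gene_id: str
    target: GenomicInterval
    flank_upstream: GenomicInterval
    flank_downstream: GenomicInterval
    target_alt: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        parts = [self.target, self.flank_upstream, self.flank_downstream]
        if self.target_alt is not None:
            parts.append(self.target_alt)
        chroms = {p.chrom for p in parts}
        strands = {p.strand for p in parts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("all intervals of an event must share chrom and strand")
        if not (
            self.flank_upstream.end <= self.target.start
            and self.target.end <= self.flank_downstream.start
        ):
            raise ValueError("flanks must not overlap the target on the genome axis")


class EventKey(NamedTuple):
    """Canonical identity of an event: equal keys mean the same event."""

    event_class: str
    chrom: str
    strand: str
    target_start: int
    target_end: int
    upstream_end: int
    downstream_start: int


def canonical_key(event: SpliceEvent) -> EventKey:
    """Canonical, arm-independent identity tuple for *event*."""
    return EventKey(
        event.event_class,
        event.target.chrom,
        event.target.strand,
        event.target.start,
        event.target.end,
        event.flank_upstream.end,
        event.flank_downstream.start,
    )


def event_id(key: EventKey | SpliceEvent) -> str:
    """Stable string form of an event key, used as the ``event_id`` column."""
    if isinstance(key, SpliceEvent):
        key = canonical_key(key)
    return (
        f"{key.event_class}:{key.chrom}:{key.strand}:"
        f"{key.target_start}-{key.target_end}:"
        f"{key.upstream_end}:{key.downstream_start}"
    )


def key_from_event_id(eid: str) -> EventKey:
    """Inverse of :func:`event_id`."""
    try:
        cls, chrom, strand, span, up_end, down_start = eid.split(":")
        t_start, t_end = span.split("-")
        return EventKey(
            cls, chrom, strand, int(t_start), int(t_end), int(up_end), int(down_start)
        )
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed event_id {eid!r}") from exc


def _prescan_gtf(path: str) -> None:
    # gffutils does not report line numbers for malformed rows, so validate
    # field structure first and raise with the offending line.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise GTFParseError(f"line {lineno}: end < start ({end} < {start})")
            if fields[6] not in ("+", "-", "."):
                raise GTFParseError(f"line {lineno}: bad strand {fields[6]!r}")


def _exons_by_transcript(gtf_path: str) -> dict[tuple[str, str], list[GenomicInterval]]:
    """Map (gene_id, transcript_id) -> genomically sorted exon intervals."""
    _prescan_gtf(gtf_path)
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[tuple[str, str], list[GenomicInterval]] = {}
    for exon in db.features_of_type("exon"):
        try:
            gene = exon.attributes["gene_id"][0]
            tx = exon.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GTFParseError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks {exc} attribute"
            ) from None
        interval = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        transcripts.setdefault((gene, tx), []).append(interval)
    for exons in transcripts.values():
        exons.sort(key=lambda iv: (iv.start, iv.end))
    return transcripts


def enumerate_se_events(annotation: str | os.PathLike) -> list[SpliceEvent]:
    """Enumerate skipped-exon events from a GTF annotation.

    An SE event exists for a (gene, exon B, flanks A/C) triple when one
    transcript of the gene contains exons A, B, C consecutively (no other exon
    of that transcript between them) and another transcript contains A and C
    consecutively without B.  Exon identity is by exact coordinates.  Events
    are deduplicated by :func:`canonical_key` and sorted by
    (chrom, target.start).
    """
    transcripts = _exons_by_transcript(str(annotation))

    by_gene: dict[str, list[list[GenomicInterval]]] = {}
    for (gene, _tx), exons in transcripts.items():
        by_gene.setdefault(gene, []).append(exons)

    seen: dict[EventKey, SpliceEvent] = {}
    for gene, chains in sorted(by_gene.items()):
        # adjacent exon pairs over all transcripts of the gene
        adjacent: set[tuple[GenomicInterval, GenomicInterval]] = set()
        for chain in chains:
            adjacent.update(zip(chain, chain[1:]))
        for chain in chains:
            for up, target, down in zip(chain, chain[1:], chain[2:]):
                if (up, down) not in adjacent:
                    continue
                event = SpliceEvent(
                    event_class="SE",
                    gene_id=gene,
                    target=target,
                    flank_upstream=up,
                    flank_downstream=down,
                )
                seen.setdefault(canonical_key(event), event)
    return sorted(
        seen.values(), key=lambda e: (e.target.chrom, e.target.start, e.target.end)
    )


def match_events(
    calls_a: Sequence, calls_b: Sequence
) -> list[tuple[EventKey, list, list]]:
    """Exact-key join of per-study calls from two arms.

    Every call must expose ``event_key``, ``study_id`` and ``arm`` attributes
    (or mapping items).  Events present in only one input appear with an empty
    partner list.  Duplicate (key, study, arm) entries within one input are an
    error: each arm produces at most one call per event per study.
    """

    def _field(call, name):
        return call[name] if isinstance(call, dict) else getattr(call, name)

    def _index(calls: Iterable) -> dict[EventKey, list]:
        out: dict[EventKey, list] = {}
        seen: set[tuple] = set()
        for call in calls:
            key = _field(call, "event_key")
            ident = (key, _field(call, "study_id"), _field(call, "arm"))
            if ident in seen:
                raise ValueError(f"duplicate call for {ident}")
            seen.add(ident)
            out.setdefault(key, []).append(call)
        return out

    index_a = _index(calls_a)
    index_b = _index(calls_b)
    keys = sorted(set(index_a) | set(index_b))
    return [(k, index_a.get(k, []), index_b.get(k, [])) for k in keys]
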