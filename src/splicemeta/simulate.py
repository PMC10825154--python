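"""Synthetic multi-study inclusion/skipping count data with known truth.

The generator emulates the study design of a seven-dataset fat-tailed vs
thin-tailed sheep comparison: two groups, 3-4 biological replicates per group
per study, study-specific read lengths, and a subset of truly differential
events whose delta-PSI sign is shared by a configurable number of studies.

Per event, study, replicate:

* a baseline PSI is drawn once per event from Uniform(0.05, 0.95);
* differential events shift the two group PSIs by +/- effect/2 (clipped to
  [0.01, 0.99]) with the event's fixed sign, in the carrying studies only;
* the replicate PSI is Beta-distributed around the group PSI with dispersion
  rho (mean psi, variance rho psi (1 - psi); rho = 0 means no
  extra-binomial noise);
* the replicate total is Poisson(depth) and the inclusion count binomial
  with read-level proportion theta = lI psi / (lI psi + lS (1 - psi)) using
  the study's read length and junction-count effective lengths.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .events import EventKey, event_id
from .psi import effective_lengths

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimResult", "ToyFixture", "simulate", "make_toy_fixture"]

#: Replicate layout and read lengths mirroring the seven public datasets
#: (fat group sizes, thin group sizes, read length per study).
DEFAULT_REPLICATES_FAT = (4, 3, 3, 3, 3, 3, 3)
DEFAULT_REPLICATES_THIN = (4, 3, 3, 3, 3, 4, 3)
DEFAULT_READ_LENGTHS = (150, 75, 150, 150, 101, 150, 150)


@dataclass
class SimConfig:
    """Parameters of one synthetic multi-study experiment."""

    n_studies: int = 7
    replicates_fat: tuple[int, ...] = DEFAULT_REPLICATES_FAT
    replicates_thin: tuple[int, ...] = DEFAULT_REPLICATES_THIN
    read_lengths: tuple[int, ...] = DEFAULT_READ_LENGTHS
    n_events: int = 1000
    frac_das: float = 0.1
    effect_size: float = 0.3
    study_sharing: int = 5
    depth: float = 100.0
    dispersion: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("replicates_fat", "replicates_thin", "read_lengths"):
            if len(getattr(self, name)) != self.n_studies:
                raise ValueError(f"{name} must have one entry per study")
        if min(self.replicates_fat + self.replicates_thin) < 1:
            raise ValueError("every study needs at least one replicate per group")
        if not 0.0 <= self.frac_das <= 1.0:
            raise ValueError("frac_das must lie in [0, 1]")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must lie in [0, 1)")
        if not 0 < self.study_sharing <= self.n_studies:
            raise ValueError("study_sharing must lie in (0, n_studies]")
        if self.depth <= 0 or self.n_events <= 0 or self.effect_size < 0:
            raise ValueError("depth and n_events must be positive, effect_size >= 0")

    @property
    def study_ids(self) -> list[str]:
        return [f"study{i + 1}" for i in range(self.n_studies)]


class SimResult(NamedTuple):
    events: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame


def _synthetic_event_table(n_events: int, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping synthetic SE events on one synthetic chromosome."""
    rows = []
    spacing = 10_000
    target_lengths = rng.integers(60, 301, size=n_events)
    for i in range(n_events):
        offset = i * spacing
        up_start, up_end = offset + 100, offset + 300
        t_start = offset + 400
        t_end = t_start + int(target_lengths[i])
        down_start = t_end + 100
        rows.append(
            {
                "event_id": event_id(
                    EventKey("SE", "chrS", "+", t_start, t_end, up_end, down_start)
                ),
                "event_class": "SE",
                "chrom": "chrS",
                "strand": "+",
                "target_start": t_start,
                "target_end": t_end,
                "upstream_flank_end": up_end,
                "downstream_flank_start": down_start,
                "gene_id": f"GENE{i:05d}",
            }
        )
    return pd.DataFrame(rows)


def simulate(config: SimConfig) -> SimResult:
    """Generate (event table, count table, truth table) for one experiment."""
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    events = _synthetic_event_table(n, rng)

    baseline = rng.uniform(0.05, 0.95, size=n)
    n_das = int(round(n * config.frac_das))
    is_das = np.zeros(n, dtype=bool)
    das_idx = rng.choice(n, size=n_das, replace=False)
    is_das[das_idx] = True
    sign = np.zeros(n, dtype=int)
    sign[das_idx] = rng.choice([-1, 1], size=n_das)
    carrying = np.zeros((n, config.n_studies), dtype=bool)
    for i in das_idx:
        studies = rng.choice(config.n_studies, size=config.study_sharing, replace=False)
        carrying[i, studies] = True

    half = config.effect_size / 2.0
    psi_fat = np.tile(baseline[:, None], (1, config.n_studies))
    psi_thin = psi_fat.copy()
    shift = np.where(carrying, sign[:, None] * half, 0.0)
    psi_fat = psi_fat + shift
    psi_thin = psi_thin - shift
    n_clipped = int(np.sum((psi_fat < 0.01) | (psi_fat > 0.99) | (psi_thin < 0.01) | (psi_thin > 0.99)))
    if n_clipped:
        logger.warning("%d group PSIs clipped into [0.01, 0.99]", n_clipped)
    psi_fat = np.clip(psi_fat, 0.01, 0.99)
    psi_thin = np.clip(psi_thin, 0.01, 0.99)

    rho = config.dispersion
    frames = []
    for s, study in enumerate(config.study_ids):
        read_len = config.read_lengths[s]
        l_inc, l_skip = effective_lengths(None, read_len, mode="JC")
        for group, group_psi, n_reps in (
            ("fat", psi_fat[:, s], config.replicates_fat[s]),
            ("thin", psi_thin[:, s], config.replicates_thin[s]),
        ):
            for r in range(n_reps):
                if rho > 0.0:
                    rep_psi = rng.beta(
                        group_psi * (1.0 - rho) / rho,
                        (1.0 - group_psi) * (1.0 - rho) / rho,
                    )
                else:
                    rep_psi = group_psi
                theta = l_inc * rep_psi / (l_inc * rep_psi + l_skip * (1.0 - rep_psi))
                totals = rng.poisson(config.depth, size=n)
                inc = rng.binomial(totals, theta)
                frames.append(
                    pd.DataFrame(
                        {
                            "event_id": events["event_id"],
                            "study_id": study,
                            "replicate_id": f"{study}_{group}_r{r + 1}",
                            "group": group,
                            "inclusion_count": inc,
                            "skipping_count": totals - inc,
                            "read_length": read_len,
                        }
                    )
                )
    counts = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame(
        {
            "event_id": events["event_id"],
            "gene_id": events["gene_id"],
            "is_das": is_das,
            "true_sign": np.where(is_das, np.where(sign > 0, "+", "-"), ""),
            "carrying_studies": [
                ",".join(
                    study for study, c in zip(config.study_ids, carrying[i]) if c
                )
                for i in range(n)
            ],
            "baseline_psi": baseline,
        }
    )
    for s, study in enumerate(config.study_ids):
        truth[f"psi_fat_{study}"] = psi_fat[:, s]
        truth[f"psi_thin_{study}"] = psi_thin[:, s]
    return SimResult(events=events, counts=counts, truth=truth)


# ---------------------------------------------------------------------------
# Hand-built 12-event consensus fixture
# ---------------------------------------------------------------------------

#: Per-replicate (inclusion, skipping) count templates, three replicates per
#: group per study, 100 bp reads (JC effective lengths 198/99, so the
#: count-arm PSI is I / (I + 2 S) and the graph arm pools raw fractions).
#:
#: NULL       both groups identical             -> no call in either arm
#: *_BIG      huge, strongly separated counts   -> called by both arms
#: *_CNT      |delta PSI| = 0.08 at high depth  -> count arm only (graph
#:            posterior-mean gap 0.071 < 0.1)
#: *_GRAPH    small counts, raw gap 0.143       -> graph arm only (LRT
#:            p = 0.18, never below the FDR threshold)
_TOY_TEMPLATES: dict[str, tuple[list[tuple[int, int]], list[tuple[int, int]]]] = {
    "NULL": ([(50, 25)] * 3, [(50, 25)] * 3),
    "NEG_BIG": ([(200, 400)] * 3, [(800, 100)] * 3),
    "POS_BIG": ([(800, 100)] * 3, [(200, 400)] * 3),
    "NEG_CNT": ([(4600, 2700)] * 3, [(5400, 2300)] * 3),
    "POS_CNT": ([(5400, 2300)] * 3, [(4600, 2700)] * 3),
    "NEG_GRAPH": ([(6, 8), (6, 8), (5, 7)], [(8, 6), (8, 6), (7, 5)]),
    "POS_GRAPH": ([(8, 6), (8, 6), (7, 5)], [(6, 8), (6, 8), (5, 7)]),
}

#: Which template each event uses in each study (studies not listed: NULL).
#: The design exercises every branch of the consensus rule; the four events
#: E01-E04 are the ones that must come out stable.
_TOY_DESIGN: dict[str, dict[str, str]] = {
    # stable: both arms, five studies (also stable at min_studies = 4)
    "E01": {s: "NEG_BIG" for s in ("study1", "study2", "study3", "study4", "study5")},
    # stable: both arms, exactly three studies
    "E02": {s: "NEG_BIG" for s in ("study1", "study2", "study3")},
    # stable: count arm 3 studies, graph arm confirms in one other study
    "E03": {"study1": "NEG_CNT", "study2": "NEG_CNT", "study3": "NEG_CNT",
            "study5": "NEG_GRAPH"},
    # stable: graph arm 3 studies (positive), count arm confirms once
    "E04": {"study1": "POS_GRAPH", "study2": "POS_GRAPH", "study3": "POS_GRAPH",
            "study6": "POS_CNT"},
    # only two supporting studies
    "E05": {"study1": "NEG_BIG", "study2": "NEG_BIG"},
    # count arm reaches three studies but the graph arm never confirms
    "E06": {"study1": "NEG_CNT", "study2": "NEG_CNT", "study3": "NEG_CNT"},
    # cross-arm confirmation exists but with the opposite sign
    "E07": {"study1": "NEG_CNT", "study2": "NEG_CNT", "study3": "NEG_CNT",
            "study4": "POS_GRAPH"},
    # ambiguous trend: three negative and three positive studies
    "E08": {"study1": "NEG_BIG", "study2": "NEG_BIG", "study3": "NEG_BIG",
            "study4": "POS_BIG", "study5": "POS_BIG", "study6": "POS_BIG"},
    # graph arm reaches three studies but the count arm never confirms
    "E09": {"study1": "NEG_GRAPH", "study2": "NEG_GRAPH", "study3": "NEG_GRAPH"},
    # never differential anywhere
    "E10": {},
    # one study per sign
    "E11": {"study1": "NEG_BIG", "study2": "POS_BIG"},
    # two studies per arm: neither arm alone reaches three
    "E12": {"study1": "NEG_CNT", "study2": "NEG_CNT",
            "study3": "NEG_GRAPH", "study4": "NEG_GRAPH"},
}

_TOY_STUDIES = [f"study{i}" for i in range(1, 8)]
_TOY_READ_LENGTH = 100


@dataclass
class ToyFixture:
    """The packaged 12-event golden fixture for the consensus rule."""

    gtf_text: str
    events: pd.DataFrame
    counts: pd.DataFrame
    expected_stable: list[str] = field(default_factory=list)
    expected_stable_min4: list[str] = field(default_factory=list)
    gene_of: dict[str, str] = field(default_factory=dict)

    def write(self, directory) -> dict[str, str]:
        """Write gtf/counts/events files into *directory*; returns the paths."""
        import os

        os.makedirs(directory, exist_ok=True)
        paths = {
            "gtf": os.path.join(directory, "toy_annotation.gtf"),
            "counts": os.path.join(directory, "toy_counts.tsv"),
            "events": os.path.join(directory, "toy_events.tsv"),
        }
        with open(paths["gtf"], "w") as fh:
            fh.write(self.gtf_text)
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        self.events.to_csv(paths["events"], sep="\t", index=False)
        return paths


def _toy_gene(index: int, label: str, strand: str) -> tuple[str, dict]:
    """GTF lines and event geometry for one toy gene (two transcripts)."""
    offset = (index - 1) * 10_000
    # 1-based inclusive exon coordinates
    a = (offset + 101, offset + 300)
    b = (offset + 401, offset + 560)
    c = (offset + 661, offset + 860)
    gene = f"TGENE{index:02d}"
    lines = []
    for tx, exons in (("T1", (a, b, c)), ("T2", (a, c))):
        for start, end in exons:
            attrs = f'gene_id "{gene}"; transcript_id "{gene}.{tx}";'
            lines.append(
                f"chr1\ttoy\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
    key = EventKey("SE", "chr1", strand, b[0] - 1, b[1], a[1], c[0] - 1)
    meta = {
        "event_id": event_id(key),
        "event_class": "SE",
        "chrom": "chr1",
        "strand": strand,
        "target_start": b[0] - 1,
        "target_end": b[1],
        "upstream_flank_end": a[1],
        "downstream_flank_start": c[0] - 1,
        "gene_id": gene,
        "label": label,
    }
    return "\n".join(lines), meta


def make_toy_fixture() -> ToyFixture:
    """Regenerate the packaged 12-event, 7-study, hand-designed fixture.

    Four events (E01-E04) satisfy the consensus rule (>= 3 same-sign
    significant studies in one arm plus >= 1 same-sign significant study in
    the other); with the study threshold raised to 4 only E01 survives.
    Counts are deterministic, so both arms' calls follow from the templates.
    """
    gtf_blocks, metas = [], []
    for i, label in enumerate(sorted(_TOY_DESIGN), start=1):
        strand = "-" if i > 10 else "+"
        block, meta = _toy_gene(i, label, strand)
        gtf_blocks.append(block)
        metas.append(meta)
    events = pd.DataFrame(metas)

    rows = []
    for meta in metas:
        design = _TOY_DESIGN[meta["label"]]
        for study in _TOY_STUDIES:
            fat_reps, thin_reps = _TOY_TEMPLATES[design.get(study, "NULL")]
            for group, reps in (("fat", fat_reps), ("thin", thin_reps)):
                for r, (inc, skip) in enumerate(reps, start=1):
                    rows.append(
                        {
                            "event_id": meta["event_id"],
                            "study_id": study,
                            "replicate_id": f"{study}_{group}_r{r}",
                            "group": group,
                            "inclusion_count": inc,
                            "skipping_count": skip,
                            "read_length": _TOY_READ_LENGTH,
                        }
                    )

    label_to_id = dict(zip(events["label"], events["event_id"]))
    fixture = ToyFixture(
        gtf_text="\n".join(gtf_blocks) + "\n",
        events=events.drop(columns="label"),
        counts=pd.DataFrame(rows),
        expected_stable=sorted(
            label_to_id[lbl] for lbl in ("E01", "E02", "E03", "E04")
        ),
        expected_stable_min4=[label_to_id["E01"]],
        gene_of=dict(zip(events["event_id"], events["gene_id"])),
    )
    return fixture
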