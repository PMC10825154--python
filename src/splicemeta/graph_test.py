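"""Splice-graph arm: node PSI and Bayesian posterior delta-PSI calling.

A gene's transcripts are collapsed into a contiguous splice graph whose nodes
are maximal exonic segments (the union of all exons split at every distinct
exon boundary) and whose edges are segment adjacencies observed in any
transcript.  A node's PSI is the fraction of read paths supporting its
inclusion:

    psi = inc / (inc + exc)

For differential calling, counts are pooled within each group and the group
inclusion levels given a uniform prior are

    psi_g | data ~ Beta(inc_g + 1, exc_g + 1)

delta_psi is the difference of posterior means (fat minus thin) and the
reported posterior probability is the Monte-Carlo estimate of
P(sign(psi_fat - psi_thin) = sign(delta_psi)).  An event is differential when
the posterior probability exceeds 0.8 (strict) and |delta_psi| >= 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventKey, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20240129
DEFAULT_SAMPLES = 10_000

__all__ = [
    "SpliceGraph",
    "GraphStudyCall",
    "build_csg",
    "node_psi",
    "posterior_delta",
    "call_das_graph",
    "graph_arm",
]


@dataclass
class SpliceGraph:
    """Contiguous splice graph of one gene.

    ``nodes`` are non-overlapping exonic segments in genomic order; ``edges``
    are directed (i, j) pairs with i < j on the genomic axis.
    """

    gene_id: str
    nodes: list[GenomicInterval]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for left, right in zip(self.nodes, self.nodes[1:]):
            if right.start < left.end:
                raise ValueError("graph nodes must be ordered and non-overlapping")
        for i, j in self.edges:
            if not (0 <= i < j < len(self.nodes)):
                raise ValueError(f"edge ({i}, {j}) does not increase over valid nodes")


@dataclass(frozen=True)
class GraphStudyCall:
    """One event's graph-arm result in one study."""

    event_key: EventKey
    study_id: str
    delta_psi: float
    posterior_prob: float
    significant: bool
    arm: str = "graph"


def build_csg(gene_id: str, transcripts: dict[str, list[GenomicInterval]]) -> SpliceGraph:
    """Build the contiguous splice graph of one gene.

    ``transcripts`` maps transcript id to its exon intervals.  Nodes are the
    maximal segments obtained by splitting the union of all exons at every
    distinct exon boundary; each transcript's exon chain induces edges between
    the consecutive segments it covers.  Deterministic and independent of
    transcript input order.
    """
    if not transcripts or all(len(v) == 0 for v in transcripts.values()):
        raise ValueError("need at least one transcript with at least one exon")
    exons = [e for chain in transcripts.values() for e in chain]
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError("transcripts must come from a single gene locus")
    chrom, strand = chroms.pop(), strands.pop()

    boundaries = sorted({x for e in exons for x in (e.start, e.end)})
    covered = []
    for left, right in zip(boundaries, boundaries[1:]):
        if any(e.start <= left and right <= e.end for e in exons):
            covered.append(GenomicInterval(chrom, left, right, strand))
    index = {(n.start, n.end): i for i, n in enumerate(covered)}

    edges: set[tuple[int, int]] = set()
    for chain in transcripts.values():
        chain = sorted(chain, key=lambda e: e.start)
        path: list[int] = []
        for exon in chain:
            path.extend(
                index[(n.start, n.end)]
                for n in covered
                if exon.start <= n.start and n.end <= exon.end
            )
        edges.update((i, j) for i, j in zip(path, path[1:]))
    return SpliceGraph(gene_id=gene_id, nodes=covered, edges=edges)


def node_psi(inclusion_paths: int, exclusion_paths: int) -> float | None:
    """Inclusion-path fraction of a node; missing when no path touches it."""
    if inclusion_paths < 0 or exclusion_paths < 0:
        raise ValueError("path counts must be non-negative")
    total = inclusion_paths + exclusion_paths
    if total == 0:
        return None
    return inclusion_paths / total


def posterior_delta(
    group_fat: tuple[int, int],
    group_thin: tuple[int, int],
    n_samples: int = DEFAULT_SAMPLES,
    seed: int | np.random.Generator = DEFAULT_SEED,
    prior: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Posterior mean delta-PSI and sign-agreement probability.

    ``group_fat`` / ``group_thin`` are pooled (inclusion, exclusion) counts.
    Returns ``(delta_psi, posterior_prob)``; delta_psi is the exact
    difference of Beta posterior means, the probability a seeded Monte-Carlo
    estimate.  With delta_psi = 0 the probability reported is P(diff > 0),
    which equals 1/2 under the symmetric posterior.
    """
    inc_f, exc_f = group_fat
    inc_t, exc_t = group_thin
    if min(inc_f, exc_f, inc_t, exc_t) < 0:
        raise ValueError("pooled counts must be non-negative")
    if inc_f + exc_f == 0 or inc_t + exc_t == 0:
        raise ValueError("each group needs a positive pooled total")
    a0, b0 = prior
    af, bf = inc_f + a0, exc_f + b0
    at, bt = inc_t + a0, exc_t + b0
    delta = af / (af + bf) - at / (at + bt)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff = rng.beta(af, bf, size=n_samples) - rng.beta(at, bt, size=n_samples)
    if delta > 0:
        prob = float(np.mean(diff > 0))
    elif delta < 0:
        prob = float(np.mean(diff < 0))
    else:
        prob = float(np.mean(diff > 0))
    return float(delta), prob


def call_das_graph(
    results: pd.DataFrame, prob_min: float = 0.8, dpsi_min: float = 0.1
) -> pd.DataFrame:
    """Differential verdict: posterior_prob > prob_min and |delta| >= dpsi_min."""
    out = results.copy()
    out["significant"] = (out["stat"] > prob_min) & (out["delta_psi"].abs() >= dpsi_min)
    out["arm"] = "graph"
    return out


def graph_arm(
    counts: pd.DataFrame,
    prob_min: float = 0.8,
    dpsi_min: float = 0.1,
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = DEFAULT_SEED,
    prior: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Run the graph arm over a count table (all studies).

    Inclusion/skipping read counts are taken as inclusion/exclusion path
    counts and pooled within group.  Posterior sampling is vectorised over
    events and seeded; events are processed in sorted order so results do not
    depend on input row order.  Events where a group has zero pooled total in
    a study are skipped with a log message.  Returns the per-(event, study)
    call table; the ``stat`` column holds the posterior probability.
    """
    pooled = (
        counts.groupby(["event_id", "study_id", "group"], sort=True)[
            ["inclusion_count", "skipping_count"]
        ]
        .sum()
        .unstack("group")
    )
    a0, b0 = prior
    rng = np.random.default_rng(seed)
    for grp in ("fat", "thin"):
        if ("inclusion_count", grp) not in pooled.columns:
            pooled[("inclusion_count", grp)] = np.nan
            pooled[("skipping_count", grp)] = np.nan
    inc_f = pooled[("inclusion_count", "fat")].to_numpy(dtype=float)
    exc_f = pooled[("skipping_count", "fat")].to_numpy(dtype=float)
    inc_t = pooled[("inclusion_count", "thin")].to_numpy(dtype=float)
    exc_t = pooled[("skipping_count", "thin")].to_numpy(dtype=float)
    usable = (
        ~np.isnan(inc_f)
        & ~np.isnan(inc_t)
        & ((inc_f + exc_f) > 0)
        & ((inc_t + exc_t) > 0)
    )
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("graph arm: skipped %d (event, study) pairs with an empty group", n_skipped)

    af, bf = inc_f + a0, exc_f + b0
    at, bt = inc_t + a0, exc_t + b0
    delta = af / (af + bf) - at / (at + bt)

    prob = np.full(len(pooled), np.nan)
    idx = np.flatnonzero(usable)
    chunk = max(1, int(2_000_000 // max(n_samples, 1)))
    for lo in range(0, len(idx), chunk):
        sel = idx[lo : lo + chunk]
        draws_f = rng.beta(af[sel, None], bf[sel, None], size=(len(sel), n_samples))
        draws_t = rng.beta(at[sel, None], bt[sel, None], size=(len(sel), n_samples))
        diff = draws_f - draws_t
        pos = (diff > 0).mean(axis=1)
        neg = (diff < 0).mean(axis=1)
        prob[sel] = np.where(delta[sel] < 0, neg, pos)

    out = pooled.index.to_frame(index=False)
    out["delta_psi"] = delta
    out["stat"] = prob
    out = out.loc[usable].reset_index(drop=True)
    return call_das_graph(out, prob_min=prob_min, dpsi_min=dpsi_min)
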