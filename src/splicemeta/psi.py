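"""Percent-spliced-in (PSI) quantification from inclusion/skipping counts.

PSI for one replicate is the effective-length-normalised inclusion fraction

    psi = (I / lI) / (I / lI + S / lS)

where I and S are reads supporting the inclusion and skipping isoform and
lI, lS their effective lengths (the number of distinct read placements able
to support each isoform).  For a skipped exon a read of length L can cross
either of two inclusion junctions but only one skipping junction, giving the
2:1 junction-opportunity ratio that motivates the normalisation:

    JC   : lI = 2 (L - 1),                     lS = L - 1
    JCEC : lI = 2 (L - 1) + max(0, e - L + 1), lS = L - 1

with e the target exon length (JCEC additionally counts reads wholly inside
the exon body).  The anchor requirement is fixed at 1 bp.

Group PSI is the unweighted mean of non-missing replicate PSIs and
delta PSI = psi_fat - psi_thin, so a negative value means the exon is more
skipped in the fat-tailed group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventKey, SpliceEvent

logger = logging.getLogger(__name__)

GROUPS = ("fat", "thin")

__all__ = [
    "GROUPS",
    "EventCounts",
    "ReplicatePSI",
    "GroupDelta",
    "effective_lengths",
    "psi_from_counts",
    "group_delta",
    "psi_table",
    "group_delta_table",
]


@dataclass(frozen=True)
class EventCounts:
    """Per-replicate inclusion/skipping read counts for one event."""

    event_key: EventKey
    replicate_id: str
    group: str
    inclusion_count: int
    skipping_count: int
    eff_len_inclusion: float
    eff_len_skipping: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.inclusion_count < 0 or self.skipping_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.eff_len_inclusion <= 0 or self.eff_len_skipping <= 0:
            raise ValueError("effective lengths must be positive")


@dataclass(frozen=True)
class ReplicatePSI:
    event_key: EventKey
    replicate_id: str
    group: str
    psi: float | None

    def __post_init__(self) -> None:
        if self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi must lie in [0, 1], got {self.psi}")


@dataclass(frozen=True)
class GroupDelta:
    event_key: EventKey
    psi_fat: float
    psi_thin: float

    @property
    def delta_psi(self) -> float:
        return self.psi_fat - self.psi_thin


def effective_lengths(
    event: SpliceEvent | int | None,
    read_length: int,
    mode: str = "JC",
) -> tuple[float, float]:
    """Effective lengths (lI, lS) for an SE event at the given read length.

    Parameters
    ----------
    event
        The event, or directly the target exon length in bp.  May be None in
        JC mode, where the exon body is not counted.
    read_length
        Sequenced read length L; must be >= 2 so a junction read can anchor
        at least 1 bp on each side.
    mode
        "JC" (junction reads only) or "JCEC" (junctions plus exon body).
    """
    if read_length < 2:
        raise ValueError(f"read_length must be >= 2, got {read_length}")
    if mode not in ("JC", "JCEC"):
        raise ValueError(f"mode must be 'JC' or 'JCEC', got {mode!r}")
    l_skip = float(read_length - 1)
    l_inc = 2.0 * l_skip
    if mode == "JCEC":
        if isinstance(event, SpliceEvent):
            exon_len = len(event.target)
        elif event is None:
            raise ValueError("JCEC mode requires the target exon length")
        else:
            exon_len = int(event)
        l_inc += max(0.0, exon_len - read_length + 1.0)
    return l_inc, l_skip


def psi_from_counts(counts: EventCounts) -> ReplicatePSI:
    """Length-normalised PSI for one replicate; missing when I = S = 0."""
    psi = _psi(
        counts.inclusion_count,
        counts.skipping_count,
        counts.eff_len_inclusion,
        counts.eff_len_skipping,
    )
    return ReplicatePSI(counts.event_key, counts.replicate_id, counts.group, psi)


def _psi(inc: float, skip: float, l_inc: float, l_skip: float) -> float | None:
    if inc < 0 or skip < 0:
        raise ValueError("read counts must be non-negative")
    if inc == 0 and skip == 0:
        return None
    norm_inc = inc / l_inc
    norm_skip = skip / l_skip
    return norm_inc / (norm_inc + norm_skip)


def group_delta(psis: list[ReplicatePSI]) -> GroupDelta:
    """Group-mean PSIs and their difference for one event in one study.

    Missing replicate PSIs are dropped; a group with no usable replicate makes
    the event unquantifiable for the study (ValueError, callers skip and log).
    """
    if not psis:
        raise ValueError("no replicate PSIs supplied")
    keys = {p.event_key for p in psis}
    if len(keys) > 1:
        raise ValueError("replicate PSIs span multiple events")
    means = {}
    for grp in GROUPS:
        values = [p.psi for p in psis if p.group == grp and p.psi is not None]
        if not values:
            raise ValueError(f"group {grp!r} has no quantifiable replicate")
        means[grp] = float(np.mean(values))
    return GroupDelta(keys.pop(), psi_fat=means["fat"], psi_thin=means["thin"])


def psi_table(
    counts: pd.DataFrame,
    events: pd.DataFrame | None = None,
    mode: str = "JC",
) -> pd.DataFrame:
    """Vectorised per-replicate PSI over a count table.

    ``counts`` columns: event_id, study_id, replicate_id, group,
    inclusion_count, skipping_count, read_length.  JCEC mode needs the event
    table to look up target exon lengths.  Rows with I = S = 0 get psi = NaN.
    """
    df = counts.copy()
    if (df["inclusion_count"] < 0).any() or (df["skipping_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    if (df["read_length"] < 2).any():
        raise ValueError("read_length must be >= 2")
    l_skip = (df["read_length"] - 1).astype(float)
    l_inc = 2.0 * l_skip
    if mode == "JCEC":
        if events is None:
            raise ValueError("JCEC mode requires the event table")
        lengths = (events["target_end"] - events["target_start"]).astype(float)
        exon_len = df["event_id"].map(
            dict(zip(events["event_id"], lengths))
        )
        if exon_len.isna().any():
            missing = df.loc[exon_len.isna(), "event_id"].iloc[0]
            raise ValueError(f"event {missing!r} absent from event table")
        l_inc = l_inc + np.maximum(0.0, exon_len - df["read_length"] + 1.0)
    elif mode != "JC":
        raise ValueError(f"mode must be 'JC' or 'JCEC', got {mode!r}")
    norm_inc = df["inclusion_count"] / l_inc
    norm_skip = df["skipping_count"] / l_skip
    total = norm_inc + norm_skip
    with np.errstate(invalid="ignore"):
        df["psi"] = np.where(total > 0, norm_inc / total, np.nan)
    df["eff_len_inclusion"] = l_inc
    df["eff_len_skipping"] = l_skip
    return df


def group_delta_table(psi_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(event, study) group PSIs and delta PSI from a PSI table.

    Events where either group has no quantifiable replicate in a study are
    dropped for that study (logged).
    """
    wide = (
        psi_df.groupby(["event_id", "study_id", "group"], sort=True)["psi"]
        .mean()
        .unstack("group")
    )
    for grp in GROUPS:
        if grp not in wide.columns:
            wide[grp] = np.nan
    usable = wide["fat"].notna() & wide["thin"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "%d (event, study) pairs dropped: one group entirely unquantifiable",
            n_dropped,
        )
    out = wide.loc[usable].reset_index()
    out = out.rename(columns={"fat": "psi_fat", "thin": "psi_thin"})
    out["delta_psi"] = out["psi_fat"] - out["psi_thin"]
    return out[["event_id", "study_id", "psi_fat", "psi_thin", "delta_psi"]]
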