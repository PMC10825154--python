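"""Cross-study, cross-arm consensus: the stable differential-splicing filter.

A differential call in a single study by a single tool is fragile; the
consensus filter keeps an event only when

* at least ``min_studies`` (default 3) studies carry a significant call with
  the same delta-PSI sign in one arm ("same trend, up or down"), and
* the other arm confirms it with at least ``min_other`` (default 1)
  significant call of the same sign, in any study.

Events reaching the study threshold with both signs are flagged as ambiguous
trend and excluded.  Calls with delta-PSI exactly 0 support neither sign.
The module also produces UpSet-style intersection counts: each event is
assigned to the exact subset of studies in which it is significant, and
subsets below an observation threshold (default 5) are omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import key_from_event_id

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusRecord",
    "per_arm_consensus",
    "cross_arm_stable",
    "intersection_counts",
]


@dataclass(frozen=True)
class ConsensusRecord:
    """One event's cross-study, cross-arm support summary."""

    event_id: str
    gene_id: str
    consensus_sign: str  # "+" or "-"
    primary_arm: str  # "count", "graph" or "both"
    n_support_primary: int
    n_support_other: int
    stable: bool
    mean_delta_psi: float
    support: dict  # arm -> {study_id: delta_psi} over significant same-sign calls


def _sig_calls(calls: pd.DataFrame) -> pd.DataFrame:
    sig = calls[calls["significant"]].copy()
    dup = sig.duplicated(subset=["event_id", "study_id"])
    if dup.any():
        bad = sig.loc[dup, ["event_id", "study_id"]].iloc[0]
        raise ValueError(
            f"duplicate call for event {bad['event_id']!r} in study {bad['study_id']!r}"
        )
    return sig


def per_arm_consensus(
    calls: pd.DataFrame, min_studies: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Within-arm vote count: events with >= min_studies same-sign calls.

    ``calls`` is one arm's call table (columns event_id, study_id, delta_psi,
    significant).  Returns ``(passes, ambiguous)``: one row per passing
    (event, sign) with its supporting studies, and the ids of events excluded
    because both signs reached the threshold.
    """
    sig = _sig_calls(calls)
    passes = []
    ambiguous: list[str] = []
    for eid, sub in sig.groupby("event_id", sort=True):
        pos = sub[sub["delta_psi"] > 0]
        neg = sub[sub["delta_psi"] < 0]
        pos_ok = len(pos) >= min_studies
        neg_ok = len(neg) >= min_studies
        if pos_ok and neg_ok:
            ambiguous.append(eid)
            continue
        for ok, sign, side in ((pos_ok, "+", pos), (neg_ok, "-", neg)):
            if ok:
                passes.append(
                    {
                        "event_id": eid,
                        "sign": sign,
                        "n_support": len(side),
                        "supporting_studies": sorted(side["study_id"]),
                        "mean_delta_psi": float(side["delta_psi"].mean()),
                    }
                )
    columns = ["event_id", "sign", "n_support", "supporting_studies", "mean_delta_psi"]
    return pd.DataFrame(passes, columns=columns), ambiguous


def _same_sign_support(calls_sig: pd.DataFrame, eid: str, sign: str) -> pd.DataFrame:
    sub = calls_sig[calls_sig["event_id"] == eid]
    if sign == "+":
        return sub[sub["delta_psi"] > 0]
    return sub[sub["delta_psi"] < 0]


def cross_arm_stable(
    calls_count: pd.DataFrame,
    calls_graph: pd.DataFrame,
    min_studies: int = 3,
    min_other: int = 1,
    require_sign_match: bool = True,
) -> list[ConsensusRecord]:
    """Stable differential events under the cross-arm double-verification rule.

    An event is stable iff it passes :func:`per_arm_consensus` in at least one
    arm with sign s and the other arm has >= ``min_other`` significant calls
    of the same sign (any study; with ``require_sign_match=False`` any
    significant call confirms).  The primary arm is the one meeting the
    study threshold — "both" when both do, in which case the reported mean
    delta-PSI comes from the arm with more supporting studies (count arm on a
    tie).  Output is sorted by genomic position of the event target.
    """
    arms = {"count": calls_count, "graph": calls_graph}
    sig = {arm: _sig_calls(df) for arm, df in arms.items()}
    if not set(calls_count["event_id"]) & set(calls_graph["event_id"]):
        logger.warning("the two arms share no event keys; stable set is empty")
        return []
    cons = {arm: per_arm_consensus(df, min_studies=min_studies)[0] for arm, df in arms.items()}
    gene_of = {}
    for df in arms.values():
        if "gene_id" in df.columns:
            gene_of.update(dict(zip(df["event_id"], df["gene_id"])))

    candidates: dict[tuple[str, str], dict] = {}
    for arm_name, passes in cons.items():
        other_name = "graph" if arm_name == "count" else "count"
        for row in passes.itertuples(index=False):
            if require_sign_match:
                other = _same_sign_support(sig[other_name], row.event_id, row.sign)
            else:
                other = sig[other_name][sig[other_name]["event_id"] == row.event_id]
            if len(other) < min_other:
                continue
            entry = candidates.setdefault(
                (row.event_id, row.sign),
                {"arms": {}, "other_counts": {}},
            )
            entry["arms"][arm_name] = row
            entry["other_counts"][arm_name] = len(other)

    records = []
    for (eid, sign), entry in candidates.items():
        arm_rows = entry["arms"]
        if len(arm_rows) == 2:
            primary_arm = "both"
            lead = max(
                ("count", "graph"),
                key=lambda a: (arm_rows[a].n_support, a == "count"),
            )
        else:
            primary_arm = lead = next(iter(arm_rows))
        lead_row = arm_rows[lead]
        support = {
            arm: dict(
                zip(
                    _same_sign_support(sig[arm], eid, sign)["study_id"],
                    _same_sign_support(sig[arm], eid, sign)["delta_psi"],
                )
            )
            for arm in arms
        }
        records.append(
            ConsensusRecord(
                event_id=eid,
                gene_id=gene_of.get(eid, ""),
                consensus_sign=sign,
                primary_arm=primary_arm,
                n_support_primary=int(lead_row.n_support),
                n_support_other=int(entry["other_counts"][lead]),
                stable=True,
                mean_delta_psi=float(lead_row.mean_delta_psi),
                support=support,
            )
        )

    def _position(rec: ConsensusRecord):
        key = key_from_event_id(rec.event_id)
        return (key.chrom, key.target_start, key.target_end, rec.consensus_sign)

    return sorted(records, key=_position)


def intersection_counts(
    calls: pd.DataFrame, observation_threshold: int = 5
) -> list[dict]:
    """UpSet-style exclusive intersection counts for one arm.

    Each significant event contributes to exactly the subset equal to its
    full set of significant studies; subsets with fewer events than the
    observation threshold are omitted.  Returns records
    ``{"subset": [studies...], "count": n}`` sorted by decreasing count.
    """
    sig = _sig_calls(calls)
    subsets = (
        sig.groupby("event_id", sort=True)["study_id"]
        .apply(lambda s: tuple(sorted(s)))
        .value_counts()
    )
    records = [
        {"subset": list(subset), "count": int(count)}
        for subset, count in subsets.items()
        if count >= observation_threshold
    ]
    records.sort(key=lambda r: (-r["count"], r["subset"]))
    return records
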