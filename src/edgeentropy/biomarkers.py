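"""Prognostic edge-biomarker calling from survival-group prevalence.

An edge is a positive biomarker when it sits in the per-sample high-ERE set
(the top-fraction set S) in strictly more than a prevalence threshold
(default 80%) of long-survival patients, and a negative biomarker when the
same holds in the short-survival group. Patients are stratified per edge at
the median of the edge's local ERE values for downstream Kaplan-Meier /
log-rank analysis, which is delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EdgeKey, LocalEREMatrix, top_set_indices, top_set_size

__all__ = [
    "SurvivalRecord",
    "EdgeBiomarkerCall",
    "survival_groups",
    "high_ere_membership",
    "classify_edges",
    "stratify_by_edge",
    "survival_table",
    "logrank_by_edge",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in years and whether death was observed."""

    sample_id: str
    survival_time: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.survival_time) or self.survival_time < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: survival_time must be finite and >= 0"
            )


@dataclass(frozen=True)
class EdgeBiomarkerCall:
    edge: EdgeKey
    call: str  # "positive" | "negative" | "none"
    prevalence_long: float
    prevalence_short: float


def survival_groups(
    records: Sequence[SurvivalRecord], cut_years: float = 5.0
) -> tuple[list[str], list[str]]:
    """Split patients at the survival cut (default 5 years).

    Long group: survived past the cut (censored or not). Short group: death
    observed at or before the cut. Patients censored at or before the cut are
    excluded — their group is unknowable.
    """
    if not records:
        raise ValueError("no survival records supplied")
    seen: set[str] = set()
    long_ids: list[str] = []
    short_ids: list[str] = []
    for r in records:
        if r.sample_id in seen:
            raise ValueError(f"duplicate survival record for {r.sample_id!r}")
        seen.add(r.sample_id)
        if r.survival_time > cut_years:
            long_ids.append(r.sample_id)
        elif r.event:
            short_ids.append(r.sample_id)
    if not long_ids or not short_ids:
        logger.warning(
            "empty survival group (long=%d, short=%d); no biomarkers can be called",
            len(long_ids), len(short_ids),
        )
    return long_ids, short_ids


def high_ere_membership(
    matrix: LocalEREMatrix,
    top_fraction: float = 0.05,
    absolute_threshold: float | None = None,
) -> pd.DataFrame:
    """Boolean edges x samples table of per-sample high-ERE membership.

    Default: an entry is True iff the edge belongs to that sample's
    top-fraction set S (identical selection, including tie-breaking, to the
    per-sample aggregation), so every column sums to M. Alternatively an
    absolute local-ERE cutoff can be used (entry True iff value > threshold).
    """
    member = np.zeros(matrix.values.shape, dtype=bool)
    if absolute_threshold is not None:
        member[:] = matrix.values > absolute_threshold
    else:
        M = top_set_size(top_fraction, len(matrix.edges))
        for k in range(len(matrix.case_sample_ids)):
            idx = top_set_indices(matrix.values[:, k], matrix.edges, M)
            member[idx, k] = True
    return pd.DataFrame(
        member, index=[str(e) for e in matrix.edges], columns=matrix.case_sample_ids
    )


def classify_edges(
    membership: pd.DataFrame,
    long_ids: Sequence[str],
    short_ids: Sequence[str],
    prevalence_threshold: float = 0.8,
    edges: Sequence[EdgeKey] | None = None,
) -> list[EdgeBiomarkerCall]:
    """Call positive/negative edge biomarkers from group prevalences.

    Prevalence is the fraction of a survival group's samples in which the
    edge is a high-ERE member; the comparison against the threshold is strict
    (exactly-at-threshold is not called). An edge exceeding the threshold in
    both groups has ambiguous prognostic direction and is called "none".
    Only edges with a positive or negative call are returned.
    """
    if set(long_ids) & set(short_ids):
        raise ValueError("long- and short-survival groups overlap")
    if not long_ids or not short_ids:
        return []
    if edges is None:
        edges = [EdgeKey(*ix.split("--", 1)) for ix in membership.index]
    prev_long = membership[list(long_ids)].mean(axis=1).to_numpy()
    prev_short = membership[list(short_ids)].mean(axis=1).to_numpy()

    calls: list[EdgeBiomarkerCall] = []
    for e, pl, ps in zip(edges, prev_long, prev_short):
        hit_long = pl > prevalence_threshold
        hit_short = ps > prevalence_threshold
        if hit_long and hit_short:
            call = "none"
        elif hit_long:
            call = "positive"
        elif hit_short:
            call = "negative"
        else:
            continue
        calls.append(EdgeBiomarkerCall(e, call, float(pl), float(ps)))
    return calls


def stratify_by_edge(
    matrix: LocalEREMatrix, edge: EdgeKey
) -> tuple[list[str], list[str]]:
    """Split case samples into high/low groups at the median of one edge's
    local ERE values; median-tied samples go to the low group."""
    try:
        row = matrix.edges.index(edge)
    except ValueError:
        raise KeyError(f"edge {edge} not present in the local ERE matrix") from None
    vals = matrix.values[row]
    med = float(np.median(vals))
    high = [s for s, v in zip(matrix.case_sample_ids, vals) if v > med]
    low = [s for s, v in zip(matrix.case_sample_ids, vals) if v <= med]
    if not high:
        logger.warning("edge %s: all local ERE values tie at the median; "
                       "high group is empty", edge)
    return high, low


def survival_table(
    matrix: LocalEREMatrix, edge: EdgeKey, records: Sequence[SurvivalRecord]
) -> pd.DataFrame:
    """Tidy per-patient table (sample_id, group, survival_time, event) for one
    edge's high/low stratification, ready for Kaplan-Meier tooling."""
    high, low = stratify_by_edge(matrix, edge)
    group = {s: "high" for s in high} | {s: "low" for s in low}
    rows = [
        {
            "sample_id": r.sample_id,
            "group": group[r.sample_id],
            "survival_time": r.survival_time,
            "event": int(r.event),
        }
        for r in records
        if r.sample_id in group
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "survival_time", "event"])


def logrank_by_edge(
    matrix: LocalEREMatrix, edge: EdgeKey, records: Sequence[SurvivalRecord]
):
    """Log-rank test between the high- and low-ERE patient groups of one edge
    (delegated to lifelines). Returns the lifelines StatisticalResult."""
    from lifelines.statistics import logrank_test

    tab = survival_table(matrix, edge, records)
    hi = tab[tab["group"] == "high"]
    lo = tab[tab["group"] == "low"]
    return logrank_test(
        hi["survival_time"], lo["survival_time"],
        event_observed_A=hi["event"], event_observed_B=lo["event"],
    )
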