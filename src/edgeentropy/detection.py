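"""Stage-level aggregation of sample ERE values and critical-stage detection.

The per-sample aggregates H^k are grouped by disease stage (or time point)
into the stage signal H(t), the mean over the N(t) case samples at stage t.
An interior stage is flagged as critical when its samples' H^k values are
significantly different from the mean of the two neighbouring stage signals
(one-sample t-test) AND the stage signal exceeds that reference — the
"significant increase" that precedes an abrupt state transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import LocalEREMatrix, SampleERE, sample_ere

__all__ = ["StageSeries", "StageSignalReport", "stage_series", "detect_critical"]

logger = logging.getLogger(__name__)


@dataclass
class StageSeries:
    """Per-stage collections of sample ERE values and their means H(t)."""

    stage_labels: list[str]
    per_stage_sample_ere: dict[str, list[SampleERE]]
    H_t: dict[str, float] = field(default_factory=dict)
    N_t: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.stage_labels:
            samples = self.per_stage_sample_ere.get(t, [])
            if len(samples) < 2:
                raise ValueError(f"stage {t!r} has {len(samples)} samples; need >= 2")
            hk = [s.H_k for s in samples]
            self.H_t[t] = float(np.mean(hk))
            self.N_t[t] = len(hk)

    def hk_values(self, stage: str) -> np.ndarray:
        return np.array([s.H_k for s in self.per_stage_sample_ere[stage]])


@dataclass
class StageSignalReport:
    """Outcome of the critical-stage test across an ordered stage series."""

    stage_labels: list[str]
    p_value: dict[str, float | None]
    reference_mean: dict[str, float | None]
    critical: dict[str, bool]
    critical_stage: str | None
    alpha: float


def stage_series(
    matrix: LocalEREMatrix | Mapping[str, LocalEREMatrix],
    stage_assignment: Mapping[str, str],
    stage_order: Sequence[str],
    top_fraction: float = 0.05,
) -> StageSeries:
    """Group case samples by stage and aggregate each into H^k, then H(t).

    ``matrix`` is either one local-ERE matrix covering all case samples, or a
    mapping stage -> matrix when case densities were fitted per stage (the
    default cohort scope): each stage's samples are then aggregated from that
    stage's own matrix.
    """
    order = list(stage_order)
    if len(set(order)) != len(order):
        raise ValueError("stage_order contains duplicate labels")

    def matrix_for(stage: str) -> LocalEREMatrix:
        if isinstance(matrix, LocalEREMatrix):
            return matrix
        try:
            return matrix[stage]
        except KeyError:
            raise ValueError(f"no local ERE matrix supplied for stage {stage!r}") from None

    per_stage: dict[str, list[SampleERE]] = {t: [] for t in order}
    for sample_id, stage in stage_assignment.items():
        if stage not in per_stage:
            raise ValueError(
                f"sample {sample_id!r} assigned to stage {stage!r} absent from stage_order"
            )
    for t in order:
        m = matrix_for(t)
        members = [s for s in m.case_sample_ids if stage_assignment.get(s) == t]
        per_stage[t] = [sample_ere(m, s, top_fraction) for s in members]
    return StageSeries(stage_labels=order, per_stage_sample_ere=per_stage)


def _one_sample_test(values: np.ndarray, popmean: float) -> float:
    """Two-sided one-sample t-test p-value; degenerate zero-variance stages
    collapse to p = 0 (mean differs) or p = 1 (mean equals the reference)."""
    if float(np.std(values, ddof=1)) == 0.0:
        logger.warning("degenerate zero-variance stage in the t-test")
        return 0.0 if float(np.mean(values)) != popmean else 1.0
    res = stats.ttest_1samp(values, popmean)
    return float(res.pvalue)


def detect_critical(
    series: StageSeries,
    alpha: float = 0.05,
    reference: str = "neighbors",
) -> StageSignalReport:
    """Flag the critical (pre-transition) stage in an ordered series.

    For each interior stage t the reference value is the mean of the two
    neighbouring stage signals (H(t-1), H(t+1)) — ``reference="neighbors"`` —
    or the mean of all other stages' signals (``reference="others"``). The
    stage's individual H^k values are tested against that scalar with a
    two-sided one-sample t-test; the stage is critical when p < alpha and
    H(t) exceeds the reference. Boundary stages are not tested. The earliest
    flagged stage is reported as THE critical stage.
    """
    order = series.stage_labels
    if len(order) < 3:
        raise ValueError(f"critical-stage detection needs >= 3 stages, got {len(order)}")
    if reference not in ("neighbors", "others"):
        raise ValueError(f"unknown reference rule {reference!r}")

    p_value: dict[str, float | None] = {t: None for t in order}
    ref_mean: dict[str, float | None] = {t: None for t in order}
    critical: dict[str, bool] = {t: False for t in order}
    for i, t in enumerate(order):
        if i == 0 or i == len(order) - 1:
            continue
        if reference == "neighbors":
            mu0 = 0.5 * (series.H_t[order[i - 1]] + series.H_t[order[i + 1]])
        else:
            mu0 = float(np.mean([series.H_t[s] for s in order if s != t]))
        hk = series.hk_values(t)
        p = _one_sample_test(hk, mu0)
        p_value[t] = p
        ref_mean[t] = mu0
        critical[t] = (p < alpha) and (series.H_t[t] > mu0)

    flagged = [t for t in order if critical[t]]
    return StageSignalReport(
        stage_labels=order,
        p_value=p_value,
        reference_mean=ref_mean,
        critical=critical,
        critical_stage=flagged[0] if flagged else None,
        alpha=alpha,
    )
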