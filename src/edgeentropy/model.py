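"""Model/Results interface over the edge-entropy pipeline.

``EdgeEntropyModel`` is constructed from an expression matrix, sample
metadata and an interaction network; ``fit()`` runs the full procedure —
reference and per-stage case density profiles, the local edge relative
entropy matrix, per-sample aggregation and the critical-stage test — and
returns an ``EdgeEntropyResults`` carrying the stage signals, p-values and
diagnostics, with ``summary()``, tidy exports, biomarker calling and
plotting hanging off it.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .core import (
    CohortVector,
    DegenerateCohortError,
    DensityProfile,
    EdgeKey,
    LocalEREMatrix,
    edge_entropy_matrix,
    kde_probability_vector,
)
from .detection import StageSeries, StageSignalReport, detect_critical, stage_series
from .io import Dataset, read_dataset

__all__ = ["EdgeEntropyModel", "EdgeEntropyResults"]

logger = logging.getLogger(__name__)


class EdgeEntropyModel:
    """Edge-based relative entropy scoring of a staged expression cohort.

    Parameters
    ----------
    expression : DataFrame, genes x samples.
    metadata : DataFrame with columns ``sample_id, cohort, stage`` (and
        optionally ``survival_time, event``); cohort is "reference" or "case".
    network : sequence of EdgeKey (or (gene, gene) pairs).
    stage_order : progression order of the case stages; defaults to order of
        first appearance in the metadata.
    top_fraction : fraction of edges in each sample's high-ERE set S.
    case_scope : "all" (default) fits the case densities from the pooled
        case cohort, so a stage whose samples are outliers against the whole
        case distribution stands out; "per-stage" fits each stage's densities
        from that stage's own samples only. Note that per-stage fitting is
        blind to pure dispersion changes: the plug-in bandwidth scales with
        the cohort sd, making the probability vectors scale-invariant.
    ddof : delta degrees of freedom of the bandwidth's standard deviation.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        metadata: pd.DataFrame,
        network: Sequence[EdgeKey | tuple[str, str]],
        stage_order: Sequence[str] | None = None,
        top_fraction: float = 0.05,
        case_scope: str = "all",
        ddof: int = 1,
    ) -> None:
        if case_scope not in ("per-stage", "all"):
            raise ValueError(f"unknown case_scope {case_scope!r}")
        from .io import intersect_and_partition

        edges = [e if isinstance(e, EdgeKey) else EdgeKey(*e) for e in network]
        self.data: Dataset = intersect_and_partition(
            expression, metadata, edges, stage_order=stage_order
        )
        self.top_fraction = float(top_fraction)
        self.case_scope = case_scope
        self.ddof = int(ddof)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        expression_path,
        metadata_path,
        network_path,
        stage_order: Sequence[str] | None = None,
        score_threshold: float | None = None,
        **kwargs,
    ) -> "EdgeEntropyModel":
        ds = read_dataset(
            expression_path, metadata_path, network_path,
            stage_order=stage_order, score_threshold=score_threshold,
        )
        meta = ds.metadata.reset_index()
        return cls(ds.expression, meta, ds.network, stage_order=ds.stage_order, **kwargs)

    @classmethod
    def from_synthetic(cls, dataset, **kwargs) -> "EdgeEntropyModel":
        """Build from a :class:`~edgeentropy.simulate.SyntheticDataset`."""
        return cls(
            dataset.expression, dataset.metadata, dataset.network,
            stage_order=dataset.stage_order, **kwargs,
        )

    # -- fitting ----------------------------------------------------------

    def _profiles(
        self, sample_ids: list[str], label: str, genes: list[str]
    ) -> tuple[dict[str, DensityProfile], list[str]]:
        """KDE probability vectors for each gene over one cohort; genes whose
        cohort is degenerate (zero variance) are reported, not raised."""
        profiles: dict[str, DensityProfile] = {}
        degenerate: list[str] = []
        for g in genes:
            vec = CohortVector(
                gene_id=g,
                values=self.data.expression.loc[g, sample_ids].to_numpy(dtype=float),
                cohort_label=label,
                sample_ids=sample_ids,
            )
            try:
                profiles[g] = kde_probability_vector(vec, ddof=self.ddof)
            except DegenerateCohortError:
                degenerate.append(g)
        return profiles, degenerate

    def fit(self, alpha: float = 0.05, reference: str = "neighbors") -> "EdgeEntropyResults":
        """Run the pipeline and test each interior stage for criticality."""
        d = self.data
        net_genes = sorted({g for e in d.network for g in e.genes})
        for t, ids in d.case_ids_by_stage.items():
            if len(ids) < 2:
                raise ValueError(f"stage {t!r} has {len(ids)} case samples; need >= 2")
        if len(d.reference_ids) < 2:
            raise ValueError("need at least 2 reference samples")

        cohorts: dict[str, list[str]] = {"reference": d.reference_ids}
        if self.case_scope == "per-stage":
            cohorts |= {t: ids for t, ids in d.case_ids_by_stage.items()}
        else:
            all_case = [s for t in d.stage_order for s in d.case_ids_by_stage[t]]
            cohorts["__all_case__"] = all_case

        all_profiles: dict[str, dict[str, DensityProfile]] = {}
        dropped_genes: set[str] = set()
        for label, ids in cohorts.items():
            profs, degen = self._profiles(ids, label, net_genes)
            all_profiles[label] = profs
            dropped_genes |= set(degen)
        if dropped_genes:
            logger.warning(
                "excluded %d degenerate zero-variance genes and their edges: %s",
                len(dropped_genes), sorted(dropped_genes)[:10],
            )
        kept = [g for g in net_genes if g not in dropped_genes]
        edges = [e for e in d.network if e.gene_a in kept and e.gene_b in kept]
        if not edges:
            raise ValueError("no edges remain after dropping degenerate genes")

        ref_profiles = {g: all_profiles["reference"][g] for g in kept}
        if self.case_scope == "per-stage":
            matrices: dict[str, LocalEREMatrix] = {
                t: edge_entropy_matrix(
                    ref_profiles, {g: all_profiles[t][g] for g in kept}, edges
                )
                for t in d.stage_order
            }
            series_input: LocalEREMatrix | Mapping[str, LocalEREMatrix] = matrices
        else:
            single = edge_entropy_matrix(
                ref_profiles, {g: all_profiles["__all_case__"][g] for g in kept}, edges
            )
            matrices = {t: single for t in d.stage_order}
            series_input = single

        stage_assignment = {
            s: t for t in d.stage_order for s in d.case_ids_by_stage[t]
        }
        series = stage_series(
            series_input, stage_assignment, d.stage_order, self.top_fraction
        )
        report = detect_critical(series, alpha=alpha, reference=reference)
        return EdgeEntropyResults(self, edges, matrices, series, report)


class EdgeEntropyResults:
    """Fitted edge-entropy pipeline: stage signals, tests and exports."""

    def __init__(
        self,
        model: EdgeEntropyModel,
        edges: list[EdgeKey],
        matrices: dict[str, LocalEREMatrix],
        series: StageSeries,
        report: StageSignalReport,
    ) -> None:
        self.model = model
        self.edges = edges
        self.matrices = matrices
        self.series = series
        self.report = report

    # -- headline results -------------------------------------------------

    @property
    def critical_stage(self) -> str | None:
        return self.report.critical_stage

    def stage_table(self) -> pd.DataFrame:
        """Stage report: N(t), H(t), reference mean, p-value, critical flag."""
        rows = []
        for t in self.series.stage_labels:
            rows.append(
                {
                    "stage": t,
                    "N_t": self.series.N_t[t],
                    "H_t": self.series.H_t[t],
                    "reference_mean": self.report.reference_mean[t],
                    "p_value": self.report.p_value[t],
                    "critical": self.report.critical[t],
                }
            )
        return pd.DataFrame(rows)

    def sample_table(self) -> pd.DataFrame:
        """Per-sample aggregates: stage, M, H^k and the top edge."""
        rows = []
        for t in self.series.stage_labels:
            for s in self.series.per_stage_sample_ere[t]:
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "stage": t,
                        "M": s.M,
                        "H_k": s.H_k,
                        "top_edge": str(s.selected_edges[0]),
                    }
                )
        return pd.DataFrame(rows)

    def local_ere_long(self) -> pd.DataFrame:
        """Long-format (edge, sample, stage, local_ere) table, heatmap-ready."""
        frames = []
        seen_samples: set[str] = set()
        for t in self.series.stage_labels:
            m = self.matrices[t]
            stage_samples = [
                s for s in m.case_sample_ids
                if s not in seen_samples and s in {
                    e.sample_id for e in self.series.per_stage_sample_ere[t]
                }
            ]
            seen_samples |= set(stage_samples)
            cols = [m.case_sample_ids.index(s) for s in stage_samples]
            df = pd.DataFrame(
                m.values[:, cols],
                index=[str(e) for e in m.edges],
                columns=stage_samples,
            )
            long = df.reset_index(names="edge").melt(
                id_vars="edge", var_name="sample_id", value_name="local_ere"
            )
            long["stage"] = t
            frames.append(long)
        return pd.concat(frames, ignore_index=True)[
            ["edge", "sample_id", "stage", "local_ere"]
        ]

    def combined_matrix(self) -> LocalEREMatrix:
        """One edges x all-case-samples matrix (columns in stage order), each
        sample scored under its own stage's case densities."""
        cols, ids = [], []
        for t in self.series.stage_labels:
            m = self.matrices[t]
            stage_ids = [s.sample_id for s in self.series.per_stage_sample_ere[t]]
            idx = [m.case_sample_ids.index(s) for s in stage_ids]
            cols.append(m.values[:, idx])
            ids.extend(stage_ids)
        return LocalEREMatrix(
            edges=self.edges, case_sample_ids=ids, values=np.hstack(cols)
        )

    # -- biomarkers --------------------------------------------------------

    def survival_records(self) -> list[bm.SurvivalRecord]:
        """Survival records parsed from the model's metadata (case samples
        with a finite survival_time)."""
        meta = self.model.data.metadata
        recs = []
        for sid, row in meta.iterrows():
            if row.get("cohort") != "case":
                continue
            t = row.get("survival_time")
            if t is None or (isinstance(t, float) and not np.isfinite(t)):
                continue
            recs.append(bm.SurvivalRecord(str(sid), float(t), bool(float(row["event"]))))
        return recs

    def call_biomarkers(
        self,
        records: Sequence[bm.SurvivalRecord] | None = None,
        cut_years: float = 5.0,
        prevalence_threshold: float = 0.8,
        top_fraction: float | None = None,
    ) -> list[bm.EdgeBiomarkerCall]:
        """Call positive/negative prognostic edges from survival prevalence."""
        if records is None:
            records = self.survival_records()
        if not records:
            logger.warning("no survival records available; no biomarkers called")
            return []
        long_ids, short_ids = bm.survival_groups(records, cut_years)
        if not long_ids or not short_ids:
            return []
        matrix = self.combined_matrix()
        scored = set(matrix.case_sample_ids)
        long_ids = [s for s in long_ids if s in scored]
        short_ids = [s for s in short_ids if s in scored]
        member = bm.high_ere_membership(
            matrix, top_fraction or self.model.top_fraction
        )
        return bm.classify_edges(
            member, long_ids, short_ids, prevalence_threshold, edges=matrix.edges
        )

    def stratify(self, edge: EdgeKey) -> tuple[list[str], list[str]]:
        """High/low patient split at the median of one edge's ERE values."""
        return bm.stratify_by_edge(self.combined_matrix(), edge)

    def logrank(self, edge: EdgeKey, records=None):
        if records is None:
            records = self.survival_records()
        return bm.logrank_by_edge(self.combined_matrix(), edge, records)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text report in the style of a fitted-model summary."""
        d = self.model.data
        n_genes = len({g for e in self.edges for g in e.genes})
        header = [
            "Edge-based relative entropy — stage signal report",
            "=" * 58,
            f"network genes: {n_genes:<6d} edges: {len(self.edges):<6d} "
            f"reference N: {len(d.reference_ids)}",
            f"case scope: {self.model.case_scope:<10s} top fraction: "
            f"{self.model.top_fraction:g}  alpha: {self.report.alpha:g}",
            "-" * 58,
            f"{'stage':<10s}{'N(t)':>6s}{'H(t)':>10s}{'ref mean':>10s}"
            f"{'p-value':>10s}{'critical':>10s}",
        ]
        body = []
        for t in self.series.stage_labels:
            p = self.report.p_value[t]
            mu = self.report.reference_mean[t]
            body.append(
                f"{t:<10s}{self.series.N_t[t]:>6d}{self.series.H_t[t]:>10.4f}"
                + (f"{mu:>10.4f}" if mu is not None else f"{'--':>10s}")
                + (f"{p:>10.2g}" if p is not None else f"{'--':>10s}")
                + f"{'yes' if self.report.critical[t] else '':>10s}"
            )
        footer = [
            "-" * 58,
            f"critical stage: {self.critical_stage if self.critical_stage else 'none detected'}",
        ]
        return "\n".join(header + body + footer)

    def plot_stage_series(self, ax=None):
        """Line plot of H(t) across stages, critical stage highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        stages = self.series.stage_labels
        h = [self.series.H_t[t] for t in stages]
        ax.plot(stages, h, marker="o", color="#2166ac")
        if self.critical_stage is not None:
            i = stages.index(self.critical_stage)
            ax.scatter([self.critical_stage], [h[i]], s=90, zorder=3, color="#b2182b",
                       label=f"critical: {self.critical_stage}")
            ax.legend(frameon=False)
        ax.set_xlabel("stage")
        ax.set_ylabel("H(t)")
        ax.set_title("stage ERE signal")
        return ax
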