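"""Readers, writers and preprocessing for expression cohorts and networks.

File formats are plain delimited text (tab or comma auto-detected on input;
output is always tab-separated):

* expression — genes x samples matrix, first column gene ids, header row of
  sample ids; duplicate gene rows (multiple probes) are collapsed by mean;
* metadata — columns ``sample_id, cohort, stage[, survival_time, event]``;
* network — two-column edge list of gene symbols, optional third
  STRING-style confidence score column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EdgeKey
from .simulate import SyntheticDataset

__all__ = [
    "Dataset",
    "read_expression",
    "collapse_probes",
    "read_network",
    "read_metadata",
    "intersect_and_partition",
    "write_expression",
    "write_metadata",
    "write_network",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"  # 12 significant digits; round trips are lossless at this precision


@dataclass
class Dataset:
    """An analysis-ready cohort: matrix, metadata, network and partitions."""

    expression: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # indexed by sample_id
    network: list[EdgeKey]
    stage_order: list[str]
    reference_ids: list[str] = field(default_factory=list)
    case_ids_by_stage: dict[str, list[str]] = field(default_factory=dict)


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix; collapse duplicate gene rows by mean,
    drop rows with missing values (logged)."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: no expression columns found")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[np.argmax(bad.to_numpy())]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d gene rows containing missing values", path, n_missing)
        df = df.dropna(axis=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return collapse_probes(df)


def collapse_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene ids (multiple probes per gene) by arithmetic
    mean; probes with an empty gene symbol are dropped."""
    idx = matrix.index.astype(str)
    keep = np.asarray((idx != "") & (idx.str.lower() != "nan"))
    n_unnamed = int((~keep).sum())
    if n_unnamed:
        logger.warning("dropped %d probes without a gene symbol", n_unnamed)
        matrix = matrix.loc[keep]
    if matrix.index.has_duplicates:
        matrix = matrix.groupby(level=0, sort=False).mean()
    return matrix


def read_network(path: str | Path, score_threshold: float | None = None) -> list[EdgeKey]:
    """Read a 2- or 3-column edge list into canonical, deduplicated edges.

    Self-loops are dropped with a warning. If a third (score) column is
    present and ``score_threshold`` is given, only edges with
    score >= threshold are kept (STRING combined-score convention).
    """
    sep = _detect_sep(path)
    edges: list[EdgeKey] = []
    seen: set[EdgeKey] = set()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.split(sep) if p != ""]
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if lineno == 1 and len(parts) == 3:
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header row
            if len(parts) == 3 and score_threshold is not None:
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}")
                if score < score_threshold:
                    continue
            a, b = parts[0], parts[1]
            if a == b:
                n_loops += 1
                continue
            e = EdgeKey(a, b)
            if e not in seen:
                seen.add(e)
                edges.append(e)
    if n_loops:
        logger.warning("%s: dropped %d self-loop edges", path, n_loops)
    return edges


def read_metadata(path: str | Path) -> pd.DataFrame:
    sep = _detect_sep(path)
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "cohort": str})
    required = {"sample_id", "cohort"}
    if not required <= set(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if "stage" in meta.columns:
        meta["stage"] = meta["stage"].fillna("").astype(str)
    return meta


def intersect_and_partition(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    network: Sequence[EdgeKey],
    stage_order: Sequence[str] | None = None,
) -> Dataset:
    """Restrict the network to measured genes and partition the samples.

    Genes absent from the expression matrix lose their edges (counted and
    logged); genes absent from the network stay in the matrix but are unused.
    Case samples are partitioned by stage in the declared order (default:
    order of first appearance in the metadata).
    """
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    unknown = [s for s in meta.index if s not in expression.columns]
    if unknown:
        raise ValueError(f"metadata samples missing from the matrix: {unknown[:5]}")

    measured = set(expression.index)
    kept = [e for e in network if e.gene_a in measured and e.gene_b in measured]
    if len(kept) < len(network):
        logger.info("dropped %d network edges with unmeasured genes", len(network) - len(kept))
    if not kept:
        raise ValueError("no network edges remain after intersecting with the matrix")

    ref_ids = list(meta.index[meta["cohort"] == "reference"])
    case_meta = meta[meta["cohort"] == "case"]
    if "stage" not in case_meta.columns:
        raise ValueError("metadata lacks a 'stage' column for the case samples")
    if stage_order is None:
        stage_order = list(dict.fromkeys(case_meta["stage"]))
    by_stage = {
        t: list(case_meta.index[case_meta["stage"] == t]) for t in stage_order
    }
    for t, ids in by_stage.items():
        if not ids:
            raise ValueError(f"declared stage {t!r} has no samples")
    covered = set().union(*by_stage.values()) if by_stage else set()
    stray = set(case_meta.index) - covered
    if stray:
        raise ValueError(f"case samples with stages outside stage_order: {sorted(stray)[:5]}")
    logger.info(
        "dataset: %d genes, %d edges kept, %d reference samples, case stages %s",
        expression.shape[0], len(kept), len(ref_ids),
        {t: len(v) for t, v in by_stage.items()},
    )
    return Dataset(
        expression=expression,
        metadata=meta,
        network=kept,
        stage_order=list(stage_order),
        reference_ids=ref_ids,
        case_ids_by_stage=by_stage,
    )


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    meta = metadata.reset_index() if metadata.index.name == "sample_id" else metadata
    meta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)


def write_network(network: Sequence[EdgeKey], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in network:
            fh.write(f"{e.gene_a}\t{e.gene_b}\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset's three files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "network": outdir / "network.tsv",
    }
    write_expression(dataset.expression, paths["expression"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_network(dataset.network, paths["network"])
    return paths


def read_dataset(
    expression_path: str | Path,
    metadata_path: str | Path,
    network_path: str | Path,
    stage_order: Sequence[str] | None = None,
    score_threshold: float | None = None,
) -> Dataset:
    """Read the three input files and assemble an analysis-ready Dataset."""
    return intersect_and_partition(
        read_expression(expression_path),
        read_metadata(metadata_path),
        read_network(network_path, score_threshold=score_threshold),
        stage_order=stage_order,
    )
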