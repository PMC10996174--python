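"""Synthetic cohorts with a programmed critical stage and planted biomarkers.

The generator emulates the phenomenology the entropy score responds to: a
reference cohort and several ordered case stages of i.i.d. Gaussian expression
per gene, where at one designated (interior) "critical" stage a small gene
group — a dynamic-network-biomarker-like module — has its dispersion
inflated by a factor kappa. When the case densities are fitted on the pooled
case cohort (the default scoring scope), the inflated stage's samples land
in sparse regions of the pooled density, which lowers their ``p_c``, raises
the ``-log p_c`` term of the edge score, and elevates the stage signal H(t)
on the module's edges. Note that under strictly per-stage density fitting a
uniform dispersion inflation is invisible: the plug-in bandwidth is
proportional to the cohort's standard deviation, so the normalised
probability vector at the cohort's own points is exactly scale-invariant.
``excited_fraction < 1`` switches to a flickering variant in which only a
seeded fraction of the stage's samples is excited — a scale-mixture shape
that remains detectable even under per-stage fitting. Stages after the
critical one add a mean shift to the module genes, mimicking the settled
after-transition state.

Survival labels are planted by locally perturbing the endpoint genes of one
positive and one negative prognostic edge into far outliers in (most of) the
long- and short-survival patients respectively, so those edges dominate the
per-sample top-ERE set of their group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EdgeKey

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "GroundTruth",
    "toy_network",
    "simulate_cohorts",
    "simulate_survival",
]


def _gene_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Defaults: a 16-gene network, five stages of 30 case samples, a
    reference cohort of 50, dispersion inflation kappa = 4 on a 4-gene module
    at the middle stage."""

    n_genes: int = 16
    network_spec: str | Sequence[tuple[str, str]] = "ring_with_chords"
    n_chords: int = 8
    n_stages: int = 5
    samples_per_stage: int = 30
    n_reference: int = 50
    critical_stage_index: int = 2
    dnb_genes: tuple[str, ...] | None = None  # default: first 4 genes
    dispersion_factor: float = 4.0
    excited_fraction: float = 1.0
    mean_shift_after: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        if self.n_stages < 3:
            raise ValueError("need at least 3 stages")
        if self.samples_per_stage < 10:
            raise ValueError("need at least 10 case samples per stage")
        if self.n_reference < 20:
            raise ValueError("need at least 20 reference samples")
        if not (0 < self.critical_stage_index < self.n_stages - 1):
            raise ValueError(
                f"critical_stage_index must be interior (1..{self.n_stages - 2}), "
                f"got {self.critical_stage_index}"
            )
        if self.dispersion_factor < 1:
            raise ValueError("dispersion_factor must be >= 1")
        if not (0 < self.excited_fraction <= 1):
            raise ValueError("excited_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dnb_genes is None:
            self.dnb_genes = tuple(_gene_names(self.n_genes)[:4])

    @property
    def gene_names(self) -> list[str]:
        return _gene_names(self.n_genes)

    @property
    def stage_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_stages)]


@dataclass
class GroundTruth:
    critical_stage: str
    dnb_genes: list[str]
    dnb_edges: list[EdgeKey]
    positive_edges: list[EdgeKey] = field(default_factory=list)
    negative_edges: list[EdgeKey] = field(default_factory=list)
    long_ids: list[str] = field(default_factory=list)
    short_ids: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    """Expression, metadata, network and the planted ground truth."""

    expression: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # sample_id, cohort, stage, survival_time, event
    network: list[EdgeKey]
    stage_order: list[str]
    truth: GroundTruth

    @property
    def reference_ids(self) -> list[str]:
        m = self.metadata
        return list(m.loc[m["cohort"] == "reference", "sample_id"])

    def case_ids(self, stage: str | None = None) -> list[str]:
        m = self.metadata[self.metadata["cohort"] == "case"]
        if stage is not None:
            m = m[m["stage"] == stage]
        return list(m["sample_id"])


def toy_network(
    spec: str | Sequence[tuple[str, str]] = "ring_with_chords",
    n_genes: int = 16,
    n_chords: int = 8,
    seed: int = 0,
) -> list[EdgeKey]:
    """Build a connected toy interaction network.

    ``ring_with_chords`` (default): a cycle over all genes plus ``n_chords``
    distinct random chords. ``random_gnm``: a connected G(n, m) graph with
    ``n_genes + n_chords`` edges. A sequence of gene pairs is used verbatim.
    Edges are returned canonical, deduplicated, sorted.
    """
    import networkx as nx

    if n_genes < 3:
        raise ValueError("need at least 3 genes for a connected toy network")
    genes = _gene_names(n_genes)
    rng = np.random.default_rng(seed)
    if not isinstance(spec, str):
        edges = {EdgeKey(a, b) for a, b in spec}
        return sorted(edges)
    if spec == "ring_with_chords":
        g = nx.cycle_graph(n_genes)
        non_edges = [
            (u, v) for u in range(n_genes) for v in range(u + 1, n_genes)
            if not g.has_edge(u, v)
        ]
        if n_chords > len(non_edges):
            raise ValueError(f"cannot place {n_chords} chords in a {n_genes}-gene ring")
        for idx in rng.choice(len(non_edges), size=n_chords, replace=False):
            g.add_edge(*non_edges[idx])
    elif spec == "random_gnm":
        m = n_genes + n_chords
        for attempt in range(1000):
            g = nx.gnm_random_graph(n_genes, m, seed=int(rng.integers(2**31)))
            if nx.is_connected(g):
                break
        else:
            raise RuntimeError("failed to draw a connected random graph")
    else:
        raise ValueError(f"unknown network spec {spec!r}")
    return sorted(EdgeKey(genes[u], genes[v]) for u, v in g.edges())


def simulate_cohorts(config: SimulationConfig) -> SyntheticDataset:
    """Draw the reference cohort and the staged case cohorts.

    Reference samples and non-critical pre-transition stages are i.i.d.
    ``N(baseline_mean, noise_sd)`` per gene. At the critical stage an
    ``excited_fraction`` of samples (default: all of them) draws the module
    genes with standard deviation ``dispersion_factor * noise_sd``; stages
    after it add ``mean_shift_after`` to the module genes. Deterministic per
    seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    network = toy_network(
        config.network_spec, config.n_genes, config.n_chords, seed=config.seed
    )
    net_genes = {g for e in network for g in e.genes}
    missing = net_genes - set(genes)
    if missing:
        raise ValueError(f"network references unknown genes: {sorted(missing)}")
    dnb = list(config.dnb_genes)
    if not set(dnb) <= set(genes):
        raise ValueError("dnb_genes must be a subset of the gene panel")
    dnb_edges = [e for e in network if e.gene_a in dnb and e.gene_b in dnb]
    if not dnb_edges:
        raise ValueError("dnb_genes induce no network edge")

    g_index = {g: i for i, g in enumerate(genes)}
    dnb_rows = [g_index[g] for g in dnb]

    ref_ids = [f"R{i + 1:03d}" for i in range(config.n_reference)]
    ref = rng.normal(config.baseline_mean, config.noise_sd,
                     size=(config.n_genes, config.n_reference))

    stage_labels = config.stage_labels
    critical = stage_labels[config.critical_stage_index]
    case_blocks, case_ids, case_stage = [], [], []
    for si, stage in enumerate(stage_labels):
        block = rng.normal(config.baseline_mean, config.noise_sd,
                           size=(config.n_genes, config.samples_per_stage))
        if si == config.critical_stage_index:
            n_exc = round(config.excited_fraction * config.samples_per_stage)
            excited = rng.choice(config.samples_per_stage, n_exc, replace=False)
            block[np.ix_(dnb_rows, excited)] = rng.normal(
                config.baseline_mean,
                config.dispersion_factor * config.noise_sd,
                size=(len(dnb_rows), n_exc),
            )
        elif si > config.critical_stage_index:
            block[dnb_rows, :] += config.mean_shift_after
        case_blocks.append(block)
        ids = [f"{stage}_{k + 1:03d}" for k in range(config.samples_per_stage)]
        case_ids.extend(ids)
        case_stage.extend([stage] * config.samples_per_stage)

    expression = pd.DataFrame(
        np.hstack([ref] + case_blocks), index=genes, columns=ref_ids + case_ids
    )
    expression.index.name = "gene_id"
    metadata = pd.DataFrame(
        {
            "sample_id": ref_ids + case_ids,
            "cohort": ["reference"] * len(ref_ids) + ["case"] * len(case_ids),
            "stage": [""] * len(ref_ids) + case_stage,
            "survival_time": np.nan,
            "event": np.nan,
        }
    )
    truth = GroundTruth(critical_stage=critical, dnb_genes=dnb, dnb_edges=dnb_edges)
    return SyntheticDataset(
        expression=expression,
        metadata=metadata,
        network=network,
        stage_order=stage_labels,
        truth=truth,
    )


def simulate_survival(
    dataset: SyntheticDataset,
    positive_edges: Sequence[EdgeKey] = (),
    negative_edges: Sequence[EdgeKey] = (),
    seed: int = 0,
    group_size: int | None = None,
    expressed_fraction: float = 0.95,
    outlier_band: tuple[float, float] = (10.0, 30.0),
    noise_sd: float = 1.0,
    cut_years: float = 5.0,
) -> list["SurvivalRecord"]:
    """Plant prognostic edges and attach survival labels to the case samples.

    ``group_size`` case samples each (default: a third of the case cohort,
    at most 25) are assigned to a long-lived and a short-lived cohort; the
    remaining patients are censored before
    ``cut_years`` (lost to follow-up), as is typical of real survival data —
    their group is unknowable and they stay unperturbed. In
    ``expressed_fraction`` of the long-lived samples the endpoint genes of
    every positive edge are pushed to far outliers (offset drawn uniformly in
    ``outlier_band`` standard deviations, random sign), making those edges the
    samples' top-ERE members under pooled case-density fitting; negative
    edges are planted the same way in the short-lived samples. Keeping the
    informative groups a minority matters: the perturbed values must stay
    sparse in the pooled case density for their probabilities to be low. The
    dataset's expression matrix is modified in place and the ground truth
    updated; survival times are drawn above ``cut_years`` for long-lived
    patients (half censored) and below it, with the death observed, for
    short-lived ones. Deterministic per seed.
    """
    from .biomarkers import SurvivalRecord

    net = set(dataset.network)
    for e in list(positive_edges) + list(negative_edges):
        if e not in net:
            raise ValueError(f"planted edge {e} is not in the network")

    rng = np.random.default_rng(seed)
    case = dataset.case_ids()
    if group_size is None:
        group_size = max(2, min(25, len(case) // 3))
    if 2 * group_size > len(case):
        raise ValueError(
            f"group_size {group_size} too large for {len(case)} case samples"
        )
    perm = rng.permutation(len(case))
    long_ids = [case[i] for i in sorted(perm[:group_size])]
    short_ids = [case[i] for i in sorted(perm[group_size:2 * group_size])]
    censored_ids = [case[i] for i in sorted(perm[2 * group_size:])]

    def plant(group: list[str], edges: Sequence[EdgeKey]) -> None:
        if not edges:
            return
        n_hit = math.ceil(expressed_fraction * len(group))
        hit = [group[i] for i in sorted(rng.choice(len(group), n_hit, replace=False))]
        genes = sorted({g for e in edges for g in e.genes})
        lo, hi = outlier_band
        for s in hit:
            offs = rng.uniform(lo, hi, size=len(genes)) * rng.choice([-1.0, 1.0], len(genes))
            dataset.expression.loc[genes, s] = (
                dataset.expression.loc[genes, s].to_numpy() + offs * noise_sd
            )

    plant(long_ids, positive_edges)
    plant(short_ids, negative_edges)

    records = []
    for s in long_ids:
        records.append(SurvivalRecord(s, float(rng.uniform(cut_years + 0.5, cut_years + 7.0)),
                                      bool(rng.random() < 0.5)))
    for s in short_ids:
        records.append(SurvivalRecord(s, float(rng.uniform(0.3, cut_years - 0.5)), True))
    for s in censored_ids:
        records.append(SurvivalRecord(s, float(rng.uniform(0.5, cut_years - 0.5)), False))
    records.sort(key=lambda r: r.sample_id)

    meta = dataset.metadata.set_index("sample_id")
    for r in records:
        meta.loc[r.sample_id, "survival_time"] = r.survival_time
        meta.loc[r.sample_id, "event"] = float(r.event)
    dataset.metadata = meta.reset_index()

    dataset.truth.positive_edges = list(positive_edges)
    dataset.truth.negative_edges = list(negative_edges)
    dataset.truth.long_ids = long_ids
    dataset.truth.short_ids = short_ids
    return records
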