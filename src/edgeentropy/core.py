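"""Edge-based relative entropy (ERE) primitives.

This module contains the entropy mathematics of the method: Gaussian kernel
density estimation with the plug-in bandwidth ``h = (4 sigma^5 / (3 N))^(1/5)``,
probability vectors evaluated at a cohort's own sample points, the directed
local edge relative entropy

    H_<j,i>(x_j, y_ik) = sum_m p_r(x_jm) * log( p_r(x_jm) / p_c(y_ik) ),

its symmetric average over the two gene orders, and the per-sample aggregation
over the top-fraction edge set S (H^k = mean of the M largest local values).

All logarithms are natural. Densities are evaluated only at observed sample
points and renormalised to sum to one, so each cohort yields a discrete
probability vector aligned with its sample order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CohortVector",
    "DensityProfile",
    "EdgeKey",
    "LocalEREMatrix",
    "SampleERE",
    "DegenerateCohortError",
    "plugin_bandwidth",
    "kde_probability_vector",
    "directed_local_ere",
    "symmetric_local_ere",
    "edge_entropy_matrix",
    "sample_ere",
    "top_set_indices",
]

logger = logging.getLogger(__name__)

#: probabilities are clipped here before taking logs, to keep underflowing
#: kernel sums from producing -inf
PROBABILITY_FLOOR = 1e-300


class DegenerateCohortError(ValueError):
    """Raised when a cohort has zero variance or fewer than two samples."""


@dataclass(frozen=True, order=True)
class EdgeKey:
    """Unordered gene pair, stored canonically with ``gene_a < gene_b``."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop edge for gene {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    def __str__(self) -> str:  # "A--B", handy in tables and logs
        return f"{self.gene_a}--{self.gene_b}"

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class CohortVector:
    """Expression values of one gene across one cohort's samples."""

    gene_id: str
    values: np.ndarray
    cohort_label: str  # "reference" or "case"
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("cohort values must be one-dimensional")
        if len(self.values) != len(self.sample_ids):
            raise ValueError(
                f"gene {self.gene_id!r}: {len(self.values)} values but "
                f"{len(self.sample_ids)} sample ids"
            )
        if len(self.values) < 2:
            raise DegenerateCohortError(
                f"gene {self.gene_id!r}: cohort needs at least 2 samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"gene {self.gene_id!r}: non-finite expression values")


@dataclass
class DensityProfile:
    """KDE-derived probability vector of one gene in one cohort.

    ``probabilities[k]`` is the renormalised kernel density at the cohort's
    k-th observed value; the vector sums to one and is strictly positive.
    """

    gene_id: str
    cohort_label: str
    bandwidth_h: float
    probabilities: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    @property
    def log_probabilities(self) -> np.ndarray:
        return np.log(np.clip(self.probabilities, PROBABILITY_FLOOR, None))

    @property
    def neg_entropy(self) -> float:
        """sum p log p (non-positive of entropy); the reference-side term of
        the directed local ERE."""
        return float(np.sum(self.probabilities * self.log_probabilities))


@dataclass
class LocalEREMatrix:
    """Dense edges x case-samples matrix of symmetric local ERE values."""

    edges: list[EdgeKey]
    case_sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.edges), len(self.case_sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.edges)} edges x {len(self.case_sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("local ERE matrix contains non-finite entries")

    def column(self, sample_id: str) -> np.ndarray:
        try:
            k = self.case_sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown case sample {sample_id!r}") from None
        return self.values[:, k]


@dataclass
class SampleERE:
    """Per-sample aggregate: the top-fraction edge set S and its mean H^k."""

    sample_id: str
    top_fraction: float
    selected_edges: list[EdgeKey]
    M: int
    H_k: float


def plugin_bandwidth(sigma: float, N: int) -> float:
    """Plug-in KDE bandwidth ``(4 sigma^5 / (3 N))^(1/5)``.

    ``sigma`` is the cohort's sample standard deviation and ``N`` the number
    of samples. Homogeneous of degree one in sigma.
    """
    if N < 2:
        raise ValueError(f"bandwidth needs N >= 2 samples, got {N}")
    if sigma < 0 or not math.isfinite(sigma):
        raise ValueError(f"sigma must be finite and non-negative, got {sigma}")
    if sigma == 0:
        raise DegenerateCohortError("zero standard deviation: all values identical")
    return (4.0 * sigma**5 / (3.0 * N)) ** 0.2


def kde_probability_vector(cohort: CohortVector, ddof: int = 1) -> DensityProfile:
    """Gaussian-KDE probability vector of a cohort at its own sample points.

    The density at each observed value is the mean of Gaussian kernels centred
    at all cohort values (self-kernel included); probabilities are these
    densities renormalised to sum to one. ``ddof`` controls the denominator of
    the standard deviation used for the bandwidth (1 = sample sd, the default).
    """
    x = cohort.values
    n = len(x)
    sigma = float(np.std(x, ddof=ddof))
    if sigma == 0.0:
        raise DegenerateCohortError(
            f"gene {cohort.gene_id!r} ({cohort.cohort_label}): all {n} values "
            "identical; KDE bandwidth would be zero"
        )
    h = plugin_bandwidth(sigma, n)
    # pairwise kernel sums; constant factors cancel in the normalisation but
    # are kept so that intermediate densities are genuine f_h values
    u = (x[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (n * h * math.sqrt(2.0 * math.pi))
    probs = dens / dens.sum()
    return DensityProfile(
        gene_id=cohort.gene_id,
        cohort_label=cohort.cohort_label,
        bandwidth_h=h,
        probabilities=probs,
        sample_ids=list(cohort.sample_ids),
    )


def directed_local_ere(ref_profile: DensityProfile, p_case_ik: float) -> float:
    """Directed local ERE of one edge direction.

    Computes ``sum_m p_r(x_m) log(p_r(x_m) / p)`` for the reference
    probability vector ``p_r`` and the scalar case probability ``p`` of the
    partner gene's value in one case sample. Since ``sum p_r = 1`` this equals
    ``sum p_r log p_r - log p``; the result may be negative.
    """
    if not (0.0 < p_case_ik <= 1.0):
        raise ValueError(f"case probability must lie in (0, 1], got {p_case_ik}")
    return ref_profile.neg_entropy - math.log(p_case_ik)


def symmetric_local_ere(h_ij: float, h_ji: float) -> float:
    """Arithmetic mean of the two directed local ERE values (Eq. 3 measure)."""
    if not (math.isfinite(h_ij) and math.isfinite(h_ji)):
        raise ValueError("directed local ERE values must be finite")
    return 0.5 * (h_ij + h_ji)


def edge_entropy_matrix(
    ref_profiles: Mapping[str, DensityProfile],
    case_profiles: Mapping[str, DensityProfile],
    network: Sequence[EdgeKey],
) -> LocalEREMatrix:
    """Assemble the symmetric local ERE matrix over a network's edges.

    Entry ``[<i,j>, k]`` averages the two directed values
    ``H_<i,j>(x_i, y_jk)`` and ``H_<j,i>(x_j, y_ik)``: the reference-side term
    of gene i combined with gene j's case probability in sample k, and vice
    versa. All case profiles must share one sample ordering.
    """
    edges = [e for e in network if e.gene_a in ref_profiles and e.gene_b in ref_profiles
             and e.gene_a in case_profiles and e.gene_b in case_profiles]
    dropped = len(network) - len(edges)
    if dropped:
        logger.warning("dropped %d edges with genes missing from the profiles", dropped)
    if not edges:
        raise ValueError("no network edges remain after filtering to profiled genes")

    sample_ids: list[str] | None = None
    for g in {gene for e in edges for gene in e.genes}:
        ids = case_profiles[g].sample_ids
        if sample_ids is None:
            sample_ids = list(ids)
        elif list(ids) != sample_ids:
            raise ValueError(
                f"case profile of gene {g!r} has a different sample ordering"
            )
    assert sample_ids is not None

    n_under = 0
    log_pc: dict[str, np.ndarray] = {}
    neg_ent: dict[str, float] = {}
    for g in {gene for e in edges for gene in e.genes}:
        p = case_profiles[g].probabilities
        n_under += int(np.sum(p < PROBABILITY_FLOOR))
        log_pc[g] = np.log(np.clip(p, PROBABILITY_FLOOR, None))
        neg_ent[g] = ref_profiles[g].neg_entropy
    if n_under:
        logger.warning("clipped %d underflowing case probabilities at %g",
                       n_under, PROBABILITY_FLOOR)

    values = np.empty((len(edges), len(sample_ids)), dtype=float)
    for row, e in enumerate(edges):
        i, j = e.genes
        # 0.5*[(S_i - log pc_j[k]) + (S_j - log pc_i[k])]
        values[row] = 0.5 * (neg_ent[i] + neg_ent[j]) - 0.5 * (log_pc[j] + log_pc[i])
    return LocalEREMatrix(edges=edges, case_sample_ids=sample_ids, values=values)


def top_set_size(top_fraction: float, n_edges: int) -> int:
    """M = max(1, floor(top_fraction * E))."""
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    return max(1, int(math.floor(top_fraction * n_edges)))


def top_set_indices(
    column: np.ndarray, edges: Sequence[EdgeKey], M: int
) -> list[int]:
    """Indices of the M largest entries; ties at the cutoff broken by
    canonical (lexicographic) edge order so selection is deterministic."""
    order = sorted(range(len(edges)), key=lambda r: (-column[r], edges[r]))
    return order[:M]


def sample_ere(
    matrix: LocalEREMatrix, sample_id: str, top_fraction: float = 0.05
) -> SampleERE:
    """Aggregate one case sample's column into H^k.

    S is the sample's ``M = max(1, floor(top_fraction * E))`` largest local
    ERE values; H^k is their mean.
    """
    col = matrix.column(sample_id)
    M = top_set_size(top_fraction, len(matrix.edges))
    idx = top_set_indices(col, matrix.edges, M)
    return SampleERE(
        sample_id=sample_id,
        top_fraction=top_fraction,
        selected_edges=[matrix.edges[r] for r in idx],
        M=M,
        H_k=float(col[idx].mean()),
    )
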