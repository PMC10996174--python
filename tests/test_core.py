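"""Unit and property tests of the entropy primitives."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from edgeentropy.core import (
    CohortVector,
    DegenerateCohortError,
    EdgeKey,
    LocalEREMatrix,
    directed_local_ere,
    edge_entropy_matrix,
    kde_probability_vector,
    plugin_bandwidth,
    sample_ere,
    symmetric_local_ere,
)
from conftest import make_cohort, make_profile


def brute_force_kde_probs(values, ddof=1):
    """Independent O(N^2) Gaussian kernel-sum oracle."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    sigma = math.sqrt(var)
    h = (4.0 * sigma**5 / (3.0 * n)) ** 0.2
    dens = []
    for x in values:
        s = 0.0
        for y in values:
            u = (x - y) / h
            s += math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
        dens.append(s / (n * h))
    total = sum(dens)
    return [d / total for d in dens]


class TestPluginBandwidth:
    def test_closed_form(self):
        assert plugin_bandwidth(1.0, 3) == pytest.approx((4 / 9) ** 0.2, abs=1e-12)
        assert plugin_bandwidth(1.0, 3) == pytest.approx(0.850283, abs=1e-6)
        assert plugin_bandwidth(1.0, 12) == pytest.approx((1 / 9) ** 0.2, abs=1e-12)

    def test_homogeneous_in_sigma(self):
        assert plugin_bandwidth(2.0, 3) == pytest.approx(2 * plugin_bandwidth(1.0, 3), rel=1e-14)

    @given(st.floats(0.01, 100), st.integers(2, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_formula_everywhere(self, sigma, n):
        assert plugin_bandwidth(sigma, n) == pytest.approx(
            (4 * sigma**5 / (3 * n)) ** 0.2, rel=1e-12
        )

    def test_degenerate_cohort_raises(self):
        with pytest.raises(DegenerateCohortError):
            plugin_bandwidth(0.0, 5)
        with pytest.raises(ValueError):
            plugin_bandwidth(1.0, 1)


class TestKdeProbabilityVector:
    def test_two_point_symmetry(self):
        p = make_profile([0.0, 1.0]).probabilities
        assert p == pytest.approx([0.5, 0.5], abs=1e-14)

    def test_equispaced_triple_midpoint_highest(self):
        p = make_profile([0.0, 1.0, 2.0]).probabilities
        assert p[0] == pytest.approx(p[2], abs=1e-14)
        assert p[1] > p[0]

    def test_matches_brute_force_oracle(self):
        vals = [0.3, 1.7, 2.2, 5.0]
        p = make_profile(vals).probabilities
        assert p == pytest.approx(brute_force_kde_probs(vals), abs=1e-12)

    def test_brute_force_agreement_random_cohorts(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 60))
            vals = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n)
            p = make_profile(vals).probabilities
            assert p == pytest.approx(brute_force_kde_probs(vals), abs=1e-12)

    def test_normalized_and_positive(self, rng):
        for _ in range(50):
            vals = rng.normal(0, 1, int(rng.integers(2, 40)))
            prof = make_profile(vals)
            assert abs(prof.probabilities.sum() - 1.0) < 1e-12
            assert np.all(prof.probabilities > 0)

    def test_translation_invariance(self, rng):
        vals = rng.normal(0, 1, 20)
        p0 = make_profile(vals).probabilities
        p1 = make_profile(vals + 137.5).probabilities
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_bandwidth_matches_plugin_formula(self, rng):
        vals = rng.normal(0, 2, 15)
        prof = make_profile(vals)
        assert prof.bandwidth_h == pytest.approx(
            plugin_bandwidth(np.std(vals, ddof=1), 15), rel=1e-14
        )

    def test_constant_cohort_raises(self):
        with pytest.raises(DegenerateCohortError):
            make_profile([2.0, 2.0, 2.0])

    def test_fewer_than_two_samples_raises(self):
        with pytest.raises(DegenerateCohortError):
            make_cohort([1.0])

    def test_scipy_kde_cross_check(self, rng):
        """Densities (pre-normalisation) agree with scipy's Gaussian KDE when
        scipy is forced to the same bandwidth."""
        from scipy.stats import gaussian_kde

        vals = rng.normal(0, 1.3, 25)
        sigma = np.std(vals, ddof=1)
        h = plugin_bandwidth(sigma, len(vals))
        # gaussian_kde's factor multiplies the data std (cov via ddof=1)
        kde = gaussian_kde(vals, bw_method=h / sigma)
        f = kde(vals)
        p = make_profile(vals).probabilities
        assert p == pytest.approx(f / f.sum(), abs=1e-10)


class TestDirectedLocalEre:
    def test_uniform_reference_at_matching_probability_is_zero(self):
        prof = make_profile([0.0, 1.0])  # exactly uniform [.5, .5]
        assert directed_local_ere(prof, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_term_hand_evaluation(self):
        prof = make_profile([0.0, 1.0])
        assert directed_local_ere(prof, 0.25) == pytest.approx(math.log(2), abs=1e-10)

    def test_decomposition_identity(self, rng):
        for _ in range(50):
            vals = rng.normal(0, 1, 10)
            prof = make_profile(vals)
            p_case = float(rng.uniform(1e-6, 1.0))
            expected = float(
                np.sum(prof.probabilities * np.log(prof.probabilities))
            ) - math.log(p_case)
            assert directed_local_ere(prof, p_case) == pytest.approx(expected, abs=1e-10)

    def test_strictly_decreasing_in_case_probability(self, rng):
        prof = make_profile(rng.normal(0, 1, 8))
        ps = np.sort(rng.uniform(1e-8, 1.0, 20))
        vals = [directed_local_ere(prof, p) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_can_be_negative(self):
        prof = make_profile([0.0, 1.0])
        assert directed_local_ere(prof, 0.9) < 0

    def test_nonpositive_probability_rejected(self):
        prof = make_profile([0.0, 1.0])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                directed_local_ere(prof, bad)


class TestSymmetricLocalEre:
    def test_arithmetic_mean_and_symmetry(self):
        assert symmetric_local_ere(0.2, 0.4) == pytest.approx(0.3)
        assert symmetric_local_ere(0.4, 0.2) == pytest.approx(0.3)
        assert symmetric_local_ere(-1.3, -1.3) == -1.3


class TestEdgeKey:
    def test_canonical_ordering(self):
        assert EdgeKey("B", "A") == EdgeKey("A", "B")
        assert EdgeKey("B", "A").gene_a == "A"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            EdgeKey("A", "A")


class TestEdgeEntropyMatrix:
    @staticmethod
    def _profiles(rng, genes, n, label):
        return {
            g: make_profile(rng.normal(0, 1, n), gene=g, label=label) for g in genes
        }

    def test_single_edge_manual_evaluation(self, rng):
        ref = self._profiles(rng, ["A", "B"], 6, "reference")
        case = self._profiles(rng, ["A", "B"], 4, "case")
        m = edge_entropy_matrix(ref, case, [EdgeKey("A", "B")])
        k = 2
        sid = case["A"].sample_ids[k]
        h_ab = directed_local_ere(ref["A"], float(case["B"].probabilities[k]))
        h_ba = directed_local_ere(ref["B"], float(case["A"].probabilities[k]))
        assert m.column(sid)[0] == pytest.approx(0.5 * (h_ab + h_ba), abs=1e-12)

    def test_gene_order_symmetry(self, rng):
        ref = self._profiles(rng, ["A", "B"], 8, "reference")
        case = self._profiles(rng, ["A", "B"], 5, "case")
        m1 = edge_entropy_matrix(ref, case, [EdgeKey("A", "B")])
        m2 = edge_entropy_matrix(ref, case, [EdgeKey("B", "A")])
        assert np.allclose(m1.values, m2.values)

    def test_identical_genes_collapse_to_directed_value(self, rng):
        vals_ref = rng.normal(0, 1, 7)
        vals_case = rng.normal(0, 1, 5)
        ref = {g: make_profile(vals_ref, gene=g) for g in ("A", "B")}
        case = {g: make_profile(vals_case, gene=g, label="case") for g in ("A", "B")}
        m = edge_entropy_matrix(ref, case, [EdgeKey("A", "B")])
        expected = [
            directed_local_ere(ref["A"], float(case["B"].probabilities[k]))
            for k in range(5)
        ]
        assert m.values[0] == pytest.approx(expected, abs=1e-12)

    def test_row_order_follows_input_edges(self, rng):
        genes = ["A", "B", "C"]
        ref = self._profiles(rng, genes, 6, "reference")
        case = self._profiles(rng, genes, 4, "case")
        e1, e2 = EdgeKey("A", "B"), EdgeKey("B", "C")
        m12 = edge_entropy_matrix(ref, case, [e1, e2])
        m21 = edge_entropy_matrix(ref, case, [e2, e1])
        assert np.allclose(m12.values[0], m21.values[1])
        assert np.allclose(m12.values[1], m21.values[0])

    def test_missing_gene_edges_dropped_and_empty_rejected(self, rng):
        ref = self._profiles(rng, ["A", "B"], 6, "reference")
        case = self._profiles(rng, ["A", "B"], 4, "case")
        m = edge_entropy_matrix(ref, case, [EdgeKey("A", "B"), EdgeKey("A", "Z")])
        assert m.edges == [EdgeKey("A", "B")]
        with pytest.raises(ValueError):
            edge_entropy_matrix(ref, case, [EdgeKey("X", "Z")])

    def test_mismatched_case_sample_orderings_rejected(self, rng):
        ref = self._profiles(rng, ["A", "B"], 6, "reference")
        case = self._profiles(rng, ["A", "B"], 4, "case")
        case["B"].sample_ids = list(reversed(case["B"].sample_ids))
        with pytest.raises(ValueError):
            edge_entropy_matrix(ref, case, [EdgeKey("A", "B")])


def random_matrix(rng, n_edges, n_samples):
    genes = [f"g{i:02d}" for i in range(n_edges + 1)]
    edges = [EdgeKey(genes[i], genes[i + 1]) for i in range(n_edges)]
    return LocalEREMatrix(
        edges=edges,
        case_sample_ids=[f"s{k}" for k in range(n_samples)],
        values=rng.normal(0, 1, (n_edges, n_samples)),
    )


class TestSampleEre:
    def test_top_one_is_column_maximum(self, rng):
        m = random_matrix(rng, 20, 3)
        r = sample_ere(m, "s1", top_fraction=0.05)
        assert r.M == 1
        assert r.H_k == pytest.approx(m.column("s1").max())

    def test_full_fraction_is_column_mean(self, rng):
        m = random_matrix(rng, 20, 3)
        r = sample_ere(m, "s0", top_fraction=1.0)
        assert r.M == 20
        assert r.H_k == pytest.approx(m.column("s0").mean())

    def test_matches_sort_oracle(self, rng):
        m = random_matrix(rng, 100, 4)
        for sid in m.case_sample_ids:
            r = sample_ere(m, sid, top_fraction=0.05)
            top5 = sorted(m.column(sid))[-5:]
            assert r.M == 5
            assert r.H_k == pytest.approx(sum(top5) / 5, abs=1e-12)

    def test_top_fraction_monotonicity(self, rng):
        m = random_matrix(rng, 60, 2)
        fracs = [0.05, 0.1, 0.25, 0.5, 1.0]
        hks = [sample_ere(m, "s0", f).H_k for f in fracs]
        assert all(a >= b - 1e-12 for a, b in zip(hks, hks[1:]))

    def test_aggregate_bounds_and_selection_consistency(self, rng):
        m = random_matrix(rng, 40, 1)
        r = sample_ere(m, "s0", top_fraction=0.2)
        col = m.column("s0")
        assert r.H_k >= col.mean() - 1e-12
        selected = {e for e in r.selected_edges}
        unselected_max = max(
            col[i] for i, e in enumerate(m.edges) if e not in selected
        )
        assert min(col[m.edges.index(e)] for e in selected) >= unselected_max - 1e-12

    def test_deterministic_tie_break_by_edge_order(self):
        edges = [EdgeKey("A", "B"), EdgeKey("A", "C"), EdgeKey("B", "C")]
        m = LocalEREMatrix(edges=edges, case_sample_ids=["s"],
                           values=np.array([[1.0], [1.0], [1.0]]))
        r = sample_ere(m, "s", top_fraction=0.4)  # M = 1, three-way tie
        assert r.selected_edges == [EdgeKey("A", "B")]

    def test_unknown_sample_rejected(self, rng):
        with pytest.raises(KeyError):
            sample_ere(random_matrix(rng, 5, 2), "nope")


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=30, unique=True),
       st.floats(0.05, 1.0))
@settings(max_examples=100, deadline=None)
def test_property_probability_vector_and_entropy_identity(values, p_case):
    """KDE probabilities are a strictly positive unit-sum vector and the
    directed score obeys its algebraic decomposition, for arbitrary cohorts."""
    assume(float(np.std(values, ddof=1)) > 1e-9)
    prof = make_profile(values)
    assert abs(float(prof.probabilities.sum()) - 1.0) < 1e-12
    assert np.all(prof.probabilities > 0)
    lhs = directed_local_ere(prof, p_case)
    rhs = float(np.sum(prof.probabilities * np.log(prof.probabilities))) - math.log(p_case)
    assert lhs == pytest.approx(rhs, abs=1e-10)
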