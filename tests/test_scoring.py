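import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_adjust, hypergeom_upper_tail
from knms.scoring import (
    contribution_coefficient,
    enrich_pathways,
    gene_coverage,
    normalized_importance,
    pathway_coverage,
    round1,
)
from knms.types import PathwayCollection
from statsmodels.stats.multitest import multipletests


DEGREES = {"A": 4, "B": 3, "C": 2, "D": 1}


class TestNormalizedImportance:
    def test_min_max_example(self):
        r = normalized_importance(DEGREES)
        assert r == {"A": 1.0, "B": 2 / 3, "C": 1 / 3, "D": 0.0}

    def test_all_equal_degrees_degenerate_to_one(self):
        assert normalized_importance({"A": 3, "B": 3}) == {"A": 1.0, "B": 1.0}

    def test_single_component(self):
        assert normalized_importance({"A": 7}) == {"A": 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            normalized_importance({})


class TestContributionCoefficient:
    def test_full_set_is_100(self):
        assert math.isclose(contribution_coefficient(DEGREES, DEGREES), 100.0)

    def test_hand_example(self):
        cc = contribution_coefficient({"A", "B"}, DEGREES)
        assert round(cc, 2) == 83.33

    def test_zero_importance_module(self):
        assert contribution_coefficient({"D"}, DEGREES) == 0.0

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            contribution_coefficient({"Z"}, DEGREES)

    @given(st.integers(min_value=0, max_value=2 ** 6 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_additive_over_disjoint_modules(self, mask):
        comps = ["A", "B", "C", "D", "E", "F"]
        degrees = {c: i + 1 for i, c in enumerate(comps)}
        left = {c for i, c in enumerate(comps) if mask >> i & 1}
        right = set(comps) - left
        total = contribution_coefficient(left, degrees) + \
            contribution_coefficient(right, degrees)
        assert math.isclose(total, 100.0, abs_tol=1e-9)


class TestGeneCoverage:
    @pytest.mark.parametrize("n_knms,n_ct,expected", [
        (39, 50, 78.0), (40, 52, 76.9), (30, 39, 76.9)])
    def test_published_count_arithmetic(self, n_knms, n_ct, expected):
        disease = {f"G{i}" for i in range(n_ct)}
        ct = disease | {f"X{i}" for i in range(5)}
        knms = {f"G{i}" for i in range(n_knms)}
        cov, k_knms, k_ct = gene_coverage(knms, ct, disease)
        assert (cov, k_knms, k_ct) == (expected, n_knms, n_ct)

    def test_identical_sets_100(self):
        cov, _, _ = gene_coverage({"A", "B"}, {"A", "B"}, {"A", "B"})
        assert cov == 100.0

    def test_no_disease_genes_flagged_undefined(self):
        cov, _, k_ct = gene_coverage({"A"}, {"A"}, {"Z"})
        assert cov is None and k_ct == 0


class TestEnrichPathways:
    def test_matches_enumeration_oracle_exhaustively(self):
        """Hypergeometric p equals brute-force enumeration for all N <= 12."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            N = int(rng.integers(3, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            bg = [f"g{i}" for i in range(N)]
            pw_genes = set(rng.choice(bg, size=K, replace=False).tolist())
            query = set(rng.choice(bg, size=n, replace=False).tolist())
            k = len(query & pw_genes)
            coll = PathwayCollection({"PW": ("d", frozenset(g.upper() for g in pw_genes))})
            res = enrich_pathways(query, coll, background=bg)
            assert abs(res.tests[0].p_value - hypergeom_upper_tail(k, N, K, n)) < 1e-12

    def test_known_exact_value(self):
        bg = [f"g{i}" for i in range(10)]
        coll = PathwayCollection({"PW": ("d", frozenset(g.upper() for g in bg[:5]))})
        res = enrich_pathways(bg[:4], coll, background=bg)
        assert abs(res.tests[0].p_value - 5 / 210) < 1e-12

    def test_p_monotone_in_overlap(self):
        bg = [f"g{i}" for i in range(12)]
        coll = PathwayCollection({"PW": ("d", frozenset(g.upper() for g in bg[:6]))})
        ps = []
        for k in range(5):
            query = bg[:k] + bg[6:6 + (4 - k)]  # n = 4 fixed, overlap = k
            ps.append(enrich_pathways(query, coll, background=bg).tests[0].p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_overlap_p_is_one(self):
        bg = ["a", "b", "c", "d"]
        coll = PathwayCollection({"PW": ("d", frozenset({"A", "B"}))})
        res = enrich_pathways(["c", "d"], coll, background=bg)
        assert res.tests[0].p_value == 1.0

    def test_bh_adjustment_and_cutoff(self):
        bg = [f"g{i}" for i in range(30)]
        coll = PathwayCollection({
            f"PW{i}": ("d", frozenset(f"G{j}" for j in range(i, i + 8)))
            for i in range(5)})
        res = enrich_pathways(bg[:8], coll, background=bg + [f"G{j}" for j in range(13)],
                              adjust="bh")
        raw = [t.p_value for t in res.tests]
        expected_q = bh_adjust(raw)
        for t, q in zip(res.tests, expected_q):
            assert abs(t.q_value - q) < 1e-12

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            enrich_pathways(["A"], PathwayCollection({"P": ("d", frozenset({"A"}))}),
                            background=[])


def test_bh_matches_hand_computed_five_values():
    pvals = [0.01, 0.04, 0.03, 0.005, 0.20]
    expected = bh_adjust(pvals)
    # hand check of the step-up on sorted values (0.005,0.01,0.03,0.04,0.20):
    # 0.005*5/1=0.025; 0.01*5/2=0.025; 0.03*5/3=0.05; 0.04*5/4=0.05; 0.20
    assert expected == pytest.approx([0.025, 0.05, 0.05, 0.025, 0.20], abs=1e-12)
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(q, expected)


class TestPathwayCoverage:
    @pytest.mark.parametrize("n_sub,n_ref,expected", [
        (158, 165, 95.8), (144, 151, 95.4), (102, 110, 92.7)])
    def test_published_fraction_arithmetic(self, n_sub, n_ref, expected):
        ref = {f"P{i}" for i in range(n_ref)}
        sub = {f"P{i}" for i in range(n_sub)}
        assert pathway_coverage(sub, ref) == expected

    def test_identical_sets(self):
        assert pathway_coverage({"P1"}, {"P1"}) == 100.0

    def test_monotone_in_subset(self):
        ref = {f"P{i}" for i in range(10)}
        covs = [pathway_coverage({f"P{i}" for i in range(k)}, ref) for k in range(11)]
        assert covs == sorted(covs)

    def test_empty_reference_undefined(self):
        assert pathway_coverage({"P1"}, set()) is None


def test_round1_is_half_even_reporting_rule():
    # 0.25 and 0.75 are exact binary halves: round half to even
    assert round1(0.25) == 0.2 and round1(0.75) == 0.8
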