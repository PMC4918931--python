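import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divrao as dv
from divrao.data import ValidationError
from .conftest import brute_force_partition, brute_force_rao


def av(*p):
    return dv.AbundanceVector([f"s{i}" for i in range(len(p))], np.array(p))


def dm(d):
    d = np.asarray(d, dtype=float)
    return dv.DissimilarityMatrix([f"s{i}" for i in range(d.shape[0])], d)


class TestEntropies:
    def test_single_species_has_zero_entropy(self):
        assert dv.rao_entropy(av(1.0), dm([[0.0]])) == 0.0
        assert dv.simpson_entropy(av(1.0)) == 0.0

    @pytest.mark.parametrize(
        "d12,expected", [(1.0, 0.5), (0.4, 0.2)],
        ids=["distinct-pair", "partially-similar-pair"],
    )
    def test_even_pair_rao(self, d12, expected):
        D = dm([[0, d12], [d12, 0]])
        assert dv.rao_entropy(av(0.5, 0.5), D) == pytest.approx(expected, abs=1e-15)

    def test_simpson_even_pair(self):
        assert dv.simpson_entropy(av(0.5, 0.5)) == pytest.approx(0.5, abs=1e-15)

    def test_misaligned_labels_error(self):
        D = dv.DissimilarityMatrix(["x", "y"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            dv.rao_entropy(av(0.5, 0.5), D)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=10), min_size=1, max_size=10))
    def test_rao_under_all_ones_equals_simpson(self, weights):
        p = np.array(weights) / np.sum(weights)
        vec = dv.AbundanceVector([f"s{i}" for i in range(len(p))], p)
        D = dv.taxonomic_distance(vec.species_ids)
        assert dv.rao_entropy(vec, D) == pytest.approx(
            dv.simpson_entropy(vec), abs=1e-12
        )


class TestJost:
    def test_analytic_values(self):
        assert dv.jost_correct(0.0) == 1.0
        assert dv.jost_correct(0.5) == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            dv.jost_correct(1.0)

    def test_even_maximally_distinct_community_counts_species(self):
        for S in range(1, 51):
            vec = av(*([1.0 / S] * S))
            assert dv.jost_correct(dv.simpson_entropy(vec)) == pytest.approx(
                S, rel=1e-12
            )


class TestPartition:
    def test_identical_transects_have_no_beta(self):
        m = dv.CommunityMatrix(
            pd.DataFrame([[3, 3], [3, 3], [3, 3], [3, 3]],
                         index=list("wxyz"), columns=["a", "b"])
        )
        h = dv.SpatialHierarchy({"w": "G1", "x": "G1", "y": "G2", "z": "G2"})
        p = dv.partition_two_level(m, h)
        assert p.beta1 == pytest.approx(0.0, abs=1e-12)
        assert p.beta2 == pytest.approx(0.0, abs=1e-12)
        assert p.gamma == pytest.approx(p.alpha1, abs=1e-12)

    def test_worked_two_transect_example(self, toy_matrix, toy_hierarchy):
        p = dv.partition_two_level(toy_matrix, toy_hierarchy)
        assert p.alpha1 == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert p.gamma == pytest.approx(1.6, abs=1e-12)
        assert p.gamma - p.alpha1 == pytest.approx(0.2667, abs=5e-5)
        total_beta_prop = (p.gamma - p.alpha1) / p.gamma
        assert total_beta_prop == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_full_functional_redundancy_collapses_fd(self, toy_matrix, toy_hierarchy):
        D = dv.DissimilarityMatrix(["spA", "spB"], np.zeros((2, 2)))
        p = dv.partition_two_level(toy_matrix, toy_hierarchy, D=D, facet="FD")
        assert p.alpha1 == p.alpha2 == p.gamma == 1.0
        assert p.beta1 == p.beta2 == 0.0

    def test_matches_bruteforce_on_random_3x4(self):
        rng = np.random.default_rng(42)
        d = rng.random((4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0, 1)
        for _ in range(25):
            counts = rng.integers(0, 9, size=(3, 4))
            if (counts.sum(axis=1) == 0).any():
                continue
            m = dv.CommunityMatrix(
                pd.DataFrame(counts, index=["t1", "t2", "t3"],
                             columns=[f"s{i}" for i in range(4)])
            )
            h = dv.SpatialHierarchy({"t1": "G1", "t2": "G1", "t3": "G2"})
            for conv in ("mean-then-correct", "correct-then-mean"):
                got = dv.partition_two_level(
                    m, h, D=dm(d), facet="FD", convention=conv
                )
                want = brute_force_partition(
                    counts.tolist(),
                    ["G1", "G1", "G2"],
                    d.tolist(),
                    convention=conv,
                )
                for comp, val in want.items():
                    assert getattr(got, comp) == pytest.approx(val, abs=1e-12)

    def test_proportions_sum_to_one(self, default_run):
        m, t, h, _ = default_run
        for D, facet in [(None, "TD"), (dv.gower_distance(t), "FD")]:
            p = dv.partition_two_level(m, h, D=D, facet=facet)
            assert p.prop_alpha1 + p.prop_beta1 + p.prop_beta2 == pytest.approx(
                1.0, abs=1e-9
            )
            assert p.beta1 >= -1e-9 and p.beta2 >= -1e-9

    def test_fd_never_exceeds_td(self, default_run):
        m, t, h, _ = default_run
        td = dv.partition_two_level(m, h)
        fd = dv.partition_two_level(m, h, D=dv.gower_distance(t), facet="FD")
        for comp in ("alpha1", "alpha2", "gamma"):
            assert getattr(fd, comp) <= getattr(td, comp) + 1e-9

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=9), min_size=4, max_size=4),
            min_size=4,
            max_size=4,
        ).filter(lambda rows: all(any(r) for r in rows))
    )
    def test_concavity_with_equal_transect_totals(self, rows):
        # scale rows to a common total so pooling counts == averaging p-vectors
        rows = np.array(rows, dtype=int)
        scaled = rows * np.prod([r.sum() for r in rows]) // rows.sum(axis=1)[:, None]
        m = dv.CommunityMatrix(
            pd.DataFrame(scaled, index=list("wxyz"), columns=list("abcd"))
        )
        h = dv.SpatialHierarchy({"w": "G1", "x": "G1", "y": "G2", "z": "G2"})
        p = dv.partition_two_level(m, h)
        assert p.alpha1 <= p.alpha2 + 1e-9
        assert p.alpha2 <= p.gamma + 1e-9

    def test_invariant_to_site_and_species_permutation(self, default_run):
        m, t, h, _ = default_run
        D = dv.gower_distance(t)
        base = dv.partition_two_level(m, h, D=D, facet="FD")
        rng = np.random.default_rng(0)
        df = m.counts.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        shuffled = dv.partition_two_level(
            dv.CommunityMatrix(df), h, D=D, facet="FD"
        )
        for comp in ("alpha1", "beta1", "alpha2", "beta2", "gamma"):
            assert getattr(shuffled, comp) == pytest.approx(
                getattr(base, comp), abs=1e-9
            )

    def test_beta1_contributions_are_percentages(self, default_run):
        m, _, h, _ = default_run
        p = dv.partition_two_level(m, h)
        assert len(p.beta1_contrib_pct) == 7
        assert ((p.beta1_contrib_pct >= -1e-9) & (p.beta1_contrib_pct <= 100)).all()

    def test_group_with_no_individuals_errors(self, toy_matrix):
        h = dv.SpatialHierarchy({"T1": "G1", "T2": "G1", "T3": "G2"})
        with pytest.raises(ValidationError):
            dv.partition_two_level(toy_matrix, h)


class TestRichness:
    def test_counting_levels(self, toy_matrix, toy_hierarchy):
        per_site = dv.richness(toy_matrix)
        assert per_site.tolist() == [2, 1]
        per_group = dv.richness(toy_matrix, toy_hierarchy, level="group")
        assert per_group.tolist() == [2]
        assert dv.richness(toy_matrix, level="total") == 2
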