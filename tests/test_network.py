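import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dissonet as dn
from dissonet import RosterError

from conftest import random_two_layer


class TestLoadLayer:
    def test_direct_construction(self):
        layer = dn.load_layer([(1, 2), (2, 1)], roster=[1, 2, 3])
        assert layer.sum() == 2
        assert layer[0, 1] == 1 and layer[1, 0] == 1

    def test_empty_edge_table(self):
        assert dn.load_layer([], roster=[1, 2, 3]).sum() == 0

    def test_duplicates_collapse(self):
        layer = dn.load_layer([(1, 2), (1, 2)], roster=[1, 2])
        assert layer.sum() == 1

    def test_unknown_actor_is_fatal_and_named(self):
        with pytest.raises(RosterError, match="99"):
            dn.load_layer([(1, 99)], roster=[1, 2])

    def test_self_nomination_warns_and_drops(self):
        with pytest.warns(UserWarning, match="self-nomination"):
            layer = dn.load_layer([(1, 1), (1, 2)], roster=[1, 2])
        assert layer.sum() == 1 and layer[0, 0] == 0


class TestMergeDislikeItems:
    def test_union(self):
        layer = dn.merge_dislike_items([(1, 2)], [(2, 3)], roster=[1, 2, 3])
        assert layer[0, 1] == 1 and layer[1, 2] == 1 and layer.sum() == 2

    def test_union_idempotent(self):
        layer = dn.merge_dislike_items([(1, 2)], [(1, 2)], roster=[1, 2, 3])
        assert layer.sum() == 1

    def test_both_empty(self):
        assert dn.merge_dislike_items([], [], roster=[1, 2]).sum() == 0

    @given(
        edges_a=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(lambda e: e[0] != e[1]),
            max_size=10,
        ),
        edges_b=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(lambda e: e[0] != e[1]),
            max_size=10,
        ),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_commutative_and_idempotent(self, edges_a, edges_b):
        roster = list(range(5))
        ab = dn.merge_dislike_items(edges_a, edges_b, roster)
        ba = dn.merge_dislike_items(edges_b, edges_a, roster)
        aa = dn.merge_dislike_items(edges_a, edges_a, roster)
        assert (ab == ba).all()
        assert (aa == dn.load_layer(edges_a, roster)).all()


class TestSubnetwork:
    def test_cross_gender_ties_discarded(self):
        g = dn.TwoLayerDigraph(
            F=dn.load_layer([(0, 1), (2, 3), (1, 2)], roster=range(4)),
            D=np.zeros((4, 4), np.uint8),
        )
        attrs = dn.ActorTable(
            pwb=[50, 51, 52, 53], smf=[1, 2, 3, 4], ses=[0, 1, 0, 1],
            gender=np.array(["boy", "girl", "boy", "girl"], object),
        )
        sub_g, sub_a = dn.subnetwork_by_group(g, attrs, "boy")
        assert sub_g.n == 2 and sub_g.F.sum() == 0
        assert list(sub_a.smf) == [1, 3]

    def test_whole_group_is_identity(self):
        g, attrs = dn.fixture("triangle")
        sub_g, sub_a = dn.subnetwork_by_group(g, attrs, "boy")
        assert (sub_g.F == g.F).all() and (sub_g.D == g.D).all()
        assert sub_a.actor_ids == attrs.actor_ids

    def test_matches_brute_force_pair_filter(self):
        g, attrs = dn.fixture("mixed-gender-6")
        for group in ("boy", "girl"):
            sub_g, _ = dn.subnetwork_by_group(g, attrs, group)
            members = [k for k, lab in enumerate(attrs.gender) if lab == group]
            for layer in ("F", "D"):
                expected = {
                    (members.index(i), members.index(j))
                    for i in members
                    for j in members
                    if i != j and g.layer(layer)[i, j]
                }
                got = set(zip(*np.nonzero(sub_g.layer(layer))))
                assert got == expected

    def test_empty_group_fatal(self):
        g, attrs = dn.fixture("triangle")
        with pytest.raises(RosterError):
            dn.subnetwork_by_group(g, attrs, "girl")


class TestSummarize:
    @pytest.mark.parametrize(
        "n,ties,density,mean_degree",
        [(59, 242, 0.07072, 4.10169), (61, 90, 0.02459, 1.47541)],
    )
    def test_density_and_mean_degree_to_five_decimals(self, rng, n, ties, density, mean_degree):
        # any layer with the given tie count gives the same density/mean degree
        layer = np.zeros((n, n), np.uint8)
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
        for k in rng.choice(len(slots), size=ties, replace=False):
            layer[slots[k]] = 1
        s = dn.summarize_layer(layer, n)
        assert round(s.density, 5) == density
        assert round(s.mean_degree, 5) == mean_degree
        assert s.n_ties == ties

    def test_complete_digraph(self):
        layer = 1 - np.eye(4, dtype=np.uint8)
        s = dn.summarize_layer(layer, 4)
        assert s.density == 1.0
        assert s.min_indegree == s.max_indegree == s.min_outdegree == s.max_outdegree == 3

    def test_too_small_is_fatal(self):
        with pytest.raises(ValueError):
            dn.summarize_layer(np.zeros((1, 1)), 1)

    def test_degree_sum_identities(self, rng):
        g = random_two_layer(rng, 9)
        s = dn.summarize_layer(g.F, 9)
        assert s.n_ties == g.F.sum() == g.F.sum(axis=0).sum() == g.F.sum(axis=1).sum()
        assert 0 <= s.density <= 1
        assert s.n_reciprocated_pairs <= s.n_ties / 2


class TestPairCounts:
    def test_reciprocated_basic(self):
        layer = dn.load_layer([(1, 2), (2, 1), (1, 3)], roster=[1, 2, 3])
        assert dn.count_reciprocated_pairs(layer) == 1
        assert dn.count_reciprocated_pairs(np.zeros((4, 4))) == 0

    def test_reciprocated_matches_enumeration(self, rng):
        g = random_two_layer(rng, 8)
        expected = sum(
            1 for i in range(8) for j in range(i + 1, 8) if g.F[i, j] and g.F[j, i]
        )
        assert dn.count_reciprocated_pairs(g.F) == expected

    def test_exchange_basic(self):
        F = dn.load_layer([(1, 2)], roster=[1, 2])
        D = dn.load_layer([(2, 1)], roster=[1, 2])
        assert dn.count_exchange_pairs(F, D) == 1
        F2 = dn.load_layer([(1, 2), (2, 1)], roster=[1, 2])
        assert dn.count_exchange_pairs(F2, np.zeros((2, 2))) == 0

    def test_exchange_matches_enumeration_and_symmetry(self, rng):
        g = random_two_layer(rng, 8)
        expected = sum(
            1 for i in range(8) for j in range(8) if i != j and g.F[i, j] and g.D[j, i]
        )
        assert dn.count_exchange_pairs(g.F, g.D) == expected
        # the defining pattern is symmetric under transposing both layers
        # and swapping their roles
        assert dn.count_exchange_pairs(g.F, g.D) == dn.count_exchange_pairs(g.D.T, g.F.T)


class TestMixing:
    def test_all_boy_boy(self):
        layer = dn.load_layer([(0, 1), (1, 0)], roster=range(3))
        mix = dn.mixing_proportions(layer, ["boy", "boy", "girl"])
        assert mix.percent["boy-boy"] == 100.0
        assert sum(mix.percent.values()) == pytest.approx(100.0)

    def test_single_girl_to_boy(self):
        layer = dn.load_layer([(0, 1)], roster=range(2))
        mix = dn.mixing_proportions(layer, ["girl", "boy"])
        assert mix.percent["girl-to-boy"] == 100.0
        assert mix.percent["boy-to-girl"] == 0.0

    def test_hand_count(self):
        g, attrs = dn.fixture("mixed-gender-6")
        mix = dn.mixing_proportions(g.F, attrs.gender)
        # F ties: boys 0,2,4 / girls 1,3,5; by hand: bb {0-2,2-0,2-4},
        # gg {1-3,3-5,5-1}, bg {0-1}, gb {3-2}
        assert mix.n_ties == 8
        assert mix.percent["boy-boy"] == pytest.approx(37.5)
        assert mix.percent["girl-girl"] == pytest.approx(37.5)
        assert mix.percent["boy-to-girl"] == pytest.approx(12.5)
        assert mix.percent["girl-to-boy"] == pytest.approx(12.5)

    def test_no_ties_gives_explicit_empty(self):
        mix = dn.mixing_proportions(np.zeros((3, 3)), ["boy"] * 3)
        assert not mix.defined and mix.n_ties == 0


class TestPooledT:
    def test_published_wellbeing_comparison(self):
        t, df = dn.pooled_t(58.2, 12.6, 61, 61.1, 11.6, 59)
        assert df == 118
        assert round(t, 2) == -1.31

    def test_identical_groups(self):
        t, df = dn.pooled_t(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0 and df == 20

    def test_matches_direct_formula(self):
        m1, s1, n1, m2, s2, n2 = 6.0, 5.1, 61, 4.0, 5.0, 59
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        expected = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, df = dn.pooled_t(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(expected, abs=1e-12)
        assert df == 118

    def test_zero_variance_fatal(self):
        with pytest.raises(ValueError):
            dn.pooled_t(1.0, 0.0, 5, 1.0, 0.0, 5)


def test_data_point_count():
    assert dn.n_tie_variables(59) == 6844
    assert dn.n_tie_variables(61) == 7320


def test_graph_invariants_enforced():
    with pytest.raises(ValueError):
        dn.TwoLayerDigraph(F=np.eye(3), D=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        dn.TwoLayerDigraph(F=np.full((3, 3), 2), D=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        dn.ActorTable(pwb=[10], smf=[0], ses=[0], gender=["boy"])  # pwb below range


def test_csv_round_trip(tmp_path):
    g, attrs = dn.fixture("mixed-gender-6")
    dn.write_edge_list(g.F, g.actor_ids, tmp_path / "f.csv")
    dn.write_edge_list(g.D, g.actor_ids, tmp_path / "d.csv")
    dn.write_attribute_table(attrs, tmp_path / "a.csv")
    g2, attrs2 = dn.load_cohort(tmp_path / "f.csv", tmp_path / "d.csv", tmp_path / "a.csv")
    assert (g2.F == g.F).all() and (g2.D == g.D).all()
    assert attrs2.actor_ids == attrs.actor_ids
    assert np.array_equal(attrs2.pwb, attrs.pwb)
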