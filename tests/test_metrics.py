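import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from helpers_oracles import nodf_bruteforce, pearson_oracle, sci_bruteforce
from matenet import (
    MetricValue,
    edge_trait_pairs,
    from_incidence,
    metric_report,
    newman_assortativity,
    nodf,
    scic,
    sperm_competition_intensity,
)
from matenet.metrics import (
    UNDEF_EMPTY,
    UNDEF_NO_EDGE_END_VAR,
    UNDEF_NO_FEMALE_VAR,
    UNDEF_NO_MALE_VAR,
)
from matenet.simulator import SimulationConfig, random_mating_network

matrices_with_edges = (
    arrays(
        np.int8,
        st.tuples(st.integers(2, 6), st.integers(2, 6)),
        elements=st.integers(0, 1),
    )
    .filter(lambda a: a.sum() >= 1)
)


class TestMetricValue:
    def test_mutually_exclusive(self):
        with pytest.raises(ValueError):
            MetricValue(value=1.0, reason="empty-network")
        with pytest.raises(ValueError):
            MetricValue()

    def test_rendering(self):
        assert MetricValue.defined(0.5).as_string("{:.3f}") == "0.500"
        assert MetricValue.undefined(UNDEF_EMPTY).as_string() == "NA:empty-network"

    def test_float_conversion(self):
        assert float(MetricValue.defined(0.25)) == 0.25
        assert np.isnan(float(MetricValue.undefined(UNDEF_EMPTY)))


class TestEdgeTraitPairs:
    def test_directed_two_by_two(self, two_by_two):
        pairs = edge_trait_pairs(two_by_two, "directed").pairs
        assert sorted(map(tuple, pairs)) == [(1, 2), (2, 1), (2, 2)]

    def test_undirected_doubles(self, two_by_two):
        etp = edge_trait_pairs(two_by_two, "undirected")
        assert len(etp.pairs) == 6
        directed = edge_trait_pairs(two_by_two, "directed").pairs
        assert (etp.pairs[:3] == directed).all()
        assert (etp.pairs[3:] == directed[:, ::-1]).all()

    def test_monogamy(self):
        pairs = edge_trait_pairs(from_incidence([[1, 0], [0, 1]]), "directed").pairs
        assert pairs.tolist() == [[1, 1], [1, 1]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            edge_trait_pairs(from_incidence([[0]]), "directed")

    def test_bad_mode(self, two_by_two):
        with pytest.raises(ValueError, match="mode"):
            edge_trait_pairs(two_by_two, "both")


class TestNewmanAssortativity:
    def test_directed_worked_example(self, two_by_two):
        # hand Pearson on pairs (2,2),(2,1),(1,2): r = -1/2
        assert newman_assortativity(two_by_two, "directed").value == pytest.approx(-0.5)

    def test_undirected_worked_example(self, two_by_two):
        assert newman_assortativity(two_by_two, "undirected").value == pytest.approx(-0.5)

    def test_complete_undefined(self):
        mv = newman_assortativity(from_incidence(np.ones((2, 2), int)))
        assert mv.reason == UNDEF_NO_EDGE_END_VAR

    def test_single_edge_undefined(self):
        mv = newman_assortativity(from_incidence([[1]]))
        assert mv.reason == UNDEF_NO_EDGE_END_VAR

    @given(matrices_with_edges)
    @settings(max_examples=100)
    def test_matches_pearson_oracle_and_bounds(self, mat):
        net = from_incidence(mat)
        for mode in ("directed", "undirected"):
            mv = newman_assortativity(net, mode)
            pairs = edge_trait_pairs(net, mode).pairs
            j, k = pairs[:, 0], pairs[:, 1]
            if np.ptp(j) == 0 or np.ptp(k) == 0:
                assert mv.reason == UNDEF_NO_EDGE_END_VAR
            else:
                assert -1 - 1e-12 <= mv.value <= 1 + 1e-12
                assert mv.value == pytest.approx(pearson_oracle(j, k), abs=1e-12)

    @given(arrays(np.int8, st.tuples(st.integers(2, 5), st.integers(2, 5)),
                  elements=st.integers(0, 1)).filter(lambda a: a.sum() >= 1))
    @settings(max_examples=60)
    def test_symmetric_incidence_equal_modes(self, mat):
        # symmetrise: works for any square matrix built as max(a, a.T)
        sym = np.maximum(mat[: min(mat.shape), : min(mat.shape)],
                         mat[: min(mat.shape), : min(mat.shape)].T)
        if sym.sum() == 0:
            return
        net = from_incidence(sym)
        d = newman_assortativity(net, "directed")
        u = newman_assortativity(net, "undirected")
        assert d.is_defined == u.is_defined
        if d.is_defined:
            assert d.value == pytest.approx(u.value, abs=1e-12)


class TestNodf:
    def test_fully_overlapping_pair_scores_100(self):
        # two males with degrees 6 and 5, lower's partners all shared
        inc = np.zeros((2, 6), dtype=int)
        inc[0] = 1
        inc[1, :5] = 1
        detail = nodf(from_incidence(inc))
        pair_idx = np.flatnonzero((detail.row_pairs == [0, 1]).all(axis=1))[0]
        assert detail.row_df[pair_idx] == 100.0
        assert detail.row_po[pair_idx] == 100.0
        assert detail.row_n[pair_idx] == 100.0

    def test_complete_matrix_zero(self):
        assert nodf(from_incidence(np.ones((3, 4), int))).value == 0.0

    def test_staircase_perfect(self, staircase):
        assert nodf(staircase).value == 100.0

    def test_detail_invariants(self, rng):
        net = random_mating_network(
            SimulationConfig(n_males=6, n_females=6, mating_density=0.5, seed=7)
        )
        detail = nodf(net)
        assert ((detail.row_df == 0) | (detail.row_df == 100)).all()
        assert (detail.row_n[detail.row_df == 0] == 0).all()
        assert (detail.row_n[detail.row_df == 100]
                == detail.row_po[detail.row_df == 100]).all()
        assert 0 <= detail.value <= 100

    @given(matrices_with_edges)
    @settings(max_examples=100)
    def test_matches_bruteforce_oracle(self, mat):
        net = from_incidence(mat)
        sub = mat[mat.sum(axis=1) > 0][:, mat.sum(axis=0) > 0]
        if sub.shape[0] < 2 and sub.shape[1] < 2:
            return
        assert nodf(net).value == pytest.approx(nodf_bruteforce(mat), abs=1e-10)

    @given(matrices_with_edges, st.integers(0, 2**32 - 1))
    @settings(max_examples=60)
    def test_permutation_invariance(self, mat, seed):
        rng = np.random.default_rng(seed)
        shuffled = mat[rng.permutation(mat.shape[0])][:, rng.permutation(mat.shape[1])]
        sub = mat[mat.sum(axis=1) > 0][:, mat.sum(axis=0) > 0]
        if sub.shape[0] < 2 and sub.shape[1] < 2:
            return
        assert nodf(from_incidence(mat)).value == pytest.approx(
            nodf(from_incidence(shuffled)).value, abs=1e-10
        )

    def test_zero_degree_lower_guard(self):
        detail = nodf(from_incidence([[1, 1], [0, 0]]), include_unmated=True)
        assert detail.value == 0.0

    def test_one_by_one_rejected(self):
        with pytest.raises(ValueError, match="two rows or two columns"):
            nodf(from_incidence([[1]]))


class TestSpermCompetitionIntensity:
    def test_worked_example(self, sci_example):
        res = sperm_competition_intensity(sci_example)
        assert res.paternity_share[0] == pytest.approx(2 / 3)
        assert res.sci[0] == pytest.approx(1.5)

    def test_monandrous_partners_give_one(self):
        res = sperm_competition_intensity(from_incidence([[1, 1, 1]]))
        assert res.sci[0] == 1.0

    def test_weighted_single_shared_female(self):
        # focal male contributes 2 of the female's 3 copulations
        net = from_incidence(
            [[1], [1]], weights=np.array([[2], [1]])
        )
        res = sperm_competition_intensity(net, weighted=True)
        assert res.paternity_share[0] == pytest.approx(2 / 3)
        assert res.sci[0] == pytest.approx(1.5)
        assert res.weighted

    def test_unmated_male_nan(self):
        res = sperm_competition_intensity(from_incidence([[1, 1], [0, 0]]))
        assert np.isnan(res.sci[1]) and np.isnan(res.paternity_share[1])

    def test_reciprocal_identity(self, sci_example):
        res = sperm_competition_intensity(sci_example)
        assert np.allclose(res.sci, 1 / res.paternity_share)

    @given(matrices_with_edges)
    @settings(max_examples=100)
    def test_bounds_and_bruteforce(self, mat):
        net = from_incidence(mat)
        res = sperm_competition_intensity(net)
        k = mat.sum(axis=0)
        for i in range(mat.shape[0]):
            partners = np.flatnonzero(mat[i])
            if len(partners) == 0:
                assert np.isnan(res.sci[i])
                continue
            assert res.sci[i] == pytest.approx(sci_bruteforce(mat, i), abs=1e-12)
            assert k[partners].min() - 1e-12 <= res.sci[i] <= k[partners].max() + 1e-12
            # SCI = 1 iff every partner is monandrous
            assert (res.sci[i] == pytest.approx(1.0)) == (k[partners].max() == 1)


class TestScic:
    def test_monogamy_undefined(self):
        mv = scic(from_incidence(np.eye(3, dtype=int)))
        assert mv.reason == UNDEF_NO_MALE_VAR

    def test_constant_sci_correlation_undefined(self):
        # varied male success, all females monandrous
        mv = scic(from_incidence([[1, 1, 1, 0], [0, 0, 0, 1]]), form="correlation")
        assert mv.reason == UNDEF_NO_FEMALE_VAR

    def test_constant_sci_slope_is_zero(self):
        mv = scic(from_incidence([[1, 1, 1, 0], [0, 0, 0, 1]]), form="slope")
        assert mv.value == pytest.approx(0.0)

    def test_block_network_perfect_correlation(self, block_plus_pair):
        assert scic(block_plus_pair, form="correlation").value == pytest.approx(1.0)

    def test_random_network_matches_pearson_oracle(self):
        net = random_mating_network(
            SimulationConfig(n_males=20, n_females=20, mating_density=0.5, seed=11)
        )
        m = net.incidence.sum(axis=1)
        sci = sperm_competition_intensity(net).sci
        assert scic(net, form="correlation").value == pytest.approx(
            pearson_oracle(m, sci), abs=1e-12
        )

    def test_too_few_males_rejected(self):
        with pytest.raises(ValueError, match="2 mated males"):
            scic(from_incidence([[1, 1]]))

    def test_bad_form(self, two_by_two):
        with pytest.raises(ValueError, match="form"):
            scic(two_by_two, form="spearman")


class TestMetricReport:
    def test_monogamy(self):
        rep = metric_report(from_incidence(np.eye(4, dtype=int)))
        assert rep.nodf.value == 0.0
        for mv in (rep.r_newman_u, rep.r_newman_d, rep.scic_corr, rep.scic_slope):
            assert not mv.is_defined

    def test_polygyny_fixture(self):
        # one successful male, monandrous females: no female degree variance
        rep = metric_report(from_incidence([[1, 1, 1, 0], [0, 0, 0, 1]]))
        assert rep.nodf.value == 0.0
        assert rep.r_newman_d.reason == UNDEF_NO_EDGE_END_VAR
        assert rep.scic_corr.reason == UNDEF_NO_FEMALE_VAR
        assert rep.scic_slope.value == pytest.approx(0.0)

    def test_disassortative_fixture_signs(self, staircase):
        rep = metric_report(staircase)
        assert rep.r_newman_u.value < 0
        assert rep.r_newman_d.value < 0
        assert rep.scic_corr.value < 0
        assert rep.nodf.value >= 0

    def test_empty_network(self):
        rep = metric_report(from_incidence([[0, 0], [0, 0]]))
        assert rep.nodf.value == 0.0
        assert rep.r_newman_d.reason == UNDEF_EMPTY
        assert rep.density == 0.0

    def test_degree_zero_individuals_excluded(self, staircase):
        # adding an unmated male and female must not change any metric
        padded = np.zeros((4, 4), dtype=int)
        padded[:3, :3] = staircase.incidence
        rep_a = metric_report(staircase)
        rep_b = metric_report(from_incidence(padded))
        assert rep_b.nodf.value == rep_a.nodf.value
        assert rep_b.r_newman_d.value == pytest.approx(rep_a.r_newman_d.value)
        assert rep_b.scic_corr.value == pytest.approx(rep_a.scic_corr.value)

    def test_to_dict_na_strings(self):
        d = metric_report(from_incidence(np.eye(3, dtype=int))).to_dict()
        assert d["scic_corr"] == "NA:no-male-degree-variance"
        assert d["nodf"] == 0.0
        assert d["density"] == pytest.approx(1 / 3)
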