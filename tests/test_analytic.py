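import math
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from pcronet import (
    AnalyticModel,
    CountDistribution,
    ERRNParams,
    PCROConfig,
    adin_count_dist,
    cl_count_dist,
    edge_count_pmf,
    enumerate_exact,
    equivalent_connection_prob,
    mean_cl_curve,
    nin_count_dist,
    nspccp_count_dist,
    nspccp_prob_given_L,
    pdin_count_dist,
    pdin_node_prob,
    simulate_counts,
)
from pcronet.analytic import nin_node_prob


@pytest.fixture(scope="module")
def model():
    return AnalyticModel(n_nodes=100, connection_prob=0.05, p_pcro=0.5)


class TestCountDistribution:
    def test_rejects_unnormalized_pmf(self):
        with pytest.raises(ValueError, match="sums to"):
            CountDistribution(np.array([0, 1]), np.array([0.5, 0.4]))

    def test_convolution_of_deltas(self):
        d = CountDistribution.delta(1).convolve(CountDistribution.delta(2)).convolve(
            CountDistribution.delta(3)
        )
        assert d.prob(6) == pytest.approx(1.0)

    def test_mean_variance_of_binomial(self):
        d = CountDistribution.binomial(50, 0.3)
        assert d.mean() == pytest.approx(15.0)
        assert d.var() == pytest.approx(50 * 0.3 * 0.7)

    def test_truncate_keeps_central_mass(self):
        d = CountDistribution.binomial(1000, 0.5)
        t = d.truncate(1e-10)
        assert t.support.size < d.support.size
        assert t.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert t.mean() == pytest.approx(d.mean(), abs=1e-6)


class TestEdgeCountLaw:
    def test_two_node_network(self):
        d = edge_count_pmf(AnalyticModel(2, 0.3))
        assert d.prob(1) == pytest.approx(0.3) and d.prob(0) == pytest.approx(0.7)

    def test_mean_is_expected_edge_count(self, model):
        assert edge_count_pmf(model).mean() == pytest.approx(247.5, rel=1e-9)

    def test_zero_probability_point_mass(self):
        d = edge_count_pmf(AnalyticModel(10, 0.0))
        assert d.prob(0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "L,N,expected", [(0, 100, 0.0), (4950, 100, 1.0), (247, 100, 247 / 4950)]
    )
    def test_equivalent_connection_prob(self, L, N, expected):
        assert equivalent_connection_prob(L, N) == pytest.approx(expected)

    def test_equivalent_connection_prob_range_check(self):
        with pytest.raises(ValueError):
            equivalent_connection_prob(5000, 100)


class TestCandidateLaw:
    def test_empty_network_has_no_candidates(self, model):
        assert nspccp_prob_given_L(model, 0) == 0.0

    def test_full_band_has_probability_one(self):
        m = AnalyticModel(100, 0.05, k1=0.0, k2=99.0)
        assert nspccp_prob_given_L(m, 247) == pytest.approx(1.0)

    def test_band_sum_matches_direct_binomial_terms(self, model):
        # independent evaluation with exact combinatorics
        L, N = 247, 100
        pecp = 247 / 4950
        expected = sum(
            math.comb(N - 1, k) * pecp**k * (1 - pecp) ** (N - 1 - k)
            for k in range(1, 5)  # band [1, 2*247/100] -> integers 1..4
        )
        assert nspccp_prob_given_L(model, L) == pytest.approx(expected, rel=1e-12)

    def test_count_dist_normalizes_and_matches_monte_carlo_mean(self, model):
        d = nspccp_count_dist(model)
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        rep = simulate_counts(ERRNParams(100, 0.05), PCROConfig(p_pcro=0.5), 20_000, seed=3)
        assert d.mean() == pytest.approx(rep.mean("nspccp"), rel=0.02)

    def test_point_mass_at_zero_without_edges(self):
        d = nspccp_count_dist(AnalyticModel(50, 0.0))
        assert d.prob(0) == pytest.approx(1.0)


class TestAdinLaw:
    def test_no_operation_no_adins(self, model):
        d = adin_count_dist(replace(model, p_pcro=0.0))
        assert d.prob(0) == pytest.approx(1.0)

    def test_certain_operation_recovers_candidate_law(self, model):
        m = replace(model, p_pcro=1.0)
        tv = adin_count_dist(m).total_variation(nspccp_count_dist(m))
        assert tv < 1e-12

    def test_thinning_mean_identity_across_grid(self, model):
        nspccp_mean = nspccp_count_dist(model).mean()
        for p in np.linspace(0, 1, 11):
            m = replace(model, p_pcro=float(p))
            assert adin_count_dist(m).mean() == pytest.approx(p * nspccp_mean, abs=1e-9)


def pdin_prob_literal_oracle(N, p_er, p_pcro, pki_form="plain", tail=1e-16):
    """Unoptimized literal summation: mixture over the edge count, an
    explicit (collapsing) average over the candidate count, and the sum over
    the focal node's degree.  Independent of the implementation."""
    n_pairs = N * (N - 1) // 2
    pL_all = stats.binom.pmf(np.arange(n_pairs + 1), n_pairs, p_er)
    ks = np.arange(N)
    total = 0.0
    for L in range(n_pairs + 1):
        if pL_all[L] < tail:
            continue
        pecp = 2 * L / (N * (N - 1))
        k1, k2 = 1.0, 2 * L / N
        # pmf tables for this L (lookups only; the sums below stay literal)
        pmf_nm1 = stats.binom.pmf(ks, N - 1, pecp)
        pmf_nm2 = stats.binom.pmf(ks, N - 2, pecp)
        band = 0.0
        for kj in range(1, N):
            if k1 <= kj <= k2:
                band += pmf_nm2[kj - 1]
        q = sum(pmf_nm1[k] for k in range(N) if k1 <= k <= k2)
        pmf_cand = stats.binom.pmf(np.arange(N + 1), N, q)
        inner = 0.0
        for n_cand in range(N + 1):
            s = 0.0
            for ki in range(1, N):
                pcp1 = (1.0 - p_pcro) if k1 <= ki <= k2 else 1.0
                pcp2 = band**ki
                pcp3 = p_pcro**ki
                pki = pmf_nm1[ki] if pki_form == "plain" else pmf_nm2[ki - 1]
                s += pcp1 * pcp2 * pcp3 * pki
            inner += pmf_cand[n_cand] * s
        total += pL_all[L] * inner
    return total


class TestPdinLaw:
    def test_zero_operation_probability_gives_zero(self, model):
        assert pdin_node_prob(replace(model, p_pcro=0.0)) == 0.0

    def test_full_band_certain_operation_gives_zero(self):
        # with k1=0, k2=N-1 every degree is in the cut band, so the survival
        # factor 1-p kills every term at p=1
        m = AnalyticModel(100, 0.05, k1=0.0, k2=99.0, p_pcro=1.0)
        assert pdin_node_prob(m) == 0.0

    @pytest.mark.parametrize("form", ["plain", "edge_biased"])
    def test_matches_literal_summation_oracle(self, form):
        """The optimized mixture agrees with the unoptimized literal triple
        summation (including the explicit candidate-count average) to ten
        significant digits at N=30."""
        m = AnalyticModel(30, 0.12, p_pcro=0.5, pki_form=form, truncation_tol=1e-12)
        oracle = pdin_prob_literal_oracle(30, 0.12, 0.5, pki_form=form)
        assert pdin_node_prob(m) == pytest.approx(oracle, rel=5e-10)

    def test_matches_oracle_at_default_size(self, model):
        oracle = pdin_prob_literal_oracle(100, 0.05, 0.5, pki_form="plain")
        assert pdin_node_prob(replace(model, truncation_tol=1e-12)) == pytest.approx(
            oracle, rel=5e-10
        )

    def test_count_dist_is_binomial(self, model):
        p = pdin_node_prob(model)
        d = pdin_count_dist(model, p)
        assert d.mean() == pytest.approx(100 * p)
        assert d.var() == pytest.approx(100 * p * (1 - p))

    def test_invalid_node_probability_rejected(self, model):
        with pytest.raises(ValueError):
            pdin_count_dist(model, 1.5)


class TestNinLaw:
    def test_closed_form_value_at_defaults(self, model):
        assert nin_node_prob(model) == pytest.approx(0.95**99, rel=1e-14)
        assert nin_count_dist(model).mean() == pytest.approx(100 * 0.95**99, rel=1e-12)

    def test_extreme_connection_probabilities(self):
        assert nin_count_dist(AnalyticModel(10, 0.0)).prob(10) == pytest.approx(1.0)
        assert nin_count_dist(AnalyticModel(10, 1.0)).prob(0) == pytest.approx(1.0)

    def test_node_probability_matches_exact_enumeration(self):
        """The per-node isolation probability is exact: it equals the mean
        isolation fraction of the exhaustively enumerated joint law."""
        n, p_er = 4, Fraction(3, 10)
        joint = enumerate_exact(n, p_er, PCROConfig(p_pcro=0.0), exact=True)
        mean_nin = sum(k[0] * w for k, w in joint.items())
        exact = mean_nin / n
        ours = nin_node_prob(AnalyticModel(n, float(p_er)))
        assert abs(ours - float(exact)) <= 1e-12


class TestClLaw:
    def test_all_components_at_zero(self):
        m = AnalyticModel(50, 0.9, p_pcro=0.0)  # dense: no NINs, no ADINs, no PDINs
        d = cl_count_dist(m)
        assert d.prob(0) == pytest.approx(1.0, abs=1e-6)

    def test_mean_additivity(self, model):
        nin = nin_count_dist(model)
        adin = adin_count_dist(model)
        pdin = pdin_count_dist(model)
        cl = cl_count_dist(model, (nin, adin, pdin))
        assert cl.mean() == pytest.approx(nin.mean() + adin.mean() + pdin.mean(), abs=1e-9)

    def test_normalization(self, model):
        assert cl_count_dist(model).pmf.sum() == pytest.approx(1.0, abs=1e-9)


class TestMeanClCurve:
    def test_no_operation_leaves_only_natural_isolates(self, model):
        curve = mean_cl_curve(model, [0.0])
        assert curve[0][1] == pytest.approx(nin_count_dist(model).mean(), abs=1e-9)

    def test_non_decreasing_on_grid(self, model):
        values = [v for _, v in mean_cl_curve(model, np.linspace(0, 1, 11))]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_lower_bound_at_full_operation(self, model):
        full = mean_cl_curve(model, [1.0])[0][1]
        floor = nspccp_count_dist(model).mean() + nin_count_dist(model).mean()
        assert full >= floor - 1e-9


class TestTruncationInsensitivity:
    @pytest.mark.parametrize("dist_fn", [nspccp_count_dist, adin_count_dist, cl_count_dist])
    def test_results_stable_across_tolerances(self, model, dist_fn):
        ref = dist_fn(replace(model, truncation_tol=1e-12))
        for tol in (1e-8, 1e-10):
            assert dist_fn(replace(model, truncation_tol=tol)).total_variation(ref) <= 1e-6
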