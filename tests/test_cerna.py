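"""Shared-miRNA test, Fisher-z edge weights, and network assembly."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from crdcnet import (build_network, classify_dysregulation, edge_weight,
                     fisher_z, identify_cerna_pairs, node_weight,
                     shared_mirna_test)
from crdcnet.matrix import ExpressionMatrix


def hypergeom_enumeration(N, M, K, r):
    """Exhaustive oracle: fraction of M-subsets of an N-universe sharing
    >= r elements with a fixed K-subset."""
    universe = range(N)
    fixed = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, M):
        total += 1
        hits += len(fixed & set(draw)) >= r
    return hits / total if total else 1.0


class TestSharedMirnaTest:
    def test_full_overlap_three_of_ten(self):
        bg = [f"m{i}" for i in range(10)]
        r, M, K, N, p = shared_mirna_test(bg[:3], bg[:3], bg)
        assert (r, M, K, N) == (3, 3, 3, 10)
        assert p == pytest.approx(1 / 120, rel=1e-12)

    def test_no_overlap_gives_p_one(self):
        bg = [f"m{i}" for i in range(8)]
        *_, p = shared_mirna_test(bg[:3], bg[3:6], bg)
        assert p == 1.0

    def test_two_of_three_in_six(self):
        bg = [f"m{i}" for i in range(6)]
        *_, p = shared_mirna_test(bg[:3], bg[1:4], bg)
        assert p == pytest.approx(0.5, rel=1e-12)

    def test_target_sets_must_be_in_background(self):
        with pytest.raises(ValueError):
            shared_mirna_test(["x"], ["m0"], ["m0", "m1"])

    def test_matches_enumeration_for_all_small_cases(self):
        """Exhaustive-oracle equivalence for every (N<=9, M, K, r)."""
        bg_all = [f"m{i}" for i in range(9)]
        worst = 0.0
        for N in range(1, 10):
            bg = bg_all[:N]
            for K in range(0, N + 1):
                for M in range(0, N + 1):
                    set_k = bg[:K]
                    set_m = bg[:M]  # maximal overlap; r = min(M, K)
                    r, *_ , p = shared_mirna_test(set_m, set_k, bg)
                    worst = max(worst, abs(p - hypergeom_enumeration(N, M, K, r)))
        assert worst < 1e-12


class TestEdgeWeight:
    def test_fisher_transform_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), rel=1e-12)

    def test_reference_point_against_high_precision_oracle(self):
        # r_high=0.5, r_low=0, n=103/103, sqrt(n-3) variant; expected values
        # computed independently with 20-digit sympy arithmetic
        e, p_two, z = edge_weight(0.5, 0.0, 103, 103)
        assert z == pytest.approx(3.8841809960604661, rel=1e-12)
        assert p_two == pytest.approx(1.0267540182064660e-4, rel=1e-10)
        assert e == pytest.approx(3.7123413205030086, rel=1e-10)

    def test_equal_correlations_hit_the_clamp_floor(self):
        e, p_two, _ = edge_weight(0.3, 0.3, 100, 100)
        assert p_two == pytest.approx(1.0, abs=1e-12)
        assert e == stats.norm.ppf(1e-16)

    def test_symmetric_under_stratum_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            r1, r2 = rng.uniform(-0.9, 0.9, 2)
            a = edge_weight(r1, r2, 120, 80)[0]
            b = edge_weight(r2, r1, 80, 120)[0]
            assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_in_fisher_distance(self):
        es = [edge_weight(r, 0.0, 200, 200)[0] for r in (0.1, 0.3, 0.5, 0.7)]
        assert es == sorted(es)

    def test_printed_variant_matches_formula_as_published(self):
        r_hi, r_lo, n = 0.5, 0.1, 100
        _, _, z = edge_weight(r_hi, r_lo, n, n, variant="printed")
        expected = abs(fisher_z(r_hi) - fisher_z(r_lo)) / (2.0 / (n + 3))
        assert z == pytest.approx(expected, rel=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(1.0, 0.0, 100, 100)

    def test_null_p_is_uniform(self):
        """Equal true correlation in both strata -> two-sided p ~ U(0,1)."""
        rng = np.random.default_rng(23)
        n, rho = 300, 0.3
        cov = [[1, rho], [rho, 1]]
        pvals = []
        for _ in range(1000):
            xh = rng.multivariate_normal([0, 0], cov, n)
            xl = rng.multivariate_normal([0, 0], cov, n)
            r_hi = np.corrcoef(xh.T)[0, 1]
            r_lo = np.corrcoef(xl.T)[0, 1]
            pvals.append(edge_weight(r_hi, r_lo, n, n)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestNodeWeight:
    def test_median_p_gives_zero(self):
        assert node_weight(0.5) == 0.0

    def test_standard_quantiles(self):
        assert node_weight(0.05) == pytest.approx(1.6448536269514722, rel=1e-10)
        assert node_weight(0.95) == pytest.approx(-1.6448536269514722, rel=1e-10)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            node_weight(0.0)

    def test_tiny_p_is_clamped_finite(self):
        assert np.isfinite(node_weight(1e-300))


class TestClassifyDysregulation:
    @pytest.mark.parametrize(
        "r_high,r_low,expected",
        [(0.224, 0.071, "gain"), (0.090, 0.262, "loss"), (0.3, 0.3, "undefined")],
    )
    def test_typing_rule(self, r_high, r_low, expected):
        assert classify_dysregulation(r_high, r_low) == expected


def _stratum_matrix(cohort, label):
    truth = cohort.truth
    samples = [s for s, lab in truth.stratum_labels.items() if lab == label]
    log2 = np.log2(cohort.expression.values[samples] + 1.0)
    return ExpressionMatrix(log2, "log2TPM", cohort.expression.gene_meta)


@pytest.fixture(scope="module")
def identified(small_cohort):
    mrnas = [g for g in small_cohort.expression.genes if g.startswith("G")]
    lncs = [g for g in small_cohort.expression.genes if g.startswith("LNC")]
    pairs = {
        lab: identify_cerna_pairs(_stratum_matrix(small_cohort, lab),
                                  small_cohort.interactions, mrnas, lncs)
        for lab in ("CIN-High", "CIN-Low")
    }
    return pairs


class TestIdentifyCernaPairs:
    def test_planted_gain_pairs_found_in_high_stratum(self, small_cohort, identified):
        found = set(zip(identified["CIN-High"]["mrna"], identified["CIN-High"]["lncrna"]))
        gain = [(m, l) for m, l, t in small_cohort.truth.planted_pairs if t == "gain"]
        assert len(set(gain) & found) >= 0.8 * len(gain)

    def test_planted_loss_pairs_found_in_low_stratum(self, small_cohort, identified):
        found = set(zip(identified["CIN-Low"]["mrna"], identified["CIN-Low"]["lncrna"]))
        loss = [(m, l) for m, l, t in small_cohort.truth.planted_pairs if t == "loss"]
        assert len(set(loss) & found) >= 0.8 * len(loss)

    def test_qualifying_pairs_satisfy_all_three_conditions(self, identified):
        for tbl in identified.values():
            assert (tbl["hyper_fdr"] < 0.05).all()
            assert (tbl["pcc"] > 0.1).all()
            assert (tbl["pcc_fdr"] < 0.05).all()

    def test_empty_deg_universe_is_error(self, small_cohort):
        with pytest.raises(ValueError):
            identify_cerna_pairs(_stratum_matrix(small_cohort, "CIN-High"),
                                 small_cohort.interactions, [], [])


class TestBuildNetwork:
    @pytest.fixture(scope="class")
    def network(self, small_cohort, identified):
        log2 = ExpressionMatrix(
            np.log2(small_cohort.expression.values + 1.0), "log2TPM",
            small_cohort.expression.gene_meta, small_cohort.expression.sample_meta)
        return build_network(identified["CIN-High"], identified["CIN-Low"],
                             small_cohort.survival, log2)

    def test_bipartite_and_simple(self, network):
        for u, v in network.edges:
            assert {network.nodes[u]["biotype"], network.nodes[v]["biotype"]} == \
                {"mRNA", "lncRNA"}
        assert not any(u == v for u, v in network.edges)

    def test_single_stratum_pair_gets_zero_pcc_and_type(self, network, identified):
        hi = set(zip(identified["CIN-High"]["mrna"], identified["CIN-High"]["lncrna"]))
        lo = set(zip(identified["CIN-Low"]["mrna"], identified["CIN-Low"]["lncrna"]))
        only_low = lo - hi
        assert only_low, "fixture should contain loss-only pairs"
        for m, l in only_low:
            d = network.edges[m, l]
            assert d["pcc_high"] == 0.0
            assert d["dysreg_type"] == "loss"

    def test_union_has_no_duplicate_edges(self, network, identified):
        hi = set(zip(identified["CIN-High"]["mrna"], identified["CIN-High"]["lncrna"]))
        lo = set(zip(identified["CIN-Low"]["mrna"], identified["CIN-Low"]["lncrna"]))
        assert network.number_of_edges() == len(hi | lo)

    def test_planted_dysregulation_types_recovered(self, small_cohort, network):
        truth_type = {(m, l): t for m, l, t in small_cohort.truth.planted_pairs}
        hits = total = 0
        for (m, l), t in truth_type.items():
            if network.has_edge(m, l):
                total += 1
                hits += network.edges[m, l]["dysreg_type"] == t
        assert total >= 0.8 * len(truth_type)
        assert hits / total >= 0.95

    def test_node_weights_are_cox_quantiles(self, network):
        for _, d in network.nodes(data=True):
            assert d["weight"] == pytest.approx(node_weight(d["cox_p"]), abs=1e-12)

    def test_empty_union_is_error(self, small_cohort):
        from crdcnet.cerna import _empty_pairs

        log2 = ExpressionMatrix(
            np.log2(small_cohort.expression.values + 1.0), "log2TPM")
        with pytest.raises(ValueError):
            build_network(_empty_pairs(), _empty_pairs(),
                          small_cohort.survival, log2)
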