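"""Seeded simulators: Yule trees, DEC/Mk histories, conjugate traces, fixture."""

import numpy as np
import pytest

import crabrange as cr
from crabrange.dec_core import DEFAULT_AREAS, build_q, enumerate_ranges
from crabrange.synthetic_data import (
    FIXTURE_N_TIPS,
    FIXTURE_ROOT_AGE,
    FIXTURE_SEED,
    NormalNormalSpec,
    study_fixture,
)


class TestSimulateYule:
    def test_cherry(self):
        t = cr.simulate_yule(2, seed=0)
        assert t.n_tips == 2
        assert t.root_age > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_binary_tree_node_count(self, seed):
        t = cr.simulate_yule(57, seed=seed)
        internals = sum(1 for v in range(t.n_nodes) if not t.is_tip(v))
        assert internals == 56
        assert t.is_ultrametric()

    def test_rescaling_to_target(self):
        t = cr.simulate_yule(30, seed=1, root_age=47.23)
        assert t.root_age == pytest.approx(47.23, abs=1e-9)

    def test_seeded_determinism(self):
        a = cr.write_newick(cr.simulate_yule(20, seed=9))
        b = cr.write_newick(cr.simulate_yule(20, seed=9))
        assert a == b

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cr.simulate_yule(1, seed=0)
        with pytest.raises(ValueError):
            cr.simulate_yule(5, birth_rate=0.0, seed=0)


class TestSimulateDecTips:
    def test_no_rates_no_change(self):
        t = cr.simulate_yule(12, seed=2)
        p = cr.DECParams(0.0, 0.0, cr.build_dispersal_matrix("H0"))
        rec = cr.simulate_dec_tips(t, p, "A", seed=3)
        assert all(v == frozenset("A") for v in rec.tip_areas.values())

    def test_no_extinction_ranges_never_shrink(self):
        t = cr.simulate_yule(20, seed=4, root_age=20.0)
        p = cr.DECParams(0.05, 0.0, cr.build_dispersal_matrix("H0"))
        rec = cr.simulate_dec_tips(t, p, "A", seed=5)
        for v, start in rec.branch_start.items():
            end = rec.node_truth[v]
            assert set(start) <= set(end)  # only gains along branches

    def test_seeded_determinism(self):
        t = cr.simulate_yule(15, seed=6, root_age=30.0)
        p = cr.DECParams(0.01, 0.001, cr.build_dispersal_matrix("HIA"))
        r1 = cr.simulate_dec_tips(t, p, "A", seed=7)
        r2 = cr.simulate_dec_tips(t, p, "A", seed=7)
        assert r1.tip_areas == r2.tip_areas
        assert r1.node_truth == r2.node_truth

    def test_disallowed_root_rejected(self):
        t = cr.simulate_yule(5, seed=8)
        p = cr.DECParams(0.01, 0.0, cr.build_dispersal_matrix("H0"))
        with pytest.raises(ValueError):
            cr.simulate_dec_tips(t, p, "AC", seed=9)  # disconnected under adjacency

    def test_single_branch_frequencies_match_transition_probs(self):
        # empirical end-state distribution over many short branches vs the
        # matrix exponential, within 3 binomial SEs
        t = cr.parse_newick("(a:0.8,b:0.8);")
        p = cr.DECParams(0.25, 0.1, cr.build_dispersal_matrix("H0"))
        ranges = enumerate_ranges(DEFAULT_AREAS)
        idx = {m: i for i, m in enumerate(ranges)}
        Q = build_q(ranges, p, DEFAULT_AREAS)
        # condition the analytic law on survival to match the simulator
        P = cr.branch_probs(Q, 0.8)
        start = DEFAULT_AREAS.mask("AB")
        row = P[idx[start]].copy()
        row[idx[0]] = 0.0
        row /= row.sum()
        n = 4000
        counts = np.zeros(len(ranges))
        from crabrange.synthetic_data import _gillespie_branch

        rng = np.random.default_rng(10)
        for _ in range(n):
            end = _gillespie_branch(Q, idx[start], 0.8, idx[0], rng, 1000)
            counts[end] += 1
        freq = counts / n
        se = np.sqrt(row * (1 - row) / n)
        assert np.all(np.abs(freq - row) <= 3 * np.maximum(se, 1e-4))


class TestSimulateMkTips:
    def test_zero_rates(self):
        t = cr.simulate_yule(10, seed=11)
        rec = cr.simulate_mk_tips(t, np.zeros((4, 4)), "C", seed=12)
        assert all(v == frozenset("C") for v in rec.tip_areas.values())

    def test_two_state_flip_probability(self):
        # symmetric 2-state chain: P(end != start) = (1 - exp(-2qt)) / 2
        q, t_len, n = 0.3, 1.5, 4000
        tree = cr.parse_newick(f"(a:{t_len},b:{t_len});")
        rates = np.array([[0.0, q], [q, 0.0]])
        flips = 0
        for i in range(n):
            rec = cr.simulate_mk_tips(tree, rates, "A", seed=i, states=("A", "B"))
            flips += rec.tip_areas["a"] == frozenset("B")
        p_expect = (1 - np.exp(-2 * q * t_len)) / 2
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(flips / n - p_expect) <= 3 * se

    def test_seeded_determinism(self):
        t = cr.simulate_yule(8, seed=13)
        r1 = cr.simulate_mk_tips(t, np.full((4, 4), 0.1), "A", seed=14)
        r2 = cr.simulate_mk_tips(t, np.full((4, 4), 0.1), "A", seed=14)
        assert r1.tip_areas == r2.tip_areas


class TestSimulateTrace:
    def test_no_data_lnml_is_zero(self):
        spec = NormalNormalSpec(prior_mean=0.0, prior_sd=0.3, like_sd=1.0, data=())
        trace, lnml = cr.simulate_trace(100, spec, seed=1)
        assert lnml == 0.0
        assert np.allclose(trace.lnl, 0.0)

    def test_true_lnml_matches_direct_integration(self):
        spec = NormalNormalSpec(prior_mean=0.2, prior_sd=0.3, like_sd=1.0, data=(0.1, -0.4, 0.9))
        # numeric quadrature over the latent mean as an independent check
        from scipy import integrate, stats

        def integrand(mu):
            like = np.prod(stats.norm.pdf(np.array(spec.data), mu, spec.like_sd))
            return like * stats.norm.pdf(mu, spec.prior_mean, spec.prior_sd)

        val, _ = integrate.quad(integrand, -5, 5, limit=200)
        assert spec.true_lnml() == pytest.approx(np.log(val), abs=1e-8)

    def test_known_lnml_gap_recovered_by_bf_matrix(self):
        s1 = NormalNormalSpec.with_simulated_data(seed=20)
        s2 = NormalNormalSpec.with_simulated_data(seed=21)
        t1, m1 = cr.simulate_trace(4000, s1, seed=22)
        t2, m2 = cr.simulate_trace(4000, s2, seed=23)
        ml1 = cr.harmonic_mean_lnml(t1)
        ml2 = cr.harmonic_mean_lnml(t2)
        mat = cr.bf_matrix([("m1", ml1), ("m2", ml2)])
        truth = (m1 - m2) / np.log(10)
        se = np.hypot(ml1.se, ml2.se) / np.log(10)
        assert abs(mat.matrix[0, 1] - truth) <= 3 * max(se, 0.02)

    def test_seeded_determinism(self):
        spec = NormalNormalSpec.with_simulated_data(seed=30)
        a, _ = cr.simulate_trace(50, spec, seed=31)
        b, _ = cr.simulate_trace(50, spec, seed=31)
        assert np.array_equal(a.lnl, b.lnl)


class TestStudyFixture:
    def test_dimensions(self):
        rec = study_fixture()
        assert rec.tree.n_tips == FIXTURE_N_TIPS == 57
        assert rec.tree.root_age == pytest.approx(FIXTURE_ROOT_AGE, abs=1e-9)
        assert set().union(*rec.tip_areas.values()) <= set("ABCD")

    def test_regeneration_matches_shipped_files(self):
        tree, tips, truth = cr.load_study_fixture()
        rec = study_fixture(FIXTURE_SEED)
        assert cr.write_newick(tree) == cr.write_newick(rec.tree)
        assert tips == rec.tip_areas
        assert truth["seed"] == FIXTURE_SEED

    def test_generating_hypothesis_fits_better_than_reverse(self):
        tree, tips, _ = cr.load_study_fixture()
        fit_ia = cr.fit_dec(tree, tips, "HIA")
        fit_ai = cr.fit_dec(tree, tips, "HAI")
        assert fit_ia.lnl > fit_ai.lnl
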