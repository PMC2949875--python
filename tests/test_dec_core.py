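"""DEC state space, rate matrix, cladogenesis and likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crabrange as cr
from crabrange.dec_core import DEFAULT_AREAS, _Propagator
from crabrange.phylo_io import PhyloError
from oracles import dec_brute_force

FULL3 = cr.AreaSet.full(("A", "B", "C"))


class TestEnumerateRanges:
    def test_full_adjacency_counts(self):
        assert len(cr.enumerate_ranges(cr.AreaSet.full())) == 15 + 1  # + null

    def test_default_adjacency_excludes_disconnected(self):
        ranges = cr.enumerate_ranges(DEFAULT_AREAS)
        labels = {DEFAULT_AREAS.label(m) for m in ranges}
        assert len(ranges) == 12 + 1
        assert {"AC", "AD", "ACD"}.isdisjoint(labels)

    def test_connectivity_matches_exhaustive_check(self):
        # independent connectivity via edge-walk over explicit pairs
        edges = {("A", "B"), ("B", "C"), ("B", "D"), ("C", "D")}

        def connected(subset):
            subset = list(subset)
            seen = {subset[0]}
            while True:
                grow = {
                    b
                    for a in seen
                    for b in subset
                    if (a, b) in edges or (b, a) in edges
                }
                if grow <= seen:
                    break
                seen |= grow
            return len(seen) == len(subset)

        import itertools

        expect = set()
        for r in range(1, 5):
            for combo in itertools.combinations("ABCD", r):
                if connected(combo):
                    expect.add(frozenset(combo))
        got = {DEFAULT_AREAS.decode(m) for m in cr.enumerate_ranges(DEFAULT_AREAS) if m}
        assert got == expect

    def test_single_area(self):
        aset = cr.AreaSet.full(("A",))
        assert cr.enumerate_ranges(aset) == [1, 0]

    def test_max_size_cap(self):
        ranges = cr.enumerate_ranges(DEFAULT_AREAS, max_size=1)
        assert len(ranges) == 4 + 1


class TestDispersalMatrix:
    def test_h0_all_open(self):
        D = cr.build_dispersal_matrix("H0")
        assert D.sum() == 12  # all off-diagonal entries 1

    def test_hia_blocks_into_india(self):
        D = cr.build_dispersal_matrix("HIA")
        i = DEFAULT_AREAS.index("A")
        assert np.all(D[:, i] == 0)
        assert D[i, DEFAULT_AREAS.index("B")] == 1

    def test_hai_blocks_out_of_india(self):
        D = cr.build_dispersal_matrix("HAI")
        i = DEFAULT_AREAS.index("A")
        assert np.all(D[i, :] == 0)
        assert D[DEFAULT_AREAS.index("B"), i] == 1

    def test_unknown_hypothesis(self):
        with pytest.raises(ValueError, match="hypothesis"):
            cr.build_dispersal_matrix("H9")


class TestBuildQ:
    def test_two_area_rates(self):
        aset = cr.AreaSet.full(("A", "B"))
        ranges = cr.enumerate_ranges(aset)
        idx = {m: i for i, m in enumerate(ranges)}
        p = cr.DECParams(0.1, 0.05, cr.build_dispersal_matrix("H0", aset))
        Q = cr.build_q(ranges, p, aset)
        A, B, AB, null = aset.mask("A"), aset.mask("B"), aset.mask("AB"), 0
        assert Q[idx[A], idx[AB]] == pytest.approx(0.1)
        assert Q[idx[AB], idx[A]] == pytest.approx(0.05)
        assert Q[idx[A], idx[null]] == pytest.approx(0.05)

    def test_zero_dispersal_kills_gains(self):
        ranges = cr.enumerate_ranges(DEFAULT_AREAS)
        p = cr.DECParams(0.0, 0.02, cr.build_dispersal_matrix("H0"))
        Q = cr.build_q(ranges, p, DEFAULT_AREAS)
        idx = {m: i for i, m in enumerate(ranges)}
        for m in ranges:
            if not m:
                continue
            for m2 in ranges:
                if m2 and (m2 & ~m) and m != m2:
                    assert Q[idx[m], idx[m2]] == 0.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(d=st.floats(0, 5), e=st.floats(0, 5))
    def test_rows_sum_to_zero(self, d, e):
        ranges = cr.enumerate_ranges(DEFAULT_AREAS)
        p = cr.DECParams(d, e, cr.build_dispersal_matrix("HIA"))
        Q = cr.build_q(ranges, p, DEFAULT_AREAS)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestBranchProbs:
    def _q(self):
        ranges = cr.enumerate_ranges(FULL3)
        p = cr.DECParams(0.3, 0.1, cr.build_dispersal_matrix("H0", FULL3))
        return cr.build_q(ranges, p, FULL3)

    def test_identity_at_zero(self):
        Q = self._q()
        assert np.allclose(cr.branch_probs(Q, 0.0), np.eye(Q.shape[0]))

    def test_chapman_kolmogorov(self):
        Q = self._q()
        P1, P2, P3 = cr.branch_probs(Q, 0.7), cr.branch_probs(Q, 1.3), cr.branch_probs(Q, 2.0)
        assert np.allclose(P1 @ P2, P3, atol=1e-8)

    def test_rows_stochastic(self):
        Q = self._q()
        P = cr.branch_probs(Q, 3.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P.min() >= 0.0

    def test_pure_extinction_closed_form(self):
        aset = cr.AreaSet.full(("A",))
        ranges = cr.enumerate_ranges(aset)
        e = 0.23
        Q = cr.build_q(ranges, cr.DECParams(0.0, e, np.zeros((1, 1))), aset)
        for t in (0.1, 1.0, 4.2):
            P = cr.branch_probs(Q, t)
            assert P[0, 0] == pytest.approx(np.exp(-e * t), abs=1e-12)

    def test_eig_fast_path_matches_expm(self):
        Q = self._q()
        prop = _Propagator(Q)
        for t in (0.05, 1.7, 9.0):
            assert np.allclose(prop(t), cr.branch_probs(Q, t), atol=1e-9)


class TestCladogenesis:
    def test_single_area_sympatry(self):
        (out,) = cr.cladogenesis_outcomes(DEFAULT_AREAS.mask("A"), DEFAULT_AREAS)
        assert out == (DEFAULT_AREAS.mask("A"), DEFAULT_AREAS.mask("A"), 1.0)

    def test_two_area_range_has_six_outcomes(self):
        outs = cr.cladogenesis_outcomes(DEFAULT_AREAS.mask("AB"), DEFAULT_AREAS)
        assert len(outs) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w in outs)
        labels = {
            (DEFAULT_AREAS.label(l), DEFAULT_AREAS.label(r)) for l, r, _ in outs
        }
        assert labels == {
            ("A", "AB"), ("AB", "A"), ("B", "AB"), ("AB", "B"), ("A", "B"), ("B", "A"),
        }

    def test_three_area_fully_connected(self):
        aset = cr.AreaSet.full(("A", "B", "C"))
        outs = cr.cladogenesis_outcomes(aset.mask("ABC"), aset)
        assert len(outs) == 12
        assert sum(w for _, _, w in outs) == pytest.approx(1.0)

    def test_disconnected_complement_dropped(self):
        # under default adjacency, ABC minus B = AC is disconnected, so the
        # vicariance pair (B, AC) must be absent
        outs = cr.cladogenesis_outcomes(DEFAULT_AREAS.mask("ABC"), DEFAULT_AREAS)
        pairs = {
            (DEFAULT_AREAS.label(l), DEFAULT_AREAS.label(r)) for l, r, _ in outs
        }
        assert ("B", "AC") not in pairs and ("AC", "B") not in pairs

    def test_null_rejected(self):
        with pytest.raises(ValueError):
            cr.cladogenesis_outcomes(0, DEFAULT_AREAS)


class TestDecLoglik:
    def test_no_events_identical_tips(self):
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("A"), "b": frozenset("A")}
        p = cr.DECParams(0.0, 0.0, cr.build_dispersal_matrix("H0"))
        assert cr.dec_loglik(t, tips, p) == pytest.approx(0.0)

    def test_no_events_split_tips_root_vicariance(self):
        # with cladogenesis at the root, {A},{B} is reachable via root {A,B}
        # vicariance at weight 1/6 even when d=e=0
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("A"), "b": frozenset("B")}
        p = cr.DECParams(0.0, 0.0, cr.build_dispersal_matrix("H0"))
        assert cr.dec_loglik(t, tips, p) == pytest.approx(np.log(1 / 6))

    def test_impossible_data_flagged_minus_inf(self):
        # fixing the root range removes the vicariance escape: no path
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("A"), "b": frozenset("B")}
        p = cr.DECParams(0.0, 0.0, cr.build_dispersal_matrix("H0"))
        lnl = cr.dec_loglik(t, tips, p, root_range=DEFAULT_AREAS.mask("A"))
        assert lnl == float("-inf")

    def test_missing_tip_rejected(self):
        t = cr.parse_newick("(a:1,b:1);")
        with pytest.raises(PhyloError):
            cr.dec_loglik(
                t, {"a": frozenset("A")}, cr.DECParams(0.1, 0.1, cr.build_dispersal_matrix("H0"))
            )

    def test_disallowed_tip_range_rejected(self):
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("AC"), "b": frozenset("B")}  # AC disconnected
        with pytest.raises(PhyloError, match="not allowed"):
            cr.dec_loglik(t, tips, cr.DECParams(0.1, 0.1, cr.build_dispersal_matrix("H0")))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        d=st.floats(0.001, 0.6),
        e=st.floats(0.0, 0.3),
        n=st.integers(2, 4),
    )
    def test_matches_brute_force(self, seed, d, e, n):
        rng = np.random.default_rng(seed)
        t = cr.simulate_yule(n, seed=seed)
        ranges = cr.enumerate_ranges(FULL3)[:-1]
        tips = {
            lab: FULL3.decode(ranges[int(rng.integers(len(ranges)))])
            for lab in t.tip_labels
        }
        p = cr.DECParams(d, e, cr.build_dispersal_matrix("H0", FULL3))
        a = cr.dec_loglik(t, tips, p, area_set=FULL3)
        b = dec_brute_force(t, tips, p, FULL3)
        if np.isinf(b):
            assert np.isinf(a)
        else:
            assert a == pytest.approx(b, abs=1e-8)

    def test_invariant_under_tip_relabeling(self):
        t = cr.simulate_yule(6, seed=42)
        rng = np.random.default_rng(0)
        ranges = cr.enumerate_ranges(DEFAULT_AREAS)[:-1]
        tips = {
            lab: DEFAULT_AREAS.decode(ranges[int(rng.integers(len(ranges)))])
            for lab in t.tip_labels
        }
        p = cr.DECParams(0.05, 0.01, cr.build_dispersal_matrix("H0"))
        base = cr.dec_loglik(t, tips, p)
        mapping = {lab: f"sp_{lab}" for lab in t.tip_labels}
        t2 = t.relabeled(mapping)
        tips2 = {mapping[k]: v for k, v in tips.items()}
        assert cr.dec_loglik(t2, tips2, p) == pytest.approx(base, abs=1e-12)


class TestFitDec:
    def test_boundary_when_no_dispersal_needed(self):
        # all tips carry the root range: d is pushed to its lower bound
        t = cr.simulate_yule(20, seed=9, root_age=10.0)
        tips = {lab: frozenset("A") for lab in t.tip_labels}
        fit = cr.fit_dec(t, tips, "H0")
        assert fit.params.d < 1e-6
        assert fit.params.e < 1e-3
        assert fit.lnl <= 0.0
        assert fit.k == 2

    def test_fit_improves_on_start_points(self):
        rec = _sim_small()
        model = cr.DECModel(rec.tree, rec.tip_areas, hypothesis="H0")
        fit = cr.fit_dec(rec.tree, rec.tip_areas, "H0")
        for d0, e0 in ((1e-2, 1e-2), (1e-3, 1e-4)):
            assert fit.lnl >= model.loglik(d0, e0) - 1e-6


def _sim_small():
    t = cr.simulate_yule(30, seed=77, root_age=47.23)
    params = cr.DECParams(8e-3, 8e-4, cr.build_dispersal_matrix("H0"))
    return cr.simulate_dec_tips(t, params, "A", seed=77)


class TestReconstructSplits:
    def test_two_tip_same_area_best_split(self):
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("A"), "b": frozenset("A")}
        fit = cr.DECFit(
            params=cr.DECParams(0.01, 0.001, cr.build_dispersal_matrix("H0")),
            lnl=0.0, k=2, model_name="H0",
        )
        splits = cr.reconstruct_splits(t, tips, fit)
        best = splits[t.root].scenarios[0]
        assert (best.ancestor, best.left, best.right) == ("A", "A", "A")
        assert best.rel_prob > 0.9

    def test_relative_probabilities_normalize(self):
        rec = _sim_small()
        fit = cr.fit_dec(rec.tree, rec.tip_areas, "H0")
        splits = cr.reconstruct_splits(rec.tree, rec.tip_areas, fit, lnl_window=1e9)
        for v, rec_v in splits.items():
            total = sum(s.rel_prob for s in rec_v.scenarios)
            assert total == pytest.approx(1.0, abs=1e-9)
            # every node's scenario likelihoods must sum to the global lnL
            liks = np.array([s.lnl for s in rec_v.scenarios])
            m = liks.max()
            assert m + np.log(np.exp(liks - m).sum()) == pytest.approx(fit.lnl, abs=1e-6)

    def test_single_scenario_gets_probability_one(self):
        t = cr.parse_newick("(a:1,b:1);")
        tips = {"a": frozenset("A"), "b": frozenset("A")}
        fit = cr.DECFit(
            params=cr.DECParams(0.0, 0.0, cr.build_dispersal_matrix("H0")),
            lnl=0.0, k=2, model_name="H0",
        )
        splits = cr.reconstruct_splits(t, tips, fit)
        assert len(splits[t.root].scenarios) == 1
        assert splits[t.root].scenarios[0].rel_prob == pytest.approx(1.0)

    def test_window_filtering(self):
        rec = _sim_small()
        fit = cr.fit_dec(rec.tree, rec.tip_areas, "H0")
        splits = cr.reconstruct_splits(rec.tree, rec.tip_areas, fit, lnl_window=2.0)
        for rec_v in splits.values():
            best = rec_v.scenarios[0].lnl
            assert all(s.lnl >= best - 2.0 - 1e-9 for s in rec_v.scenarios)
            assert rec_v.scenarios == sorted(
                rec_v.scenarios, key=lambda s: -s.lnl
            )
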