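"""Independent brute-force oracles used by the test suite.

Each oracle enumerates the full joint space (internal-node states,
cladogenetic scenario choices, event assignments) directly with itertools,
deliberately avoiding the pruning / dynamic-programming recursions it is
used to check.  Only feasible for tiny trees and few areas.
"""

from __future__ import annotations

import itertools

import numpy as np

from crabrange.dec_core import (
    AreaSet,
    DECParams,
    branch_probs,
    build_q,
    cladogenesis_outcomes,
    enumerate_ranges,
)


def dec_brute_force(tree, tip_areas, params: DECParams, area_set: AreaSet) -> float:
    """DEC log-likelihood by exhaustive enumeration of internal-node range
    assignments and per-node cladogenetic scenarios."""
    ranges = enumerate_ranges(area_set)
    idx = {m: i for i, m in enumerate(ranges)}
    nonempty = [m for m in ranges if m]
    Q = build_q(ranges, params, area_set)
    P = {v: branch_probs(Q, tree.blen[v]) for v in range(tree.n_nodes) if tree.parent[v] >= 0}

    internals = [v for v in tree.postorder() if not tree.is_tip(v)]
    tip_state = {v: idx[area_set.mask(tip_areas[tree.labels[v]])] for v in tree.tips}
    scen = {m: cladogenesis_outcomes(m, area_set) for m in nonempty}

    # joint choice per internal node: (range, scenario index)
    choices = {v: [(m, s) for m in nonempty for s in range(len(scen[m]))] for v in internals}

    total = 0.0
    for combo in itertools.product(*(choices[v] for v in internals)):
        assign = dict(zip(internals, combo))
        lik = 1.0
        for v in internals:
            m, s = assign[v]
            left, right, w = scen[m][s]
            lik *= w
            for child, start in zip(tree.children[v], (left, right)):
                end = assign[child][0] if child in assign else None
                end_idx = idx[end] if end is not None else tip_state[child]
                lik *= P[child][idx[start], end_idx]
            if lik == 0.0:
                break
        total += lik
    return np.log(total) if total > 0 else float("-inf")


def mk_brute_force(tree, tip_areas, rates, states=("A", "B", "C", "D")) -> float:
    """Mk log-likelihood by summing over all internal-node states."""
    k = len(states)
    Q = np.array(rates, dtype=float, copy=True)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = {v: branch_probs(Q, tree.blen[v]) for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = [v for v in tree.postorder() if not tree.is_tip(v)]
    tip_state = {v: states.index(next(iter(tip_areas[tree.labels[v]]))) for v in tree.tips}

    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        lik = 1.0 / k  # uniform root prior
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            end = assign[v] if v in assign else tip_state[v]
            lik *= P[v][assign[p], end]
        total += lik
    return np.log(total) if total > 0 else float("-inf")


def mk_node_conditionals_brute(tree, tip_areas, rates, node, states=("A", "B", "C", "D")):
    """Exact posterior P(node state | tips, rates) by enumeration."""
    k = len(states)
    Q = np.array(rates, dtype=float, copy=True)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = {v: branch_probs(Q, tree.blen[v]) for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = [v for v in tree.postorder() if not tree.is_tip(v)]
    tip_state = {v: states.index(next(iter(tip_areas[tree.labels[v]]))) for v in tree.tips}

    marg = np.zeros(k)
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        lik = 1.0 / k
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            end = assign[v] if v in assign else tip_state[v]
            lik *= P[v][assign[p], end]
        marg[assign[node]] += lik
    return marg / marg.sum()


def diva_brute_force(tree, tip_areas, max_areas=None, area_codes="ABC"):
    """Minimum DIVA event cost and optimal root sets by exhaustive search
    over all internal-node distributions and all cladogenetic divisions."""
    n_areas = len(area_codes)
    cap = n_areas if max_areas is None else max_areas
    states = [m for m in range(1, 1 << n_areas) if bin(m).count("1") <= cap]

    def mask_of(areas):
        m = 0
        for a in areas:
            m |= 1 << area_codes.index(a)
        return m

    def acost(a, b):
        return bin(b & ~a).count("1") + bin(a & ~b).count("1")

    def divisions(m):
        if bin(m).count("1") == 1:
            return [(m, m)]
        out = []
        for sub in range(1, m):
            if sub & m == sub and sub != m:
                out.append((sub, m & ~sub))
        return out

    internals = [v for v in tree.postorder() if not tree.is_tip(v)]
    tip_mask = {v: mask_of(tip_areas[tree.labels[v]]) for v in tree.tips}

    best = None
    root_sets = set()
    node_sets = {v: set() for v in internals}
    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        cost = 0
        for v in internals:
            mv = assign[v]
            child_masks = [
                assign[c] if c in assign else tip_mask[c] for c in tree.children[v]
            ]
            local = min(
                acost(a1, child_masks[0]) + acost(a2, child_masks[1])
                for a1, a2 in divisions(mv)
            )
            cost += local
        if best is None or cost < best:
            best = cost
            root_sets = {assign[tree.root]}
            node_sets = {v: {assign[v]} for v in internals}
        elif cost == best:
            root_sets.add(assign[tree.root])
            for v in internals:
                node_sets[v].add(assign[v])

    def label_of(m):
        return "".join(a for i, a in enumerate(area_codes) if m >> i & 1)

    order = lambda m: (bin(m).count("1"), m)
    return (
        best,
        [label_of(m) for m in sorted(root_sets, key=order)],
        {v: [label_of(m) for m in sorted(s, key=order)] for v, s in node_sets.items()},
    )
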