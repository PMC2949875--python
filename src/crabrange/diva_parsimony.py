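"""Dispersal-vicariance (DIVA) parsimony reconstruction of ancestral areas.

DIVA assigns ancestral distributions (nonempty area subsets) to internal
nodes so as to minimize the number of dispersal events (each area added
along a branch costs 1) plus extinction events (each area lost along a
branch costs 1), while vicariance and within-area duplication at nodes are
free.  At a speciation event a single-area ancestor duplicates (both
daughter lineages start with that area); a widespread ancestor divides by
vicariance into two nonempty, disjoint subsets whose union is the
ancestral distribution.  Events implied along the branch from a daughter
start-set to the daughter node's own distribution are counted by symmetric
set difference.

Unlike the original software's heuristics, the optimization here is an
exact dynamic program over all nonempty subsets at every node (15 states
for four areas), with an outside pass to report, for each node, every
distribution that participates in at least one globally optimal
reconstruction.  No adjacency restriction is applied (range adjacency is a
DEC-side device).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .phylo_io import Phylogeny, PhyloError, validate_tip_areas

__all__ = ["DivaReconstruction", "diva_reconstruct"]

INF = 10**9


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _splits(mask: int) -> list[tuple[int, int]]:
    """Cost-free cladogenetic divisions of an ancestral distribution:
    duplication for single areas, ordered disjoint bipartitions otherwise."""
    if _popcount(mask) == 1:
        return [(mask, mask)]
    bits = [1 << b for b in range(mask.bit_length()) if mask >> b & 1]
    out = []
    for r in range(1, len(bits)):
        for combo in itertools.combinations(bits, r):
            s = 0
            for b in combo:
                s |= b
            out.append((s, mask & ~s))
    return out


@dataclass
class DivaReconstruction:
    """Exact DIVA result: minimum event cost, per-node optimal ancestral
    distributions (area-code strings, deterministic order) and whether any
    node's alternative list was truncated by the cap."""

    cost: int
    node_distributions: dict[int, list[str]]
    alternatives_kept: dict[int, int]
    truncated: bool


def diva_reconstruct(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    max_areas: int | None = None,
    max_alternatives: int = 1000,
    area_codes: str = "ABCD",
) -> DivaReconstruction:
    """Exact dispersal-vicariance parsimony over all subset assignments.

    ``max_areas`` caps the size of ancestral distributions (tip data are
    taken as given even if larger); ``max_alternatives`` caps the number of
    optimal distributions reported per node, applied after optimality
    filtering in (size, bitmask) order.
    """
    validate_tip_areas(tip_areas, tree)
    n_areas = len(area_codes)
    universe = (1 << n_areas) - 1
    cap = n_areas if max_areas is None else max(1, int(max_areas))
    states = [m for m in range(1, universe + 1) if _popcount(m) <= cap]

    def mask_of(areas: frozenset[str]) -> int:
        m = 0
        for a in areas:
            if a not in area_codes:
                raise PhyloError(f"unknown area code {a!r}")
            m |= 1 << area_codes.index(a)
        return m

    def label_of(m: int) -> str:
        return "".join(a for i, a in enumerate(area_codes) if m >> i & 1)

    def acost(a: int, b: int) -> int:
        # dispersals (areas gained) + extinctions (areas lost) along a branch
        return _popcount(b & ~a) + _popcount(a & ~b)

    for lab, areas in tip_areas.items():
        if not areas:
            raise PhyloError(f"tip {lab!r} has an empty area set")

    splits = {m: _splits(m) for m in states}
    post = tree.postorder()

    # inside pass: c[v][R] = min cost of v's subtree with v's distribution R
    c: dict[int, dict[int, int]] = {}
    # bm[v][A] = min over R of c[v][R] + acost(A, R): best cost of child v
    # when its branch starts with set A
    bm: dict[int, dict[int, int]] = {}
    all_sets = states  # candidate start sets equal candidate distributions

    for v in post:
        if tree.is_tip(v):
            tip_mask = mask_of(tip_areas[tree.labels[v]])
            c[v] = {tip_mask: 0}
        else:
            l, r = tree.children[v]
            cv = {}
            for m in states:
                best = INF
                for a1, a2 in splits[m]:
                    val = bm[l].get(a1, INF) + bm[r].get(a2, INF)
                    if val < best:
                        best = val
                if best < INF:
                    cv[m] = best
            c[v] = cv
        bm[v] = {
            a: min(c[v][rr] + acost(a, rr) for rr in c[v]) for a in all_sets
        }

    root = tree.root
    total = min(c[root].values())

    # outside pass: o[v][R] = min cost outside v's subtree given v has R
    o: dict[int, dict[int, int]] = {root: {m: 0 for m in states}}
    for v in reversed(post):  # preorder
        if tree.is_tip(v):
            continue
        l, r = tree.children[v]
        # h[A] for child = min over parent's R, split with that child's part A
        hl = {a: INF for a in all_sets}
        hr = {a: INF for a in all_sets}
        for m in states:
            base = o[v].get(m, INF)
            if base >= INF:
                continue
            for a1, a2 in splits[m]:
                vl = base + bm[r].get(a2, INF)
                if vl < hl[a1]:
                    hl[a1] = vl
                vr = base + bm[l].get(a1, INF)
                if vr < hr[a2]:
                    hr[a2] = vr
        o[l] = {
            rr: min(hl[a] + acost(a, rr) for a in all_sets) for rr in c[l]
        }
        o[r] = {
            rr: min(hr[a] + acost(a, rr) for a in all_sets) for rr in c[r]
        }

    node_distributions: dict[int, list[str]] = {}
    kept: dict[int, int] = {}
    truncated = False
    for v in post:
        if tree.is_tip(v):
            continue
        opt = sorted(
            (m for m in c[v] if c[v][m] + o[v].get(m, INF) == total),
            key=lambda m: (_popcount(m), m),
        )
        if len(opt) > max_alternatives:
            opt = opt[:max_alternatives]
            truncated = True
        node_distributions[v] = [label_of(m) for m in opt]
        kept[v] = len(opt)

    return DivaReconstruction(
        cost=int(total),
        node_distributions=node_distributions,
        alternatives_kept=kept,
        truncated=truncated,
    )
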