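"""Dispersal-extinction-cladogenesis (DEC) likelihood for ancestral ranges.

The DEC model treats a species' geographic range as a nonempty subset of
discrete areas.  Along branches the range evolves by a continuous-time
Markov chain: single areas are gained at rate ``d`` (modulated by a 0/1
dispersal multiplier matrix ``D`` over source->target area pairs) and lost
at rate ``e`` (loss of the last area moves the lineage to an absorbing null
range).  At speciation the ancestral range splits into the two daughter
ranges under the classic DEC scenario set: within-area sympatry for single
areas, and for widespread ranges peripheral-isolate sympatry plus
vicariance with a singleton part, all outcomes equally weighted.

Range states are restricted to adjacency-connected subsets of the area
graph.  The default four-area coding (A = Indian Subcontinent,
B = Southeast Asia, C = Philippines, D = east of the Wallace Line) uses the
adjacency A-B, B-C, B-D, C-D, i.e. India touches only Southeast Asia while
the Philippine and Wallacean ranges are mutually reachable; this realizes
the restriction that India is not adjacent to the Philippines or to the
area east of the Wallace Line.

Three directional dispersal hypotheses are supported:

* ``H0``  -- unconstrained dispersal (all multipliers 1);
* ``HIA`` -- dispersal only out of India (all gains *into* A disabled);
* ``HAI`` -- dispersal only into India (all gains *out of* A disabled).

Each hypothesis has the same two free parameters (d, e); the hypotheses
differ in the fixed multiplier matrix and are therefore compared by AIC,
not by nested likelihood-ratio tests.

Ranges are represented as bitmasks over the ordered area tuple; the null
range is mask 0 and is kept as the last state of the rate matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo_io import Phylogeny, PhyloError, validate_tip_areas

__all__ = [
    "AreaSet",
    "DECParams",
    "DECFit",
    "SplitScenario",
    "SplitReconstruction",
    "DEFAULT_AREAS",
    "enumerate_ranges",
    "build_dispersal_matrix",
    "build_q",
    "branch_probs",
    "cladogenesis_outcomes",
    "DECModel",
    "dec_loglik",
    "fit_dec",
    "reconstruct_splits",
]

NEG_INF = float("-inf")

_HYPOTHESES = ("H0", "HIA", "HAI")


def _normalize_hypothesis(name: str) -> str:
    key = name.upper().replace("_", "").replace("->", "").replace("→", "")
    aliases = {"H0": "H0", "HIA": "HIA", "HAI": "HAI"}
    if key not in aliases:
        raise ValueError(f"unknown dispersal hypothesis {name!r}; expected one of {_HYPOTHESES}")
    return aliases[key]


# -- area sets and range states -------------------------------------------


@dataclass(frozen=True)
class AreaSet:
    """Ordered area codes plus a symmetric, irreflexive adjacency relation.

    ``adjacency`` is a frozenset of two-element frozensets of area codes;
    the representation makes irreflexivity and symmetry structural.
    """

    areas: tuple[str, ...] = ("A", "B", "C", "D")
    adjacency: frozenset = frozenset(
        {frozenset("AB"), frozenset("BC"), frozenset("BD"), frozenset("CD")}
    )

    def __post_init__(self):
        if not self.areas:
            raise ValueError("area set must contain at least one area")
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area codes")
        for pair in self.adjacency:
            if len(pair) != 2 or not pair <= set(self.areas):
                raise ValueError(f"bad adjacency pair {set(pair)}")

    @classmethod
    def full(cls, areas=("A", "B", "C", "D")) -> "AreaSet":
        """All areas mutually adjacent (no range restriction)."""
        pairs = frozenset(frozenset(p) for p in itertools.combinations(areas, 2))
        return cls(areas=tuple(areas), adjacency=pairs)

    @property
    def n(self) -> int:
        return len(self.areas)

    def index(self, area: str) -> int:
        return self.areas.index(area)

    def mask(self, areas) -> int:
        """Bitmask of an iterable (or string) of area codes."""
        m = 0
        for a in areas:
            m |= 1 << self.index(a)
        return m

    def decode(self, mask: int) -> frozenset[str]:
        return frozenset(a for i, a in enumerate(self.areas) if mask >> i & 1)

    def label(self, mask: int) -> str:
        return "".join(a for i, a in enumerate(self.areas) if mask >> i & 1) or "0"

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def connected(self, mask: int) -> bool:
        """Is the subset connected in the adjacency graph?"""
        bits = [i for i in range(self.n) if mask >> i & 1]
        if not bits:
            return False
        seen, frontier = {bits[0]}, [bits[0]]
        while frontier:
            i = frontier.pop()
            for j in bits:
                if j not in seen and self.adjacent(self.areas[i], self.areas[j]):
                    seen.add(j)
                    frontier.append(j)
        return len(seen) == len(bits)


DEFAULT_AREAS = AreaSet()


def enumerate_ranges(area_set: AreaSet, max_size: int | None = None) -> list[int]:
    """All allowed range states as bitmasks, plus the null range.

    Allowed = nonempty, adjacency-connected, of size <= ``max_size``.
    Deterministic order: by size, then bitmask value; the null range (0) is
    appended last so rate matrices can treat it as the final, absorbing
    state.
    """
    if area_set.n < 1:
        raise ValueError("empty area list")
    cap = area_set.n if max_size is None else max_size
    masks = [
        m
        for m in range(1, 1 << area_set.n)
        if bin(m).count("1") <= cap and area_set.connected(m)
    ]
    masks.sort(key=lambda m: (bin(m).count("1"), m))
    return masks + [0]


# -- parameters ------------------------------------------------------------


@dataclass
class DECParams:
    """DEC rate parameters: dispersal ``d``, extinction ``e`` (per Ma) and a
    fixed 0/1 dispersal multiplier matrix ``D`` (source row -> target
    column; the diagonal is ignored)."""

    d: float
    e: float
    D: np.ndarray

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")
        self.D = np.asarray(self.D, dtype=float)


def build_dispersal_matrix(
    hypothesis: str, area_set: AreaSet = DEFAULT_AREAS, source_area: str = "A"
) -> np.ndarray:
    """Dispersal multiplier matrix for one of the directional hypotheses.

    ``HIA`` permits range expansion only out of ``source_area`` (India):
    every multiplier *into* it is zeroed.  ``HAI`` is the reverse: every
    multiplier *out of* it is zeroed.  ``H0`` leaves all off-diagonal
    multipliers at 1.
    """
    h = _normalize_hypothesis(hypothesis)
    n = area_set.n
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    i = area_set.index(source_area)
    if h == "HIA":
        D[:, i] = 0.0
    elif h == "HAI":
        D[i, :] = 0.0
    return D


def build_q(ranges: list[int], params: DECParams, area_set: AreaSet = DEFAULT_AREAS) -> np.ndarray:
    """Anagenetic rate matrix over the range states (null state last).

    Gain of area ``a`` by range R (when R + a is an allowed state) has rate
    ``d * sum_{b in R} D[b, a]``; loss of any area of R has rate ``e`` (the
    last loss moves to the absorbing null range).  Rows sum to zero.
    """
    if params.d < 0 or params.e < 0:
        raise ValueError("rates must be non-negative")
    idx = {m: i for i, m in enumerate(ranges)}
    n = len(ranges)
    Q = np.zeros((n, n))
    for m in ranges:
        if m == 0:
            continue  # null is absorbing
        i = idx[m]
        bits = [b for b in range(area_set.n) if m >> b & 1]
        for a in range(area_set.n):
            if m >> a & 1:
                # loss of area a
                target = m & ~(1 << a)
                if target in idx:  # null always present; others need connectivity
                    Q[i, idx[target]] += params.e
            else:
                target = m | (1 << a)
                if target in idx:
                    rate = params.d * sum(params.D[b, a] for b in bits)
                    Q[i, idx[target]] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def _reach_mask(Q: np.ndarray) -> np.ndarray:
    """Boolean transitive closure of Q's transition digraph.

    P(t)[i, j] is exactly zero whenever j is unreachable from i; masking
    with the closure removes the ~1e-16 numerical noise that expm or an
    eigendecomposition would otherwise leave in structurally zero entries
    (which matters when the true likelihood is exactly zero).
    """
    pos = np.asarray(Q) > 0
    n = Q.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    if pos[offdiag].all():
        return np.ones((n, n), dtype=bool)
    reach = pos | np.eye(n, dtype=bool)
    for _ in range(Q.shape[0]):
        new = (reach.astype(np.uint8) @ reach.astype(np.uint8)) > 0
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def branch_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities exp(Q t); rows sum to 1, tiny negatives and
    structurally impossible transitions clipped to exactly 0."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite rate matrix")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    P[P < 0] = 0.0
    P[~_reach_mask(Q)] = 0.0
    return P


class _Propagator:
    """P(t) factory: eigendecomposition fast path with expm fallback."""

    def __init__(self, Q: np.ndarray, reach: np.ndarray | None = None):
        self.Q = np.asarray(Q, dtype=float)
        self.reach = _reach_mask(self.Q) if reach is None else reach
        self._eig = None
        try:
            w, V = np.linalg.eig(self.Q)
            # validity is checked per call via row sums (with expm fallback),
            # so no conditioning estimate is needed here
            self._eig = (w, V, np.linalg.inv(V))
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        return self.batch(np.array([t]))[0]

    def batch(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for many branch lengths at once."""
        ts = np.asarray(ts, dtype=float)
        n = self.Q.shape[0]
        if self._eig is not None:
            w, V, Vinv = self._eig
            E = np.exp(np.outer(ts, w))  # (T, n)
            P = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
            rows = P.sum(axis=2)
            if np.all(np.abs(rows - 1.0) < 1e-9):
                P[P < 0] = 0.0
                P[:, ~self.reach] = 0.0
                P[ts == 0] = np.eye(n)
                return P
        return np.stack([branch_probs(self.Q, t) for t in ts])


# -- cladogenesis ----------------------------------------------------------


def cladogenesis_outcomes(
    range_mask: int, area_set: AreaSet = DEFAULT_AREAS
) -> list[tuple[int, int, float]]:
    """Equally weighted (left, right, weight) daughter-range scenarios.

    Single-area ranges split sympatrically (R, R).  Widespread ranges admit
    (i) peripheral-isolate sympatry ({a}, R) and (R, {a}) for each area a of
    R, and (ii) vicariance into a singleton and its complement, both ordered
    directions, provided the complement is itself an allowed (connected)
    state.  Weights are uniform over the admitted ordered outcomes.
    """
    if range_mask == 0:
        raise ValueError("null range has no cladogenetic outcomes")
    bits = [b for b in range(area_set.n) if range_mask >> b & 1]
    if len(bits) == 1:
        return [(range_mask, range_mask, 1.0)]
    pairs: set[tuple[int, int]] = set()
    for b in bits:
        single = 1 << b
        pairs.add((single, range_mask))
        pairs.add((range_mask, single))
        rest = range_mask & ~single
        if area_set.connected(rest):
            pairs.add((single, rest))
            pairs.add((rest, single))
    ordered = sorted(pairs)
    w = 1.0 / len(ordered)
    return [(l, r, w) for l, r in ordered]


# -- likelihood ------------------------------------------------------------


@dataclass
class DECFit:
    """A fitted DEC model: parameters, maximized log-likelihood, parameter
    count and model name."""

    params: DECParams
    lnl: float
    k: int
    model_name: str
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "d": self.params.d,
            "e": self.params.e,
            "lnL": self.lnl,
            "k": self.k,
            "converged": self.converged,
        }


class DECModel:
    """Pruning-algorithm DEC likelihood for a fixed tree, tip table and
    dispersal multiplier matrix.

    The state space is the adjacency-allowed ranges plus the null range.
    Partial likelihoods are rescaled per node to avoid underflow on large
    trees; the root likelihood is the unweighted sum of the conditional
    likelihoods over all nonempty allowed root ranges (no range-size prior,
    no conditioning on survival).
    """

    def __init__(
        self,
        tree: Phylogeny,
        tip_areas: dict[str, frozenset[str]],
        D: np.ndarray | None = None,
        hypothesis: str = "H0",
        area_set: AreaSet = DEFAULT_AREAS,
        max_range_size: int | None = None,
        root_range: int | None = None,
    ):
        tree.assert_ultrametric()
        validate_tip_areas(tip_areas, tree)
        self.tree = tree
        self.area_set = area_set
        self.ranges = enumerate_ranges(area_set, max_range_size)
        self.idx = {m: i for i, m in enumerate(self.ranges)}
        self.n_states = len(self.ranges)
        self.null_index = self.idx[0]
        self.D = build_dispersal_matrix(hypothesis, area_set) if D is None else np.asarray(D, float)
        self.hypothesis = hypothesis
        self.root_range = root_range
        # cladogenesis scenario index arrays per nonempty range
        self.clado: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
        for m in self.ranges:
            if m == 0:
                continue
            outs = cladogenesis_outcomes(m, area_set)
            li = np.array([self.idx[l] for l, _, _ in outs])
            ri = np.array([self.idx[r] for _, r, _ in outs])
            self.clado[m] = (li, ri, outs[0][2])
        # unique branch lengths, shared across likelihood evaluations
        uniq = sorted(
            {round(float(tree.blen[v]), 12) for v in range(tree.n_nodes) if tree.parent[v] >= 0}
        )
        self._uts = np.array(uniq)
        self._ut_index = {t: i for i, t in enumerate(uniq)}
        # tip indicator vectors
        self.tip_vec: dict[int, np.ndarray] = {}
        for v in tree.tips:
            mask = area_set.mask(tip_areas[tree.labels[v]])
            if mask not in self.idx or mask == 0:
                raise PhyloError(
                    f"tip {tree.labels[v]!r} has range "
                    f"{area_set.label(mask)} not allowed under adjacency"
                )
            vec = np.zeros(self.n_states)
            vec[self.idx[mask]] = 1.0
            self.tip_vec[v] = vec

    # ..................................................................

    def _inside(self, d: float, e: float):
        """Post-order partial likelihoods with per-node log scaling.

        Returns (L, logscale, P, alive) where L[v] are scaled conditional
        likelihoods at node v, logscale[v] the accumulated log factor for
        v's subtree, and alive is False when some node has zero likelihood
        for every state (the data are impossible under the parameters).
        """
        Q = build_q(self.ranges, DECParams(d, e, self.D), self.area_set)
        prop = _Propagator(Q)
        tree = self.tree
        L = np.zeros((tree.n_nodes, self.n_states))
        logscale = np.zeros(tree.n_nodes)
        Ps = prop.batch(self._uts)

        def P(t):
            return Ps[self._ut_index[round(float(t), 12)]]

        for v in tree.postorder():
            if tree.is_tip(v):
                L[v] = self.tip_vec[v]
                continue
            l, r = tree.children[v]
            dl = P(tree.blen[l]) @ L[l]
            dr = P(tree.blen[r]) @ L[r]
            Lv = np.zeros(self.n_states)
            for m, (li, ri, w) in self.clado.items():
                Lv[self.idx[m]] = w * np.sum(dl[li] * dr[ri])
            top = Lv.max()
            if top <= 0:
                return L, logscale, P, False
            L[v] = Lv / top
            logscale[v] = np.log(top) + logscale[l] + logscale[r]
        return L, logscale, P, True

    def loglik(self, d: float, e: float) -> float:
        """ln of the likelihood summed over allowed root ranges (nats)."""
        if d < 0 or e < 0:
            raise ValueError("rates must be non-negative")
        tree = self.tree
        if tree.n_tips == 1:
            raise PhyloError("need at least two tips")
        L, logscale, _, alive = self._inside(d, e)
        root = tree.root
        if not alive:
            return NEG_INF
        if self.root_range is not None:
            total = L[root][self.idx[self.root_range]]
        else:
            keep = np.ones(self.n_states, bool)
            keep[self.null_index] = False
            total = L[root][keep].sum()
        if total <= 0:
            return NEG_INF
        return float(np.log(total) + logscale[root])


def dec_loglik(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    params: DECParams,
    area_set: AreaSet = DEFAULT_AREAS,
    root_range: int | None = None,
) -> float:
    """DEC log-likelihood for explicit parameters (convenience wrapper)."""
    model = DECModel(tree, tip_areas, D=params.D, area_set=area_set, root_range=root_range)
    return model.loglik(params.d, params.e)


# -- maximum-likelihood fitting -------------------------------------------

_RATE_BOUNDS = (1e-8, 10.0)  # per Ma, on both d and e
_STARTS = ((1e-2, 1e-2), (1e-3, 1e-4), (1e-1, 1e-2))


def fit_dec(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    hypothesis: str = "H0",
    area_set: AreaSet = DEFAULT_AREAS,
) -> DECFit:
    """Maximize the DEC likelihood over (d, e) for one dispersal hypothesis.

    Bounded L-BFGS-B on (ln d, ln e) with three fixed starting points;
    bounds 1e-8..10 per Ma.  Both hypotheses keep k = 2 free parameters.
    """
    h = _normalize_hypothesis(hypothesis)
    model = DECModel(tree, tip_areas, hypothesis=h, area_set=area_set)
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])

    def nll(x):
        val = model.loglik(float(np.exp(x[0])), float(np.exp(x[1])))
        return 1e12 if not np.isfinite(val) else -val

    best = None
    any_finite = False
    for d0, e0 in _STARTS:
        res = minimize(
            nll,
            x0=np.log([d0, e0]),
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if res.fun < 1e11:
            any_finite = True
        if best is None or res.fun < best.fun:
            best = res
    if not any_finite:
        raise PhyloError("DEC likelihood is zero everywhere on the search grid")
    d_hat, e_hat = np.exp(best.x)
    params = DECParams(float(d_hat), float(e_hat), build_dispersal_matrix(h, area_set))
    return DECFit(params=params, lnl=float(-best.fun), k=2, model_name=h, converged=bool(best.success))


# -- ancestral split reconstruction ---------------------------------------


@dataclass
class SplitScenario:
    """One cladogenetic scenario at a node: ancestral range and the two
    daughter ranges, with its global log-likelihood and relative
    probability (scenario likelihood / total over all scenarios)."""

    ancestor: str
    left: str
    right: str
    lnl: float
    rel_prob: float


@dataclass
class SplitReconstruction:
    """Scenarios retained at one internal node (within 2 lnL units of the
    best; best first)."""

    node: int
    scenarios: list[SplitScenario]
    best_lnl: float


def reconstruct_splits(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    fit: DECFit,
    area_set: AreaSet = DEFAULT_AREAS,
    lnl_window: float = 2.0,
) -> dict[int, SplitReconstruction]:
    """Per-node cladogenetic scenarios within ``lnl_window`` of the best.

    For every internal node the global likelihood is decomposed over the
    (ancestor, left daughter, right daughter) scenarios at that node using
    an inside-outside pass; relative probabilities are normalized by the
    sum over *all* scenarios at the node, which equals the global
    likelihood.
    """
    model = DECModel(tree, tip_areas, D=fit.params.D, area_set=area_set)
    d, e = fit.params.d, fit.params.e
    L, ls, P, alive = model._inside(d, e)
    root = tree.root
    if not alive:
        raise PhyloError("zero likelihood; cannot reconstruct splits")

    n_states = model.n_states
    nonempty = [i for i, m in enumerate(model.ranges) if m != 0]

    # outside vectors F[v][R]: likelihood of data outside v's subtree given
    # node state R, with its own log scale fs[v]
    F = np.zeros((tree.n_nodes, n_states))
    fs = np.zeros(tree.n_nodes)
    F[root][nonempty] = 1.0

    out: dict[int, SplitReconstruction] = {}
    down: dict[int, tuple[np.ndarray, float]] = {}

    for v in reversed(tree.postorder()):  # preorder: parents first
        if tree.is_tip(v):
            continue
        l, r = tree.children[v]
        dl = P(tree.blen[l]) @ L[l]
        dr = P(tree.blen[r]) @ L[r]
        sl, sr = ls[l], ls[r]

        # scenario decomposition at v
        scen = []
        total = 0.0
        base = fs[v] + sl + sr
        for m, (li, ri, w) in model.clado.items():
            fv = F[v][model.idx[m]]
            if fv <= 0:
                continue
            liks = fv * w * dl[li] * dr[ri]
            total += liks.sum()
            for k in range(len(li)):
                if liks[k] > 0:
                    scen.append(
                        (
                            float(np.log(liks[k]) + base),
                            liks[k],
                            model.area_set.label(m),
                            model.area_set.label(model.ranges[li[k]]),
                            model.area_set.label(model.ranges[ri[k]]),
                        )
                    )
        scen.sort(key=lambda s: -s[0])
        best = scen[0][0]
        recs = [
            SplitScenario(anc, lft, rgt, lnl_s, lik / total)
            for lnl_s, lik, anc, lft, rgt in scen
            if lnl_s >= best - lnl_window
        ]
        out[v] = SplitReconstruction(node=v, scenarios=recs, best_lnl=best)

        # propagate outside vectors to children
        ftop_l = np.zeros(n_states)
        ftop_r = np.zeros(n_states)
        for m, (li, ri, w) in model.clado.items():
            coeff = F[v][model.idx[m]] * w
            if coeff <= 0:
                continue
            np.add.at(ftop_l, li, coeff * dr[ri])
            np.add.at(ftop_r, ri, coeff * dl[li])
        for c, ftop, s_sib in ((l, ftop_l, sr), (r, ftop_r, sl)):
            if tree.is_tip(c):
                continue
            Fc = P(tree.blen[c]).T @ ftop
            top = Fc.max()
            if top > 0:
                F[c] = Fc / top
                fs[c] = fs[v] + s_sib + np.log(top)
            else:
                F[c] = Fc
                fs[c] = NEG_INF
    return out
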