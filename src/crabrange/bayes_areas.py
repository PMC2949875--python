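"""Bayesian multistate (Mk) ancestral-area reconstruction.

Each tip occupies exactly one area; the character evolves along the tree
under a continuous-time Markov chain with a fully asymmetric rate matrix
(12 free rates for four areas) and a uniform root-state prior.  Rates get
a hierarchical exponential prior whose mean is itself uniform on
(0, ``hyper_mean_max``), mirroring the seeded exponential hyperprior of
BayesTraits-style multistate analyses; proposals are sliding windows of
width ``rate_deviation`` on one randomly chosen rate (or the hyperprior
mean) per generation, reflected at the boundaries.

Ancestral states at internal nodes are sampled by conditional draws from
the pruning partials at each sampled generation.  A node may be
"fossilized" (constrained) to one state by zeroing its partial
likelihoods for all other states; running one constrained analysis per
candidate state and comparing harmonic-mean marginal likelihoods yields a
Bayes-factor test of node support: a state is supported only when it beats
every alternative by log10 BF > 0.48, otherwise the node is equivocal.
Because harmonic means are unstable, each constrained run is repeated
(five times by default) and the per-state estimate is the mean over runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dec_core import _Propagator
from .model_select import BF_THRESHOLDS, harmonic_mean_lnml, log10_bf
from .phylo_io import MCMCTrace, Phylogeny, PhyloError, validate_tip_areas

__all__ = [
    "MCMCConfig",
    "MkPosterior",
    "NodeSupport",
    "mk_loglik",
    "sample_posterior",
    "node_support",
]

DEFAULT_STATES = ("A", "B", "C", "D")


def _build_rate_matrix(rates: np.ndarray) -> np.ndarray:
    Q = np.array(rates, dtype=float, copy=True)
    if np.any(Q[~np.eye(Q.shape[0], dtype=bool)] < 0):
        raise ValueError("rates must be non-negative")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _MkEngine:
    """Pruning likelihood with cached structure, reusable across proposals."""

    def __init__(self, tree, tip_areas, states, fossilize=None):
        tree.assert_ultrametric()
        validate_tip_areas(tip_areas, tree)
        self.tree = tree
        self.states = tuple(states)
        self.k = len(self.states)
        self.fossilize = {}
        if fossilize:
            for node, state in fossilize.items():
                if tree.is_tip(node) or not 0 <= node < tree.n_nodes:
                    raise PhyloError(f"invalid internal node id {node}")
                self.fossilize[int(node)] = self.states.index(state)
        uniq = sorted(
            {round(float(tree.blen[v]), 12) for v in range(tree.n_nodes) if tree.parent[v] >= 0}
        )
        self._uts = np.array(uniq)
        self._ut_index = {t: i for i, t in enumerate(uniq)}
        self.tip_state = {}
        for v in tree.tips:
            areas = tip_areas[tree.labels[v]]
            if len(areas) != 1:
                raise PhyloError(
                    f"tip {tree.labels[v]!r} is widespread ({''.join(sorted(areas))}); "
                    "the multistate model needs single-area tips"
                )
            (a,) = areas
            self.tip_state[v] = self.states.index(a)
        self.pi = np.full(self.k, 1.0 / self.k)

    def partials(self, Q: np.ndarray):
        """Scaled conditional likelihoods per node plus branch P matrices."""
        tree = self.tree
        Ps = _Propagator(Q).batch(self._uts)

        def P(t):
            return Ps[self._ut_index[round(float(t), 12)]]

        L = np.zeros((tree.n_nodes, self.k))
        logscale = 0.0
        for v in tree.postorder():
            if tree.is_tip(v):
                L[v, self.tip_state[v]] = 1.0
            else:
                l, r = tree.children[v]
                Lv = (P(tree.blen[l]) @ L[l]) * (P(tree.blen[r]) @ L[r])
                if v in self.fossilize:
                    keep = self.fossilize[v]
                    masked = np.zeros_like(Lv)
                    masked[keep] = Lv[keep]
                    Lv = masked
                top = Lv.max()
                if top <= 0:
                    return None, None, float("-inf"), P
                L[v] = Lv / top
                logscale += np.log(top)
        root_lik = float(self.pi @ L[tree.root])
        if root_lik <= 0:
            return None, None, float("-inf"), P
        return L, logscale, float(np.log(root_lik) + logscale), P

    def loglik(self, Q: np.ndarray) -> float:
        return self.partials(Q)[2]

    def draw_node_states(self, L, P, rng) -> dict[int, int]:
        """Joint conditional draw of internal-node states, root downward."""
        tree = self.tree
        draw = {}
        for v in reversed(tree.postorder()):  # preorder
            if tree.is_tip(v):
                continue
            p = tree.parent[v]
            if p < 0:
                probs = self.pi * L[v]
            else:
                probs = P(tree.blen[v])[draw[p]] * L[v]
            probs = probs / probs.sum()
            draw[v] = int(rng.choice(self.k, p=probs))
        return draw


def mk_loglik(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    rates: np.ndarray,
    states: tuple[str, ...] = DEFAULT_STATES,
) -> float:
    """Felsenstein-pruning Mk log-likelihood with uniform root frequencies.

    ``rates`` is a (k, k) matrix of off-diagonal transition rates (the
    diagonal is recomputed).  Tips must be single-area.
    """
    engine = _MkEngine(tree, tip_areas, states)
    return engine.loglik(_build_rate_matrix(np.asarray(rates, dtype=float)))


# -- MCMC ------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler settings.

    Desk-scale defaults (1e5 generations, sampling every 100, 100 samples
    of burn-in) give quick, well-mixed runs on four states; the historical
    large-scale settings (5e7 generations etc.) remain valid values.
    ``rate_deviation`` is the sliding-window proposal width.
    """

    generations: int = 100_000
    sample_interval: int = 100
    burn_in_samples: int = 100
    rate_deviation: float = 0.1
    seed: int | None = None
    repeats: int = 5
    hyper_mean_max: float = 80.0

    def __post_init__(self):
        if self.generations < self.sample_interval * 10:
            raise ValueError("generations must be at least 10x the sample interval")
        if self.rate_deviation < 0:
            raise ValueError("rate_deviation must be non-negative")


@dataclass
class MkPosterior:
    """Output of one MCMC run: the lnL trace (plus rate and hyperprior-mean
    columns), per-sample internal-node state draws, and the realized
    proposal acceptance rate."""

    trace: MCMCTrace
    node_states: pd.DataFrame | None
    acceptance_rate: float
    states: tuple[str, ...]


def sample_posterior(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    config: MCMCConfig,
    *,
    fossilize: dict[int, str] | None = None,
    fix_rates: np.ndarray | None = None,
    sample_node_states: bool = True,
    states: tuple[str, ...] = DEFAULT_STATES,
) -> MkPosterior:
    """Metropolis-Hastings over the 12 rates and the exponential-hyperprior
    mean, with optional node fossilization.

    ``fix_rates`` freezes the rate matrix (no proposals at all); the chain
    then only redraws node states, which makes the draws iid from the
    exact conditional distribution -- useful for validation.
    """
    engine = _MkEngine(tree, tip_areas, states, fossilize=fossilize)
    k = engine.k
    off = [(i, j) for i in range(k) for j in range(k) if i != j]
    rng = np.random.default_rng(config.seed)

    # initialization at the tree's natural rate scale (~1 expected change on
    # the whole tree); the stationary distribution is unaffected, but
    # desk-scale chains would otherwise spend their whole run walking in from
    # the far tail of the seeded prior
    scale0 = 1.0 / max(float(tree.blen.sum()), 1e-6)
    if fix_rates is not None:
        rates = np.array(fix_rates, dtype=float, copy=True)
        m = max(rates[~np.eye(k, dtype=bool)].mean(), 1e-6)
        fixed = True
    else:
        m = min(scale0, config.hyper_mean_max)
        rates = rng.exponential(m, size=(k, k))
        fixed = False
    np.fill_diagonal(rates, 0.0)

    def log_prior(r, mean):
        if mean <= 0 or mean > config.hyper_mean_max:
            return float("-inf")
        vals = r[~np.eye(k, dtype=bool)]
        return float(-len(vals) * np.log(mean) - vals.sum() / mean)

    L, Pfun, lnl = None, None, None
    L, _, lnl, Pfun = engine.partials(_build_rate_matrix(rates))
    # a fresh chain can start in a zero-likelihood corner under fossilization;
    # re-draw rates until the state is viable
    tries = 0
    while not np.isfinite(lnl) and not fixed:
        tries += 1
        if tries > 200:
            raise PhyloError("could not initialize MCMC at finite likelihood")
        rates = rng.exponential(min(scale0, config.hyper_mean_max), size=(k, k))
        np.fill_diagonal(rates, 0.0)
        L, _, lnl, Pfun = engine.partials(_build_rate_matrix(rates))
    if not np.isfinite(lnl):
        raise PhyloError("zero likelihood under the fixed rates")
    lp = log_prior(rates, m)

    n_samples = config.generations // config.sample_interval
    records = []
    node_rows = []
    accepted = proposed = 0

    for gen in range(1, config.generations + 1):
        if not fixed:
            proposed += 1
            idx = int(rng.integers(0, len(off) + 1))
            if idx < len(off):
                i, j = off[idx]
                new_rates = rates.copy()
                delta = rng.uniform(-config.rate_deviation / 2, config.rate_deviation / 2)
                new_rates[i, j] = abs(new_rates[i, j] + delta)  # reflect at 0
                newL, _, new_lnl, newP = engine.partials(_build_rate_matrix(new_rates))
                new_lp = log_prior(new_rates, m)
                if np.log(rng.uniform()) < (new_lnl + new_lp) - (lnl + lp):
                    rates, lnl, lp, L, Pfun = new_rates, new_lnl, new_lp, newL, newP
                    accepted += 1
            else:
                # independent uniform proposal over the hyperprior-mean range
                # (symmetric, so the MH ratio is just the prior ratio)
                new_m = rng.uniform(1e-9, config.hyper_mean_max)
                new_lp = log_prior(rates, new_m)
                if np.log(rng.uniform()) < new_lp - lp:
                    m, lp = new_m, new_lp
                    accepted += 1
        if gen % config.sample_interval == 0:
            rec = {"state": gen, "lnL": lnl, "hyper_mean": m}
            for (i, j) in off:
                rec[f"q_{states[i]}{states[j]}"] = rates[i, j]
            records.append(rec)
            if sample_node_states:
                draw = engine.draw_node_states(L, Pfun, rng)
                node_rows.append({f"node_{v}": states[s] for v, s in draw.items()})

    trace = MCMCTrace(samples=pd.DataFrame(records), burn_in=min(config.burn_in_samples, n_samples - 2))
    node_df = pd.DataFrame(node_rows) if sample_node_states else None
    acc = accepted / proposed if proposed else float("nan")
    return MkPosterior(trace=trace, node_states=node_df, acceptance_rate=acc, states=engine.states)


# -- node support ----------------------------------------------------------


@dataclass
class NodeSupport:
    """Bayes-factor comparison of constrained (fossilized) states at a node.

    ``lnml`` maps state -> mean harmonic-mean lnML over repeats, ``lnml_se``
    the standard error over repeats.  ``verdict`` is ``"supported:<state>"``
    only when the best state beats every alternative by log10 BF above the
    substantial-support threshold, else ``"equivocal"``.
    """

    node: int
    states: tuple[str, ...]
    lnml: dict[str, float]
    lnml_se: dict[str, float]
    runs: dict[str, list[float]]
    best_state: str
    bf_vs_best: dict[str, float]
    supported: bool

    @property
    def verdict(self) -> str:
        return f"supported:{self.best_state}" if self.supported else "equivocal"


def node_support(
    tree: Phylogeny,
    tip_areas: dict[str, frozenset[str]],
    node: int,
    config: MCMCConfig,
    *,
    states: tuple[str, ...] = DEFAULT_STATES,
    candidate_states: tuple[str, ...] | None = None,
) -> NodeSupport:
    """Fossilize ``node`` to each candidate state, estimate each constrained
    model's marginal likelihood (mean of ``config.repeats`` harmonic-mean
    runs) and test the best state against the alternatives."""
    if tree.is_tip(node) or not 0 <= node < tree.n_nodes:
        raise PhyloError(f"invalid internal node id {node}")
    cands = candidate_states or states
    seeds = np.random.SeedSequence(config.seed).spawn(len(cands) * config.repeats)
    lnml: dict[str, float] = {}
    se: dict[str, float] = {}
    runs: dict[str, list[float]] = {}
    si = 0
    for st in cands:
        vals = []
        for _ in range(config.repeats):
            cfg = MCMCConfig(
                generations=config.generations,
                sample_interval=config.sample_interval,
                burn_in_samples=config.burn_in_samples,
                rate_deviation=config.rate_deviation,
                seed=int(seeds[si].generate_state(1)[0] % (2**31)),
                repeats=config.repeats,
                hyper_mean_max=config.hyper_mean_max,
            )
            si += 1
            post = sample_posterior(
                tree,
                tip_areas,
                cfg,
                fossilize={node: st},
                sample_node_states=False,
                states=states,
            )
            vals.append(harmonic_mean_lnml(post.trace).lnml)
        runs[st] = vals
        lnml[st] = float(np.mean(vals))
        se[st] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    best = max(lnml, key=lnml.get)
    bf = {st: log10_bf(lnml[best], lnml[st]) for st in cands if st != best}
    supported = all(v > BF_THRESHOLDS[0] for v in bf.values())
    return NodeSupport(
        node=node,
        states=tuple(cands),
        lnml=lnml,
        lnml_se=se,
        runs=runs,
        best_state=best,
        bf_vs_best=bf,
        supported=supported,
    )
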