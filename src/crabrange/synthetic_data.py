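"""Synthetic data with known ground truth for every pipeline input.

The study system this package analyzes -- a ~57-species ultrametric
chronogram of Asian freshwater crabs with a root age near 47.23 Ma and
tips assigned to four areas -- cannot be redistributed, so every analysis
is validated on simulated stand-ins:

* Yule (pure-birth) trees, optionally rescaled to a target root age;
* forward DEC simulations (Gillespie gains/losses along branches, a
  cladogenetic scenario drawn at every node) with the true node ranges
  recorded;
* forward Mk simulations of single-area characters;
* MCMC-style log-likelihood traces from a conjugate normal-normal model
  whose true marginal likelihood is available in closed form; and
* a 57-tip "study-scale" fixture: a Yule tree rescaled to root age
  47.23 Ma whose tip areas were generated under the India-to-Asia
  dispersal hypothesis from an Indian root.

All simulators consume an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from random import Random

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .dec_core import (
    AreaSet,
    DECParams,
    DEFAULT_AREAS,
    build_dispersal_matrix,
    build_q,
    cladogenesis_outcomes,
    enumerate_ranges,
)
from .phylo_io import MCMCTrace, Phylogeny, PhyloError, parse_newick, write_newick

__all__ = [
    "SimRecord",
    "NormalNormalSpec",
    "simulate_yule",
    "simulate_dec_tips",
    "simulate_mk_tips",
    "simulate_trace",
    "study_fixture",
    "load_study_fixture",
    "FIXTURE_SEED",
    "FIXTURE_ROOT_AGE",
    "FIXTURE_N_TIPS",
]

FIXTURE_N_TIPS = 57
FIXTURE_ROOT_AGE = 47.23
#: Fixture seed, fixed at fixture creation (the shipped tree/tip files were
#: generated with it).
FIXTURE_SEED = 20109

#: Study-anchored DEC generating rates for the fixture (per Ma).
FIXTURE_D = 3.9e-3
FIXTURE_E = 3.2e-4


@dataclass
class SimRecord:
    """A simulated dataset plus its generating truth."""

    tree: Phylogeny
    tip_areas: dict[str, frozenset[str]]
    params: dict
    node_truth: dict[int, str]
    branch_start: dict[int, str]
    seed: int


# -- Yule trees ------------------------------------------------------------


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    root_age: float | None = None,
) -> Phylogeny:
    """Pure-birth ultrametric tree with ``n_tips`` extant tips.

    The simulator stops at the n-th speciation and then runs all lineages
    forward by one further exponential epoch (the time until the next,
    unobserved split), so the youngest divergence sits strictly before the
    present.  Optionally rescaled so the root age equals ``root_age`` (the
    Yule shape is scale-free, so rescaling preserves the generating process
    up to the time unit).
    """
    if n_tips < 2 or birth_rate <= 0:
        raise ValueError("need n_tips >= 2 and birth_rate > 0")
    from dendropy.simulate import treesim

    pyrng = Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=pyrng,
    )
    stretch = pyrng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(dtree.leaf_node_iter(), 1):
        leaf.taxon.label = f"t{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + stretch
    tree = parse_newick(
        dtree.as_string(schema="newick", suppress_rooting=True),
        require_ultrametric=False,
    )
    # guard against float drift in the simulator's depths
    if not tree.is_ultrametric(1e-6):
        raise PhyloError("simulated tree unexpectedly non-ultrametric")
    if root_age is not None:
        tree = tree.rescaled(root_age)
    return tree


# -- DEC forward simulation ------------------------------------------------


def _gillespie_branch(Q, start, t, null_index, rng, max_rejections):
    """CTMC path endpoint over time t, conditioned on not entering the null
    (extinct) range by rejection; returns the end state index."""
    for _ in range(max_rejections):
        state = start
        remaining = t
        dead = False
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            probs = Q[state].clip(min=0.0)
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(len(probs), p=probs))
            if state == null_index:
                dead = True
                break
        if not dead:
            return state
    raise PhyloError("branch resimulation cap hit; extinction rate too high")


def simulate_dec_tips(
    tree: Phylogeny,
    params: DECParams,
    root_range,
    seed: int | None = None,
    area_set: AreaSet = DEFAULT_AREAS,
    max_rejections: int = 1000,
) -> SimRecord:
    """Forward DEC simulation on a fixed tree.

    Uses the same anagenetic generator (:func:`~crabrange.dec_core.build_q`)
    and cladogenetic scenario weights as the likelihood.  Branches that
    reach the null (globally extinct) range are redrawn, so the tip count
    stays fixed; at the small extinction rates used here the survival
    conditioning this introduces is negligible relative to the unconditioned
    likelihood (see the methods note).
    """
    rng = np.random.default_rng(seed)
    ranges = enumerate_ranges(area_set)
    idx = {m: i for i, m in enumerate(ranges)}
    root_mask = root_range if isinstance(root_range, int) else area_set.mask(root_range)
    if root_mask not in idx or root_mask == 0:
        raise ValueError("root range is not an allowed state")
    Q = build_q(ranges, params, area_set)
    null_index = idx[0]

    clado = {}
    for m in ranges:
        if m:
            outs = cladogenesis_outcomes(m, area_set)
            clado[m] = outs

    node_state: dict[int, int] = {}
    branch_start: dict[int, int] = {}
    tip_areas: dict[str, frozenset[str]] = {}

    order = list(reversed(tree.postorder()))  # preorder
    node_state[tree.root] = idx[root_mask]
    for v in order:
        state = node_state[v]
        if tree.is_tip(v):
            tip_areas[tree.labels[v]] = area_set.decode(ranges[state])
            continue
        outs = clado[ranges[state]]
        pick = outs[int(rng.choice(len(outs)))]
        for child, start_mask in zip(tree.children[v], pick[:2]):
            branch_start[child] = idx[start_mask]
            node_state[child] = _gillespie_branch(
                Q, idx[start_mask], tree.blen[child], null_index, rng, max_rejections
            )

    return SimRecord(
        tree=tree,
        tip_areas=tip_areas,
        params={"d": params.d, "e": params.e, "model": "DEC"},
        node_truth={v: area_set.label(ranges[s]) for v, s in node_state.items()},
        branch_start={v: area_set.label(ranges[s]) for v, s in branch_start.items()},
        seed=seed if seed is not None else -1,
    )


# -- Mk forward simulation -------------------------------------------------


def simulate_mk_tips(
    tree: Phylogeny,
    rates: np.ndarray,
    root_state: str,
    seed: int | None = None,
    states: tuple[str, ...] = ("A", "B", "C", "D"),
) -> SimRecord:
    """Forward CTMC simulation of a single-area character."""
    rng = np.random.default_rng(seed)
    k = len(states)
    Q = np.array(rates, dtype=float, copy=True)
    np.fill_diagonal(Q, 0.0)
    if np.any(Q < 0):
        raise ValueError("rates must be non-negative")
    np.fill_diagonal(Q, -Q.sum(axis=1))

    node_state = {tree.root: states.index(root_state)}
    tip_areas: dict[str, frozenset[str]] = {}
    for v in reversed(tree.postorder()):
        if v != tree.root:
            state = node_state[tree.parent[v]]
            remaining = tree.blen[v]
            while True:
                rate = -Q[state, state]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                probs = Q[state].clip(min=0.0)
                probs[state] = 0.0
                probs /= probs.sum()
                state = int(rng.choice(k, p=probs))
            node_state[v] = state
        if tree.is_tip(v):
            tip_areas[tree.labels[v]] = frozenset(states[node_state[v]])

    return SimRecord(
        tree=tree,
        tip_areas=tip_areas,
        params={"rates": np.asarray(rates, float).tolist(), "model": "Mk"},
        node_truth={v: states[s] for v, s in node_state.items()},
        branch_start={v: states[node_state[tree.parent[v]]] for v in node_state if v != tree.root},
        seed=seed if seed is not None else -1,
    )


# -- conjugate-normal traces ----------------------------------------------


@dataclass(frozen=True)
class NormalNormalSpec:
    """Conjugate normal-normal model with a closed-form marginal likelihood.

    Latent mean ``mu ~ N(prior_mean, prior_sd^2)``; observations
    ``y_j ~ N(mu, like_sd^2)``.  For the harmonic-mean estimator to have
    finite variance the prior must be tighter than the likelihood of the
    sample mean: ``prior_sd^2 < like_sd^2 / n_obs`` (the defaults used by
    the package's validation keep a factor-2 margin).
    """

    prior_mean: float
    prior_sd: float
    like_sd: float
    data: tuple[float, ...]

    def __post_init__(self):
        if self.prior_sd <= 0 or self.like_sd <= 0:
            raise ValueError("variances must be positive")

    @classmethod
    def with_simulated_data(
        cls,
        n_obs: int = 5,
        prior_mean: float = 0.0,
        prior_sd: float = 0.3,
        like_sd: float = 1.0,
        seed: int | None = None,
    ) -> "NormalNormalSpec":
        rng = np.random.default_rng(seed)
        mu = rng.normal(prior_mean, prior_sd)
        y = rng.normal(mu, like_sd, size=n_obs)
        return cls(prior_mean, prior_sd, like_sd, tuple(float(v) for v in y))

    def posterior(self) -> tuple[float, float]:
        """Posterior (mean, sd) of the latent mean."""
        k = len(self.data)
        if k == 0:
            return self.prior_mean, self.prior_sd
        prec = k / self.like_sd**2 + 1 / self.prior_sd**2
        mean = (sum(self.data) / self.like_sd**2 + self.prior_mean / self.prior_sd**2) / prec
        return mean, prec**-0.5

    def true_lnml(self) -> float:
        """Exact ln marginal likelihood of the data (multivariate normal)."""
        k = len(self.data)
        if k == 0:
            return 0.0
        y = np.asarray(self.data)
        cov = self.like_sd**2 * np.eye(k) + self.prior_sd**2 * np.ones((k, k))
        return float(
            stats.multivariate_normal.logpdf(y, mean=np.full(k, self.prior_mean), cov=cov)
        )

    def loglik(self, mu) -> np.ndarray:
        y = np.asarray(self.data)
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if y.size == 0:
            return np.zeros(mu.shape)
        return stats.norm.logpdf(y[None, :], loc=mu[:, None], scale=self.like_sd).sum(axis=1)


def simulate_trace(
    n_samples: int, model_spec: NormalNormalSpec, seed: int | None = None
) -> tuple[MCMCTrace, float]:
    """Posterior draws converted to a per-sample lnL trace.

    Returns the trace and the model's true ln marginal likelihood.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    mean, sd = model_spec.posterior()
    mu = rng.normal(mean, sd, size=n_samples)
    lnl = model_spec.loglik(mu)
    df = pd.DataFrame({"state": np.arange(n_samples), "lnL": lnl, "mu": mu})
    return MCMCTrace(samples=df, burn_in=0), model_spec.true_lnml()


# -- study-scale fixture ---------------------------------------------------


def study_fixture(seed: int = FIXTURE_SEED) -> SimRecord:
    """57-tip, four-area dataset at study scale.

    A Yule tree rescaled to root age 47.23 Ma; tip areas simulated under
    the India-to-Asia dispersal hypothesis (HIA) from an Indian root
    ({A}), at the study-scale rates d=3.9e-3, e=3.2e-4 per Ma.
    """
    tree = simulate_yule(FIXTURE_N_TIPS, birth_rate=1.0, seed=seed, root_age=FIXTURE_ROOT_AGE)
    params = DECParams(FIXTURE_D, FIXTURE_E, build_dispersal_matrix("HIA"))
    rec = simulate_dec_tips(tree, params, root_range="A", seed=seed)
    rec.params.update({"hypothesis": "HIA", "root_range": "A", "root_age": FIXTURE_ROOT_AGE})
    return rec


def load_study_fixture() -> tuple[Phylogeny, dict[str, frozenset[str]], dict]:
    """Load the shipped (versioned) fixture files."""
    pkg = resources.files("crabrange") / "data"
    tree = parse_newick((pkg / "study_fixture_v1.nwk").read_text())
    from .phylo_io import read_tip_areas

    tips = read_tip_areas((pkg / "study_fixture_v1.tsv").read_text())
    truth = json.loads((pkg / "study_fixture_v1.json").read_text())
    return tree, tips, truth
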