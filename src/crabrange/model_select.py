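"""Model-comparison machinery.

Two families of comparisons are provided:

* information-theoretic comparison of maximum-likelihood fits with equal or
  differing parameter counts (AIC, delta-AIC and Akaike weights); and
* Bayesian comparison of hypotheses through marginal likelihoods estimated
  from MCMC log-likelihood traces by the harmonic-mean estimator, with
  pairwise log10 Bayes factors classified by the conventional
  Kass-Raftery-style thresholds: log10 BF > 0.48 substantial (*),
  > 1.00 strong (**), > 1.48 very strong (***).

The harmonic-mean estimator is known to be unstable (it is implemented
here because it is the standard Tracer-style workflow this package
mirrors); a top-fraction truncation variant is available behind a flag,
off by default.  Its standard error is obtained by a moving-block
bootstrap, since traces are autocorrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .phylo_io import MCMCTrace

__all__ = [
    "AICRow",
    "MarginalLikelihood",
    "BFMatrix",
    "aic_table",
    "harmonic_mean_lnml",
    "log10_bf",
    "bf_category",
    "category_stars",
    "bf_matrix",
    "hpd_interval",
    "BF_THRESHOLDS",
]

LN10 = math.log(10.0)

#: (substantial, strong, very strong) log10 Bayes-factor thresholds.
BF_THRESHOLDS = (0.48, 1.00, 1.48)


# -- AIC -------------------------------------------------------------------


@dataclass
class AICRow:
    model: str
    lnl: float
    k: int
    aic: float
    delta: float
    weight: float


def aic_table(fits) -> list[AICRow]:
    """AIC, delta-AIC and Akaike weights for >= 2 maximum-likelihood fits.

    ``fits`` may be objects with ``model_name``/``lnl``/``k`` attributes
    (e.g. :class:`~crabrange.dec_core.DECFit`) or ``(name, lnl, k)``
    tuples.  Rows are returned sorted by AIC (best first).
    """
    rows = []
    for f in fits:
        if isinstance(f, tuple):
            name, lnl, k = f
        else:
            name, lnl, k = f.model_name, f.lnl, f.k
        if not np.isfinite(lnl):
            raise ValueError(f"non-finite log-likelihood for model {name!r}")
        rows.append((str(name), float(lnl), int(k)))
    if len(rows) < 2:
        raise ValueError("need at least two fits to compare")
    aics = np.array([2 * k - 2 * lnl for _, lnl, k in rows])
    deltas = aics - aics.min()
    w = np.exp(-deltas / 2)
    w /= w.sum()
    out = [
        AICRow(model=n, lnl=l, k=k, aic=float(a), delta=float(dd), weight=float(ww))
        for (n, l, k), a, dd, ww in zip(rows, aics, deltas, w)
    ]
    out.sort(key=lambda r: r.aic)
    return out


# -- harmonic-mean marginal likelihood ------------------------------------


@dataclass
class MarginalLikelihood:
    """A marginal-likelihood estimate in nats with bootstrap SE."""

    lnml: float
    se: float
    n: int
    estimator: str = "harmonic-mean"


def _hm(lnl: np.ndarray) -> float:
    # ln ML = -( logsumexp(-lnL) - ln n ), the log harmonic mean
    return float(-(logsumexp(-lnl) - math.log(lnl.size)))


def harmonic_mean_lnml(
    trace,
    *,
    n_bootstrap: int = 1000,
    bootstrap_seed: int = 0,
    truncate_frac: float | None = None,
) -> MarginalLikelihood:
    """Harmonic-mean estimate of ln marginal likelihood from a trace.

    ``trace`` is an :class:`~crabrange.phylo_io.MCMCTrace` (post-burn-in
    samples are used) or a plain array of log-likelihoods.  The SE is a
    moving-block bootstrap with block length ceil(sqrt(n)) and a fixed
    seed, which respects the autocorrelation of MCMC output.

    ``truncate_frac`` optionally drops that fraction of the *smallest*
    log-likelihood samples before estimation (a crude stabilization of the
    estimator's heavy left tail); it is off by default so the estimator
    matches the standard harmonic mean exactly.
    """
    lnl = trace.lnl if isinstance(trace, MCMCTrace) else np.asarray(trace, dtype=float)
    if lnl.ndim != 1 or lnl.size < 10:
        raise ValueError("need at least 10 post-burn-in samples")
    if not np.all(np.isfinite(lnl)):
        raise ValueError("non-finite log-likelihoods")
    if truncate_frac:
        drop = int(math.floor(truncate_frac * lnl.size))
        if drop:
            lnl = np.sort(lnl)[drop:]
    n = lnl.size
    est = _hm(lnl)

    b = int(math.ceil(math.sqrt(n)))
    k = int(math.ceil(n / b))
    starts = n - b + 1
    rng = np.random.default_rng(bootstrap_seed)
    reps = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        picks = rng.integers(0, starts, size=k)
        sample = np.concatenate([lnl[s : s + b] for s in picks])[:n]
        reps[i] = _hm(sample)
    se = float(np.std(reps, ddof=1))
    tag = "harmonic-mean" if not truncate_frac else f"harmonic-mean(trunc={truncate_frac})"
    return MarginalLikelihood(lnml=est, se=se, n=n, estimator=tag)


# -- Bayes factors ---------------------------------------------------------


def log10_bf(lnml_a: float, lnml_b: float) -> float:
    """log10 Bayes factor of model a over model b from ln marginal likelihoods."""
    if not (np.isfinite(lnml_a) and np.isfinite(lnml_b)):
        raise ValueError("marginal likelihoods must be finite")
    return (lnml_a - lnml_b) / LN10


def bf_category(log10bf: float) -> str:
    """Support category of a log10 Bayes factor (computed on the unrounded
    value; negative or small values give ``none``)."""
    if not np.isfinite(log10bf):
        raise ValueError("log10 BF must be finite")
    s, st, vs = BF_THRESHOLDS
    if log10bf > vs:
        return "very strong"
    if log10bf > st:
        return "strong"
    if log10bf > s:
        return "substantial"
    return "none"


def category_stars(category: str) -> str:
    return {"none": "", "substantial": "*", "strong": "**", "very strong": "***"}[category]


@dataclass
class BFMatrix:
    """Pairwise log10 Bayes-factor matrix with support-category marks.

    ``matrix[i, j]`` is the log10 BF of model i over model j (antisymmetric
    up to rounding); the diagonal is NaN.
    """

    labels: list[str]
    lnml: np.ndarray
    matrix: np.ndarray
    categories: list[list[str]]

    def to_dataframe(self, decimals: int = 2) -> pd.DataFrame:
        """Half-up rounded table with star marks, Table-style."""
        cells = []
        for i, _ in enumerate(self.labels):
            row = []
            for j, _ in enumerate(self.labels):
                if i == j:
                    row.append("-")
                else:
                    val = self.matrix[i, j]
                    txt = f"{_round_half_up(val, decimals):.{decimals}f}"
                    if val > 0:
                        txt += category_stars(self.categories[i][j])
                    row.append(txt)
            cells.append(row)
        return pd.DataFrame(cells, index=self.labels, columns=self.labels)


def _round_half_up(x: float, decimals: int) -> float:
    f = 10**decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


def bf_matrix(models: list[tuple]) -> BFMatrix:
    """Pairwise log10 BF matrix from (label, lnML) pairs.

    ``lnML`` entries may be floats or :class:`MarginalLikelihood` records.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    labels = [str(lab) for lab, _ in models]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    lnml = np.array(
        [m.lnml if isinstance(m, MarginalLikelihood) else float(m) for _, m in models]
    )
    k = len(labels)
    M = np.full((k, k), np.nan)
    cats = [["" for _ in range(k)] for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            M[i, j] = log10_bf(lnml[i], lnml[j])
            cats[i][j] = bf_category(M[i, j])
    return BFMatrix(labels=labels, lnml=lnml, matrix=M, categories=cats)


# -- HPD intervals ---------------------------------------------------------


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(level * n) sorted samples.

    Ties between equal-width windows break toward the lowest lower bound.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    m = int(math.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum = lowest lower bound
    return float(x[i]), float(x[i + m - 1])
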