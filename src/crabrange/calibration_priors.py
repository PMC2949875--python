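"""Prior densities for the dating design.

Three families of priors parameterize divergence-time analyses on the crab
chronogram and the package's synthetic dating fixtures:

* **Offset gamma fossil calibrations** -- a gamma density shifted so its
  support starts at the fossil's minimum age (the node must predate the
  fossil).  The three calibrations used here are 16.5 Ma (shape 4.0),
  6 Ma (shape 2.0) and 2.5 Ma (shape 3.0), all with scale 1.0; larger
  shapes express more uncertainty about how far the node predates the
  fossil.
* **Temporal node-age constraints** -- normal densities centred on a
  hypothesized age (45, 35 or 25 Ma) with standard deviation equal to 20%
  of the mean, expressing general temporal uncertainty for
  hypothesis-testing runs.
* **A rate-calibrated clock prior** -- a normal density on the 16S rDNA
  substitution rate, mean 0.88 %/Ma with 10% SD, truncated at zero and
  renormalized (rates are positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "OffsetGamma",
    "TemporalConstraint",
    "ClockRatePrior",
    "DEFAULT_FOSSIL_CALIBRATIONS",
    "TEMPORAL_MEANS",
    "offset_gamma",
    "temporal_prior",
    "clock_rate_prior",
    "load_calibrations",
]

#: Node-age means (Ma) of the temporal hypotheses compared by Bayes factors.
TEMPORAL_MEANS = (45.0, 35.0, 25.0)


@dataclass(frozen=True)
class OffsetGamma:
    """Gamma calibration density with a hard lower cut-off at ``offset`` Ma."""

    offset: float
    shape: float
    scale: float = 1.0
    node: str | None = None  # e.g. "MRCA(tipX,tipY)"

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def _dist(self):
        return stats.gamma(a=self.shape, loc=self.offset, scale=self.scale)

    def pdf(self, x) -> np.ndarray | float:
        return self._dist.pdf(x)

    def logpdf(self, x):
        return self._dist.logpdf(x)

    def rvs(self, size: int, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng)
        return self.offset + rng.gamma(self.shape, self.scale, size=size)

    @property
    def mean(self) -> float:
        return self.offset + self.shape * self.scale

    @property
    def mode(self) -> float:
        return self.offset + max(self.shape - 1.0, 0.0) * self.scale


def offset_gamma(x, prior: OffsetGamma):
    """Density of the offset-gamma calibration at age(s) ``x`` (Ma)."""
    return prior.pdf(x)


#: The three fossil calibrations of the crab dating design.
DEFAULT_FOSSIL_CALIBRATIONS = (
    OffsetGamma(offset=16.5, shape=4.0, scale=1.0, node="MRCA(Potamon_fluviatile,Potamon_persicum)"),
    OffsetGamma(offset=6.0, shape=2.0, scale=1.0, node="MRCA(Potamonautes_niloticus,Platythelphusa_armata)"),
    OffsetGamma(offset=2.5, shape=3.0, scale=1.0, node="MRCA(Sartoriana_spinigera,Sartoriana_blanfordi)"),
)


@dataclass(frozen=True)
class TemporalConstraint:
    """Normal node-age constraint, sd fixed at 20% of the mean."""

    node: str
    mean_age: float

    def __post_init__(self):
        if self.mean_age <= 0:
            raise ValueError("mean age must be positive")

    @property
    def sd(self) -> float:
        return 0.20 * self.mean_age

    def pdf(self, age):
        return stats.norm.pdf(age, loc=self.mean_age, scale=self.sd)

    def rvs(self, size: int, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng)
        return rng.normal(self.mean_age, self.sd, size=size)


def temporal_prior(age, constraint: TemporalConstraint):
    """Density of a temporal node-age hypothesis at ``age`` (Ma)."""
    return constraint.pdf(age)


@dataclass(frozen=True)
class ClockRatePrior:
    """Zero-truncated normal prior on a substitution rate (%/Ma)."""

    mean: float = 0.88
    sd: float = 0.088  # 10% of the mean

    @property
    def _dist(self):
        a = (0.0 - self.mean) / self.sd
        return stats.truncnorm(a=a, b=np.inf, loc=self.mean, scale=self.sd)

    def pdf(self, rate):
        x = np.asarray(rate, dtype=float)
        out = np.where(x > 0, self._dist.pdf(np.maximum(x, 1e-300)), 0.0)
        return float(out) if np.isscalar(rate) else out

    def rvs(self, size: int, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng)
        return self._dist.rvs(size=size, random_state=rng)


def clock_rate_prior(rate, prior: ClockRatePrior | None = None):
    """Density of the rate-calibrated clock prior at ``rate`` (%/Ma)."""
    return (prior or ClockRatePrior()).pdf(rate)


def load_calibrations(yaml_text: str) -> list[OffsetGamma]:
    """Parse a YAML calibration list.

    Each entry: ``{node: "MRCA(tipX,tipY)", offset: Ma, shape: float,
    scale: float}`` (scale defaults to 1.0).
    """
    doc = yaml.safe_load(yaml_text)
    entries = doc.get("calibrations", doc) if isinstance(doc, dict) else doc
    if not isinstance(entries, list) or not entries:
        raise ValueError("expected a list of calibration entries")
    out = []
    for ent in entries:
        out.append(
            OffsetGamma(
                offset=float(ent["offset"]),
                shape=float(ent["shape"]),
                scale=float(ent.get("scale", 1.0)),
                node=ent.get("node"),
            )
        )
    return out
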