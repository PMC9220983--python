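"""Shared configuration machinery: errors, named random substreams, and
parametric distribution specifications used by the natural-history model.

Every stochastic component of the simulator draws from a named substream so
that, e.g., changing a test's specificity never perturbs the natural-history
draws — a requirement for clean parallel-universe contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
from scipy import stats


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


class DomainError(ValueError):
    """An operation was called outside its mathematical domain."""


class ContractViolation(RuntimeError):
    """Paired inputs (e.g. control/screened universes) do not match."""


#: Named substreams. The indices are part of the reproducibility contract:
#: reordering them changes every seeded simulation.
STREAMS: Mapping[str, int] = {
    "other_cause": 0,   # other-cause death ages
    "onset": 1,         # tumor presence, onset ages, DCIS fates
    "thresholds": 2,    # growth rates, detectability quantiles, d_clinical, d_fatal
    "screening": 3,     # per-round DCIS detection draws
    "survival": 4,      # survival after the fatal-diameter crossing
    "fp": 5,            # false-positive draws (Bernoulli mode only)
    "attendance": 6,    # per-round attendance draws
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    Children are spawned from :class:`numpy.random.SeedSequence` with a fixed
    spawn key per stream name, so streams are mutually independent and stable
    across runs and platforms.
    """
    if name not in STREAMS:
        raise ConfigError(f"unknown random stream {name!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[name],))
    return np.random.Generator(np.random.PCG64(ss))


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------
#
# The natural-history parameters are declared as small frozen specs rather
# than frozen scipy objects so they can round-trip through YAML/JSON configs.


@dataclass(frozen=True)
class Lognormal:
    """Lognormal parameterised by its median and log-scale sigma."""

    median: float
    sigma: float

    def validate(self, field: str) -> None:
        if not (self.median > 0):
            raise ConfigError(f"{field}: lognormal median must be > 0, got {self.median}")
        if not (self.sigma > 0):
            raise ConfigError(f"{field}: lognormal sigma must be > 0, got {self.sigma}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median), self.sigma, size=size))

    def mean(self) -> float:
        return self.median * math.exp(0.5 * self.sigma**2)


@dataclass(frozen=True)
class TruncNormal:
    """Normal truncated to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def validate(self, field: str) -> None:
        if not (self.sd > 0):
            raise ConfigError(f"{field}: sd must be > 0, got {self.sd}")
        if not (self.low < self.high):
            raise ConfigError(f"{field}: require low < high, got [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        # inverse-CDF sampling keeps the draw count fixed (one uniform each),
        # which the substream reproducibility contract relies on
        u = rng.uniform(size=size)
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class Exponential:
    """Exponential parameterised by its mean."""

    mean: float

    def validate(self, field: str) -> None:
        if not (self.mean > 0):
            raise ConfigError(f"{field}: exponential mean must be > 0, got {self.mean}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.exponential(self.mean, size=size)


_DIST_KINDS = {"lognormal": Lognormal, "truncnormal": TruncNormal, "exponential": Exponential}

Distribution = Lognormal | TruncNormal | Exponential


def distribution_from_dict(spec: Any, field: str) -> Distribution:
    """Build a distribution spec from a config mapping like
    ``{"kind": "lognormal", "median": 3.0, "sigma": 0.4}``."""
    if isinstance(spec, (Lognormal, TruncNormal, Exponential)):
        return spec
    if not isinstance(spec, Mapping) or "kind" not in spec:
        raise ConfigError(f"{field}: expected a mapping with a 'kind' key, got {spec!r}")
    kind = spec["kind"]
    if kind not in _DIST_KINDS:
        raise ConfigError(f"{field}: unknown distribution kind {kind!r}")
    kwargs = {k: float(v) for k, v in spec.items() if k != "kind"}
    try:
        dist = _DIST_KINDS[kind](**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{field}: bad parameters for {kind}: {exc}") from exc
    dist.validate(field)
    return dist


def distribution_to_dict(dist: Distribution) -> dict:
    kind = {Lognormal: "lognormal", TruncNormal: "truncnormal", Exponential: "exponential"}[type(dist)]
    out = {"kind": kind}
    out.update({k: getattr(dist, k) for k in dist.__dataclass_fields__})
    return out
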