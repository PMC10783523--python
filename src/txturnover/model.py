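"""Analytic core of the infinitely-many-genes model for transcript turnover.

Each de novo transcript is gained exactly once on the genealogy of the
sampled individuals and is subsequently lost independently in each lineage.
On the coalescent time scale, gains arrive at rate ``theta/2`` per lineage
and each transcript is lost at rate ``rho/2`` per lineage, where
``theta = 2*Ne*u`` and ``rho = 2*Ne*v`` for per-generation rates ``u, v``
and effective population size ``Ne``.  The expected frequency spectrum of a
sample of ``n`` individuals has the closed form

    E[G_k] = sum_i theta_i/k * [n (n-1) ... (n-k+1)]
                            / [(n-1+rho_i) (n-2+rho_i) ... (n-k+rho_i)]

for ``k < n``; for ``k = n`` the denominator product extends one step
further down to ``rho_i`` and a count ``C_fixed`` of permanently fixed
(zero-loss) transcripts is added.  One or two independent transcript
classes (slow/fast turnover) are supported.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .spectra import FrequencySpectrum, TheoreticalSpectrum

__all__ = [
    "Scale",
    "RateClass",
    "PopulationScaling",
    "TurnoverParams",
    "deterministic_transcript_count",
    "expected_spectrum",
    "chi_square",
    "convert_scale",
    "pairwise_difference",
    "mean_per_sample",
    "normalize_gain",
]


class Scale(str, enum.Enum):
    """Time scale a parameter set is expressed on."""

    COALESCENT = "coalescent"      # rates per 2*Ne generations
    PER_GENERATION = "per_generation"
    PER_YEAR = "per_year"


class RateClass(NamedTuple):
    theta: float  # gain rate
    rho: float    # loss rate


@dataclass(frozen=True)
class PopulationScaling:
    """Constants linking coalescent, generation and calendar time.

    Defaults are for the European D. melanogaster population: effective size
    900 000 and 26 generations per year (a two-week generation time).
    """

    effective_population_size: float = 900_000.0
    generations_per_year: float = 26.0
    generation_time_weeks: float = 2.0  # informational only

    def __post_init__(self) -> None:
        if self.effective_population_size <= 0 or self.generations_per_year <= 0:
            raise ValueError("population scaling constants must be positive")


@dataclass(frozen=True)
class TurnoverParams:
    """Gain/loss rates for one or two transcript classes plus fixed count."""

    classes: tuple[RateClass, ...]
    c_fixed: float = 0.0
    scale: Scale = Scale.COALESCENT

    def __post_init__(self) -> None:
        classes = tuple(RateClass(float(t), float(r)) for t, r in self.classes)
        if not 1 <= len(classes) <= 2:
            raise ValueError("supports one or two transcript classes")
        for cl in classes:
            if cl.theta < 0 or cl.rho < 0:
                raise ValueError("rates must be non-negative")
        if self.c_fixed < 0:
            raise ValueError("c_fixed must be non-negative")
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "scale", Scale(self.scale))

    @classmethod
    def single(cls, theta: float, rho: float, c_fixed: float = 0.0,
               scale: Scale = Scale.COALESCENT) -> "TurnoverParams":
        return cls(classes=(RateClass(theta, rho),), c_fixed=c_fixed, scale=scale)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def equilibrium_count(self) -> float:
        """Expected per-sample transcript count, sum theta_i/rho_i + c_fixed."""
        total = self.c_fixed
        for cl in self.classes:
            if cl.theta > 0 and cl.rho == 0:
                raise ValueError("class with theta>0 and rho=0 has no equilibrium; "
                                 "model permanent transcripts via c_fixed")
            if cl.theta > 0:
                total += cl.theta / cl.rho
        return total


def deterministic_transcript_count(u: float, v: float, t: float) -> float:
    """Mean transcript count after time ``t`` starting from zero.

    Solves dg/dt = u - v*g, i.e. g(t) = u/v * (1 - exp(-v*t)); the v=0 limit
    is linear accumulation u*t.  Saturates at the equilibrium u/v.
    """
    if u < 0 or v < 0 or t < 0:
        raise ValueError("u, v and t must be non-negative")
    if v == 0:
        return u * t
    return u / v * -math.expm1(-v * t)


def _spectrum_one_class(theta: float, rho: float, n: int) -> np.ndarray:
    t = np.zeros(n)
    if theta == 0:
        return t
    num = 1.0
    den = 1.0
    for k in range(1, n):
        num *= n - k + 1          # n * (n-1) * ... * (n-k+1)
        den *= n - k + rho        # (n-1+rho) * ... * (n-k+rho)
        t[k - 1] = theta / k * num / den
    # k = n: denominator product runs one factor further, down to rho itself
    if rho == 0:
        raise ValueError("rho=0 makes the k=n expectation infinite; "
                         "model fixed transcripts via c_fixed instead")
    num *= 1.0
    den *= rho
    t[n - 1] = theta / n * num / den
    return t


def expected_spectrum(params: TurnoverParams, n: int) -> TheoreticalSpectrum:
    """Expected frequency spectrum under the infinitely-many-genes model.

    ``params`` must be on the coalescent scale.  ``c_fixed`` is added to the
    ``k = n`` entry once (fixed transcripts are present in every sample).
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if params.scale is not Scale.COALESCENT:
        raise ValueError("expected_spectrum requires coalescent-scale parameters; "
                         "use convert_scale first")
    t = np.zeros(n)
    for cl in params.classes:
        t += _spectrum_one_class(cl.theta, cl.rho, n)
    t[n - 1] += params.c_fixed
    return TheoreticalSpectrum(n=n, t=tuple(t))


def chi_square(empirical, theoretical) -> float:
    """Pearson-style distance sum_k (d_k - t_k)^2 / t_k between spectra.

    Terms with ``t_k = 0`` contribute 0 when ``d_k = 0`` and raise otherwise.
    """
    d = empirical.as_array() if hasattr(empirical, "as_array") else np.asarray(empirical, float)
    t = theoretical.as_array() if hasattr(theoretical, "as_array") else np.asarray(theoretical, float)
    if d.shape != t.shape:
        raise ValueError("spectra have different lengths")
    zero = t == 0
    if np.any(zero & (d != 0)):
        raise ValueError("t_k = 0 with d_k > 0: chi-square undefined")
    out = np.zeros_like(d)
    np.divide((d - t) ** 2, t, out=out, where=~zero)
    return float(out.sum())


_COALESCENT_FACTOR = {
    # multiplier taking a coalescent-scale rate to the target scale
    Scale.COALESCENT: lambda s: 1.0,
    Scale.PER_GENERATION: lambda s: 1.0 / (2.0 * s.effective_population_size),
    Scale.PER_YEAR: lambda s: s.generations_per_year / (2.0 * s.effective_population_size),
}


def convert_scale(params: TurnoverParams, scaling: PopulationScaling,
                  target_scale: Scale) -> TurnoverParams:
    """Re-express gain/loss rates on another time scale.

    theta = 2*Ne*u links the coalescent and per-generation scales; per-year
    rates are per-generation rates times the number of generations per year.
    ``c_fixed`` is a count and is never rescaled.
    """
    target_scale = Scale(target_scale)
    source = Scale(params.scale)
    factor = _COALESCENT_FACTOR[target_scale](scaling) / _COALESCENT_FACTOR[source](scaling)
    classes = tuple(RateClass(cl.theta * factor, cl.rho * factor) for cl in params.classes)
    return replace(params, classes=classes, scale=target_scale)


def mean_per_sample(spectrum: FrequencySpectrum) -> float:
    """Mean number of transcripts carried by one sample, sum_k k*d_k / n."""
    k = np.arange(1, spectrum.n + 1)
    return float((k * spectrum.as_array()).sum() / spectrum.n)


def pairwise_difference(spectrum) -> float:
    """Average number of transcripts private to one member of a sample pair.

    A transcript present in k of n samples differs in k*(n-k) of the
    n*(n-1)/2 unordered pairs, hence the weight 2*k*(n-k)/(n*(n-1)).
    """
    n = spectrum.n
    if n < 2:
        raise ValueError("pairwise difference needs n >= 2")
    k = np.arange(1, n + 1)
    w = 2.0 * k * (n - k) / (n * (n - 1))
    return float((w * spectrum.as_array()).sum())


def normalize_gain(gain_rate: float, coverage_fraction: float) -> float:
    """Gain rate per unit of genome actually belonging to the region.

    Regions covering more of the genome offer more positions for a transcript
    to arise; dividing by the genome fraction the region covers makes gain
    rates comparable across regions.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    return gain_rate / coverage_fraction
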