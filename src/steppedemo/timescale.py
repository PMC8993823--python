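"""Calibration of relative divergence estimates to absolute time.

The multispecies coalescent reports divergence as tau = 2*mu*t, with mu the
mutation rate per site per generation and t the divergence time in
generations.  Absolute ages in years are obtained per posterior tau sample
by drawing the mutation rate and the generation time from gamma
distributions parameterized by mean and standard deviation, so calibration
uncertainty propagates into the reported highest-posterior-density (HPD)
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GammaSpec", "TimeEstimate", "gamma_from_mean_sd", "tau_to_years", "hpd_interval"]


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution given as mean and sd; shape=(mean/sd)^2, rate=mean/sd^2.

    ``sd == 0`` marks a degenerate point mass at the mean (allowed: used for
    species with a fixed, known generation time).
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("mean must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def degenerate(self) -> bool:
        return self.sd == 0

    @property
    def shape(self) -> float:
        if self.degenerate:
            return np.inf
        return (self.mean / self.sd) ** 2

    @property
    def rate(self) -> float:
        if self.degenerate:
            return np.inf
        return self.mean / self.sd**2

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.degenerate:
            return np.full(size, self.mean)
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


def gamma_from_mean_sd(mean: float, sd: float) -> GammaSpec:
    """Gamma spec from a mean and standard deviation (sd=0 -> point mass)."""
    return GammaSpec(mean=mean, sd=sd)


@dataclass(frozen=True)
class TimeEstimate:
    """Posterior samples of an absolute time in years, with mean and 95% HPD."""

    samples: np.ndarray
    mean: float
    hpd95: tuple[float, float]


def tau_to_years(
    tau_samples: np.ndarray,
    mu_spec: GammaSpec,
    gen_spec: GammaSpec,
    seed: int,
) -> TimeEstimate:
    """Convert tau samples to years: years = tau / (2*mu) * g per sample.

    One mutation-rate draw and one generation-time draw are paired with each
    tau sample.
    """
    tau = np.asarray(tau_samples, dtype=float)
    if tau.ndim != 1 or tau.size == 0:
        raise ValueError("tau_samples must be a non-empty 1-D array")
    if (tau <= 0).any():
        raise ValueError("all tau samples must be > 0")
    rng = np.random.default_rng(seed)
    mu = mu_spec.sample(rng, tau.size)
    g = gen_spec.sample(rng, tau.size)
    if (mu <= 0).any() or (g <= 0).any():  # pragma: no cover - gamma draws are positive
        raise RuntimeError("non-positive calibration draw")
    years = tau / (2.0 * mu) * g
    if years.size >= 20:
        hpd = hpd_interval(years, 0.95)
    else:  # too few samples for a meaningful HPD: report the full range
        hpd = (float(years.min()), float(years.max()))
    return TimeEstimate(samples=years, mean=float(years.mean()), hpd95=hpd)


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over the sorted samples containing
    ceil(mass * n) points."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])
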