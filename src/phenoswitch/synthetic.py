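"""Synthetic particle-size samples and phenotype-count time courses.

The generator emulates the statistical structure the analysis assumes, so every
downstream stage is testable without instrument exports:

* diameter samples are drawn from a two-component Gaussian mixture — a small
  ancestral-like mode inside the 3–13 μm class and a large multicellular mode
  above 13 μm — truncated below an instrument detection threshold by rejection
  sampling (Coulter-counter style lower cutoff);
* phenotype-count time courses are produced by forward-simulating the
  switching model and, optionally, adding binomial counting noise to the
  small-cluster tallies at each observation time.

Default mixture parameters (means 6 and 25 μm, SDs 1.5 and 5 μm, equal
weights, 3 μm detection threshold) respect the 13 μm class boundary; default
observation times are 12, 20, 24 and 48 h of batch growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .model import SwitchingParams, predicted_fractions, simulate
from .sizedist import ParticleSample

__all__ = [
    "MixtureSpec",
    "ObservationDesign",
    "generate_mixture_sample",
    "generate_timecourse_observations",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component Gaussian diameter mixture with a lower detection cutoff."""

    weight_small: float = 0.5
    mean_small: float = 6.0
    sd_small: float = 1.5
    mean_large: float = 25.0
    sd_large: float = 5.0
    detection_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_small <= 1.0:
            raise ValidationError(f"weight_small must be in [0, 1], got {self.weight_small}")
        if self.sd_small <= 0 or self.sd_large <= 0:
            raise ValidationError("component SDs must be > 0")
        if not self.mean_small < self.mean_large:
            raise ValidationError("mean_small must be < mean_large")
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")

    def pdf(self, x) -> np.ndarray:
        """Untruncated mixture density."""
        x = np.asarray(x, dtype=float)
        return self.weight_small * norm.pdf(x, self.mean_small, self.sd_small) + (
            1.0 - self.weight_small
        ) * norm.pdf(x, self.mean_large, self.sd_large)

    def cdf(self, x) -> np.ndarray:
        """Untruncated mixture CDF."""
        x = np.asarray(x, dtype=float)
        return self.weight_small * norm.cdf(x, self.mean_small, self.sd_small) + (
            1.0 - self.weight_small
        ) * norm.cdf(x, self.mean_large, self.sd_large)

    def truncated_cdf(self, x) -> np.ndarray:
        """CDF of the mixture conditioned on exceeding the detection threshold."""
        tail = 1.0 - float(self.cdf(self.detection_threshold))
        x = np.asarray(x, dtype=float)
        out = (self.cdf(x) - self.cdf(self.detection_threshold)) / tail
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ObservationDesign:
    """Sampling design for phenotype-count time courses."""

    observation_times: tuple = (12.0, 20.0, 24.0, 48.0)
    total_count_per_time: int = 10_000
    binomial_sampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.observation_times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("observation_times must be non-empty and strictly increasing")
        if self.total_count_per_time < 1:
            raise ValidationError("total_count_per_time must be >= 1")


def generate_mixture_sample(
    spec: MixtureSpec,
    n: int,
    seed: int,
    *,
    sample_id: str = "synthetic",
    time_h: float = 24.0,
    condition: str | None = None,
) -> ParticleSample:
    """Draw ``n`` diameters from the truncated mixture (rejection sampling).

    Every returned diameter strictly exceeds the detection threshold; the
    draw is bitwise-deterministic for a fixed seed.
    """
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    accept_prob = 1.0 - float(spec.cdf(spec.detection_threshold))
    if accept_prob < 1e-12:
        raise ValidationError(
            "detection_threshold truncates essentially all mixture mass; "
            "rejection sampling would not terminate"
        )
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        size = max(int(remaining / accept_prob * 1.2) + 16, 64)
        small = rng.random(size) < spec.weight_small
        means = np.where(small, spec.mean_small, spec.mean_large)
        sds = np.where(small, spec.sd_small, spec.sd_large)
        draws = rng.normal(means, sds)
        kept = draws[draws > spec.detection_threshold]
        chunks.append(kept[:remaining])
        remaining -= min(kept.size, remaining)
    diameters = np.concatenate(chunks) if chunks else np.empty(0)
    return ParticleSample(
        sample_id=sample_id,
        time_h=time_h,
        diameters=diameters,
        condition=condition,
        detection_threshold=spec.detection_threshold,
    )


def generate_timecourse_observations(
    params: SwitchingParams,
    design: ObservationDesign,
    *,
    t_end: float | None = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Simulate the switching model and tabulate phenotype counts.

    Returns a DataFrame with columns ``time_h``, ``count_small``,
    ``count_large`` and ``fraction_small``.  With ``binomial_sampling`` the
    small-cluster count at each time is a Binomial(total_count_per_time, p)
    draw around the model fraction p and ``fraction_small`` is the observed
    count fraction; without it the model fractions are passed through exactly
    and counts are their rounded expectations.  All randomness (simulation
    noise when sigma_eta > 0, and binomial counting noise) derives from
    ``design.seed``.
    """
    times = np.asarray(design.observation_times, dtype=float)
    if t_end is None:
        t_end = float(times[-1])
    rng = np.random.default_rng(design.seed)
    if params.sigma_eta > 0:
        sim_seed = int(rng.integers(0, 2**31 - 1))
        traj = simulate(params, t_end=t_end, dt=dt, seed=sim_seed)
    else:
        traj = simulate(params, t_end=t_end, dt=dt)
    fractions = predicted_fractions(traj, times)
    n_total = design.total_count_per_time
    if design.binomial_sampling:
        count_small = rng.binomial(n_total, fractions)
        fraction_small = count_small / n_total
    else:
        count_small = np.rint(n_total * fractions).astype(int)
        fraction_small = fractions
    return pd.DataFrame(
        {
            "time_h": times,
            "count_small": count_small.astype(int),
            "count_large": (n_total - count_small).astype(int),
            "fraction_small": fraction_small,
        }
    )
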